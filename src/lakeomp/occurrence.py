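"""Occurrence accounting, source clustering, and bioactivity screening.

Works on tidy concentration tables (compound, site_group, date,
depth_m, replicate, value_ngL, censored, loq_ngL):

* detection frequencies (value >= LOQ counts as detected);
* compound x site-group median matrices with configurable substitution
  of left-censored values (LOQ/sqrt(2) by default);
* row-wise z-score standardization (population SD) followed by
  agglomerative clustering with Euclidean distance and Ward linkage,
  the standard recipe for source-related occurrence heatmaps;
* Pearson correlation of a compound against the per-sample cumulative
  concentration of all detected compounds;
* exposure-activity ratios (EAR): measured molar concentration over a
  bioassay activity concentration cutoff, summed per site and flagged
  against the conservative effects-screening threshold of 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "ClusterAssignment",
    "EarResult",
    "detection_frequency",
    "substitute_censored",
    "median_concentration_matrix",
    "zscore_standardize",
    "ward_cluster",
    "correlate_with_cumulative",
    "exposure_activity_ratios",
    "EAR_THRESHOLD",
]

#: conservative effects-screening threshold on the exposure-activity ratio
EAR_THRESHOLD = 1e-3

_SAMPLE_KEYS = ["site_group", "date", "depth_m", "replicate"]

_SUBSTITUTIONS = {
    "zero": lambda loq: 0.0,
    "loq_half": lambda loq: loq / 2.0,
    "loq_sqrt2": lambda loq: loq / np.sqrt(2.0),
}


def detection_frequency(values, loq: float, censored=None) -> float:
    """Percent of samples in which a compound is detected.

    A sample counts as detected when its value is >= LOQ and not
    flagged censored.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one sample")
    detected = vals >= loq
    if censored is not None:
        detected &= ~np.asarray(censored, dtype=bool)
    return float(100.0 * detected.sum() / vals.size)


def substitute_censored(
    frame: pd.DataFrame, rule: str = "loq_sqrt2"
) -> pd.Series:
    """Concentrations with censored entries replaced per ``rule``
    (one of 'zero', 'loq_half', 'loq_sqrt2')."""
    if rule not in _SUBSTITUTIONS:
        raise ValueError(f"unknown substitution rule '{rule}'")
    sub = _SUBSTITUTIONS[rule]
    values = frame["value_ngL"].to_numpy(dtype=float).copy()
    censored = frame["censored"].to_numpy(dtype=bool)
    loq = frame["loq_ngL"].to_numpy(dtype=float)
    values[censored] = [sub(l) for l in loq[censored]]
    return pd.Series(values, index=frame.index, name="value_ngL")


def median_concentration_matrix(
    frame: pd.DataFrame,
    group_col: str = "site_group",
    substitution: str = "loq_sqrt2",
) -> pd.DataFrame:
    """Compound x site-group matrix of median concentrations.

    Censored values are substituted per ``substitution`` before taking
    medians. Groups with no samples for a compound are dropped with a
    warning when they would otherwise produce empty cells.
    """
    required = {"compound", group_col, "value_ngL", "censored", "loq_ngL"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"concentration frame missing columns: {sorted(missing)}")
    work = frame.copy()
    work["value_ngL"] = substitute_censored(work, substitution)
    matrix = work.pivot_table(
        index="compound", columns=group_col, values="value_ngL", aggfunc="median"
    )
    empty = matrix.columns[matrix.isna().all(axis=0)]
    if len(empty):
        warnings.warn(f"dropping empty site groups: {list(empty)}", stacklevel=2)
        matrix = matrix.drop(columns=empty)
    matrix.columns.name = None
    return matrix


def zscore_standardize(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-scores (population SD): each compound row gets mean 0
    and SD 1. Zero-variance rows are set to all zeros and flagged.

    Returns ``(standardized, zero_variance_flags)``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two site groups per compound")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD across groups
    flags = (sd.ravel() == 0.0)
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (values - mean) / safe_sd
    z[flags, :] = 0.0
    return (
        pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        pd.Series(flags, index=matrix.index, name="zero_variance"),
    )


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat cluster labels plus the full agglomeration record."""

    labels: pd.Series  # compound -> cluster id (1..k)
    linkage: np.ndarray  # scipy linkage matrix (merge heights in col 2)
    k: int


def ward_cluster(matrix: pd.DataFrame, k: int) -> ClusterAssignment:
    """Agglomerative clustering of compound rows: Euclidean distance,
    Ward linkage, tree cut at ``k`` flat clusters."""
    if k < 1:
        raise ValueError("k must be >= 1")
    n = matrix.shape[0]
    if k > n:
        raise ValueError("k cannot exceed the number of compounds")
    if n == 1:
        return ClusterAssignment(
            labels=pd.Series([1], index=matrix.index, name="cluster"),
            linkage=np.empty((0, 4)),
            k=k,
        )
    Z = linkage(matrix.to_numpy(dtype=float), method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels, index=matrix.index, name="cluster"),
        linkage=Z,
        k=k,
    )


def correlate_with_cumulative(frame: pd.DataFrame, compound: str) -> float:
    """Pearson r between a compound's per-sample concentration and the
    per-sample cumulative concentration of all detected compounds.

    Cumulative concentration sums uncensored values only. Samples where
    the compound itself is censored are excluded. Returns NaN when the
    correlation is undefined (zero variance); raises if fewer than
    three detected samples exist.
    """
    detected = frame[~frame["censored"]]
    cumulative = detected.groupby(_SAMPLE_KEYS)["value_ngL"].sum()
    own = (
        detected[detected["compound"] == compound]
        .set_index(_SAMPLE_KEYS)["value_ngL"]
    )
    if len(own) < 3:
        raise ValueError(
            f"{compound}: need >= 3 samples with the compound detected"
        )
    total = cumulative.loc[own.index]
    x = own.to_numpy(dtype=float)
    y = total.to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class EarResult:
    """Exposure-activity ratios at three aggregation levels."""

    per_endpoint: pd.DataFrame  # compound, site_group, endpoint, ear
    per_compound: pd.DataFrame  # compound, site_group, ear, exceeds
    per_site: pd.DataFrame  # site_group, cumulative_ear
    threshold: float = EAR_THRESHOLD


def exposure_activity_ratios(
    frame: pd.DataFrame,
    acc_table: pd.DataFrame,
    molecular_weights: Mapping[str, float] | None = None,
    scenario: str = "mean",
    endpoint_stat: str = "max",
    threshold: float = EAR_THRESHOLD,
    substitution: str = "loq_sqrt2",
) -> EarResult:
    """Screening-level exposure-activity ratios per compound and site.

    EAR = C_uM / ACC_uM with C_uM = C_ngL / MW / 1000. The exposure
    statistic per site is the mean (``scenario='mean'``) or max of the
    per-sample concentrations across dates/replicates; endpoints are
    summarized per compound by ``endpoint_stat`` ('max' is the
    conservative default, 'median' available); the per-site cumulative
    EAR sums over compounds. Compounds without a molecular weight or
    any ACC row are skipped with a warning.
    """
    if scenario not in ("mean", "max"):
        raise ValueError("scenario must be 'mean' or 'max'")
    if endpoint_stat not in ("max", "median"):
        raise ValueError("endpoint_stat must be 'max' or 'median'")
    mw_map: dict[str, float] = dict(molecular_weights or {})
    if not mw_map and "molecular_weight" in acc_table.columns:
        mw_map = (
            acc_table.drop_duplicates("compound")
            .set_index("compound")["molecular_weight"]
            .to_dict()
        )
    work = frame.copy()
    work["value_ngL"] = substitute_censored(work, substitution)
    exposure = (
        work.groupby(["compound", "site_group"])["value_ngL"]
        .agg(scenario)
        .rename("c_ngL")
        .reset_index()
    )
    acc_by_compound = {name: grp for name, grp in acc_table.groupby("compound")}
    endpoint_rows = []
    for _, row in exposure.iterrows():
        comp = row["compound"]
        if comp not in mw_map or comp not in acc_by_compound:
            warnings.warn(
                f"skipping {comp}: no molecular weight or activity data",
                stacklevel=2,
            )
            continue
        c_um = row["c_ngL"] / mw_map[comp] / 1000.0
        for _, acc_row in acc_by_compound[comp].iterrows():
            endpoint_rows.append(
                (comp, row["site_group"], acc_row["endpoint"],
                 c_um / acc_row["acc_uM"])
            )
    per_endpoint = pd.DataFrame(
        endpoint_rows, columns=["compound", "site_group", "endpoint", "ear"]
    )
    if per_endpoint.empty:
        per_compound = pd.DataFrame(
            columns=["compound", "site_group", "ear", "exceeds"]
        )
        per_site = pd.DataFrame(columns=["site_group", "cumulative_ear"])
        return EarResult(per_endpoint, per_compound, per_site, threshold)
    per_compound = (
        per_endpoint.groupby(["compound", "site_group"])["ear"]
        .agg(endpoint_stat)
        .reset_index()
    )
    per_compound["exceeds"] = per_compound["ear"] >= threshold
    per_site = (
        per_compound.groupby("site_group")["ear"]
        .sum()
        .rename("cumulative_ear")
        .reset_index()
    )
    return EarResult(per_endpoint, per_compound, per_site, threshold)
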