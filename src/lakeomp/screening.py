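"""Nontarget HRMS feature prioritization by vertical-profile similarity.

During strong summer stratification, negatively buoyant wastewater and
tributary inflows plunge into the metalimnion and imprint a
concentration spike (here at 7 m) on wastewater-derived compounds.
This module exploits that fingerprint to prioritize unknown features
from a peak table:

1. spike filter - intensity at the spike depth at least ``fold_threshold``
   (default 1.2) times the intensity at both adjacent depths;
2. static filters - presence in every vertical-profile sample, maximum
   intensity strictly above ``intensity_floor`` (default 1e5), and an
   optional blank-ratio check;
3. correlation filter - Pearson r strictly above ``r_threshold``
   (default 0.7) between the max-normalized feature profile and the
   reference profile built from confirmed wastewater-derived compounds.

The retained set is the pure conjunction of the three filters, so the
application order never changes the outcome; the cascade runs cheapest
first and keeps a per-feature audit trail. Peak-shape and molecular-
formula plausibility checks need raw spectra, which a feature table
does not carry; the audit trail marks them unevaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Feature",
    "FeatureTable",
    "ReferenceProfile",
    "ScreeningConfig",
    "normalize_profile",
    "build_reference_profile",
    "pearson_r",
    "spike_filter",
    "static_filters",
    "correlation_filter",
    "prioritize_features",
]

UNEVALUATED_NOTE = "peak shape/symmetry and molecular formula criteria unevaluated"


@dataclass(frozen=True)
class Feature:
    """One HRMS feature: mass, retention time, per-depth intensities."""

    feature_id: str
    mz: float  # Da
    retention_time: float  # min
    intensities: np.ndarray  # one per sampling depth, >= 0
    blank_intensity: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("mz must be > 0")
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite and >= 0")


@dataclass
class FeatureTable:
    """A feature table: per-depth intensity columns plus metadata.

    ``frame`` columns: ``feature_id``, ``mz``, ``rt_min``, one
    ``int_<depth>m`` column per sampling depth, optionally ``blank``
    and a ground-truth ``truth`` label for synthetic tables.
    """

    depths: np.ndarray
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        for col in ("feature_id", "mz", "rt_min"):
            if col not in self.frame.columns:
                raise ValueError(f"feature table missing column '{col}'")
        missing = [c for c in self.intensity_columns if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table missing intensity columns: {missing}")

    @property
    def intensity_columns(self) -> list[str]:
        return [_intensity_column(z) for z in self.depths]

    def __len__(self) -> int:
        return len(self.frame)

    def feature(self, row) -> Feature:
        """Build a :class:`Feature` from one frame row."""
        blank = row["blank"] if "blank" in row.index and pd.notna(row["blank"]) else None
        return Feature(
            feature_id=str(row["feature_id"]),
            mz=float(row["mz"]),
            retention_time=float(row["rt_min"]),
            intensities=row[self.intensity_columns].to_numpy(dtype=float),
            blank_intensity=None if blank is None else float(blank),
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        frame = pd.read_csv(path)
        depths = sorted(
            float(c[4:-1]) for c in frame.columns if c.startswith("int_") and c.endswith("m")
        )
        if not depths:
            raise ValueError("no int_<depth>m intensity columns found")
        return cls(depths=np.asarray(depths), frame=frame)


def _intensity_column(depth: float) -> str:
    d = float(depth)
    return f"int_{d:g}m"


@dataclass(frozen=True)
class ReferenceProfile:
    """Mean normalized vertical profile of confirmed wastewater compounds."""

    depths: np.ndarray
    values: np.ndarray  # max-normalized, peak = 1
    std: np.ndarray | None = None  # pointwise spread band

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "values", values)
        if depths.size != values.size:
            raise ValueError("depths and values must have equal length")
        if self.std is not None:
            object.__setattr__(self, "std", np.asarray(self.std, dtype=float))


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds of the prioritization cascade (defaults as applied
    to the July vertical-profile samples)."""

    spike_depth: float = 7.0  # m
    adjacent_depths: tuple[float, float] = (6.0, 8.0)
    fold_threshold: float = 1.2  # inclusive ("at least")
    r_threshold: float = 0.7  # strict (">")
    intensity_floor: float = 1e5  # strict ("above")
    blank_ratio: float = 3.0
    require_all_samples: bool = True
    normalization: str = "max"

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not -1 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must lie in [-1, 1]")
        if self.intensity_floor < 0:
            raise ValueError("intensity_floor must be >= 0")


def normalize_profile(values, mode: str = "max") -> np.ndarray:
    """Scale a nonnegative profile so its max (or mean) equals 1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("profile is empty")
    if np.any(arr < 0):
        raise ValueError("profile values must be >= 0")
    if mode == "max":
        scale = arr.max()
    elif mode == "mean":
        scale = arr.mean()
    else:
        raise ValueError(f"unknown normalization mode '{mode}'")
    if scale <= 0:
        raise ValueError("profile must contain at least one positive value")
    return arr / scale


def build_reference_profile(
    profiles: Sequence[np.ndarray], depths
) -> ReferenceProfile:
    """Pointwise mean of normalized profiles, re-normalized to peak 1.

    The pointwise standard deviation of the input profiles (the spread
    band around the mean) is carried along, scaled by the same factor.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    depths = np.asarray(depths, dtype=float)
    stack = np.vstack([np.asarray(p, dtype=float) for p in profiles])
    if stack.shape[1] != depths.size:
        raise ValueError("profiles and depth grid have mismatched lengths")
    mean = stack.mean(axis=0)
    std = stack.std(axis=0)
    peak = mean.max()
    if peak <= 0:
        raise ValueError("mean profile has no positive values")
    return ReferenceProfile(depths=depths, values=mean / peak, std=std / peak)


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.corrcoef(xa, ya)[0, 1])


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    detail: dict = field(default_factory=dict)


def spike_filter(feature: Feature, depths, config: ScreeningConfig) -> FilterResult:
    """Metalimnetic spike test: I(spike)/I(adjacent) >= fold for both
    adjacent depths (inclusive). Zero adjacent intensity gives an
    infinite ratio: the test passes but is flagged."""
    depths = np.asarray(depths, dtype=float)
    try:
        i_spike = feature.intensities[_depth_index(depths, config.spike_depth)]
    except KeyError as exc:
        raise ValueError(str(exc)) from None
    ratios = {}
    flagged = False
    passed = True
    for d in config.adjacent_depths:
        i_adj = feature.intensities[_depth_index(depths, d)]
        if i_adj == 0.0:
            ratios[d] = np.inf
            flagged = True
            continue
        ratio = i_spike / i_adj
        ratios[d] = ratio
        if ratio < config.fold_threshold:
            passed = False
    return FilterResult(passed, {"ratios": ratios, "zero_adjacent": flagged})


def _depth_index(depths: np.ndarray, target: float) -> int:
    hits = np.flatnonzero(np.isclose(depths, target))
    if hits.size == 0:
        raise KeyError(f"depth {target} m not in sampling grid")
    return int(hits[0])


def static_filters(feature: Feature, config: ScreeningConfig) -> FilterResult:
    """Presence, intensity-floor (strict), and blank-ratio criteria."""
    present = bool(np.all(feature.intensities > 0)) or not config.require_all_samples
    peak = float(feature.intensities.max())
    above_floor = peak > config.intensity_floor
    if feature.blank_intensity is None:
        blank_ok = True
    else:
        blank_ok = peak >= config.blank_ratio * feature.blank_intensity
    return FilterResult(
        present and above_floor and blank_ok,
        {"present_all": present, "above_floor": above_floor, "blank_ok": blank_ok},
    )


def correlation_filter(
    feature: Feature, reference: ReferenceProfile, config: ScreeningConfig
) -> FilterResult:
    """Shape-similarity test: r(normalized profile, reference) > threshold.

    A constant (zero-variance) feature profile fails with an
    undefined-correlation flag rather than raising.
    """
    if feature.intensities.size != reference.values.size:
        raise ValueError("feature and reference are on different depth grids")
    if np.all(feature.intensities == 0) or np.std(feature.intensities) == 0:
        return FilterResult(False, {"r": np.nan, "undefined": True})
    norm = normalize_profile(feature.intensities, config.normalization)
    try:
        r = pearson_r(norm, reference.values)
    except ValueError:
        # effectively constant profile after normalization round-off
        return FilterResult(False, {"r": np.nan, "undefined": True})
    return FilterResult(r > config.r_threshold, {"r": r, "undefined": False})


def prioritize_features(
    table: FeatureTable,
    reference: ReferenceProfile,
    config: ScreeningConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full cascade over a feature table.

    Returns ``(selected, audit)``: the retained rows sorted by
    descending r, then descending peak intensity, then feature_id; and
    a per-feature audit trail recording every criterion's outcome and,
    for rejected features, the first criterion that eliminated them.
    """
    config = config or ScreeningConfig()
    if not np.allclose(table.depths, reference.depths):
        raise ValueError("feature table and reference are on different depth grids")
    audit_rows = []
    keep = []
    for _, row in table.frame.iterrows():
        feat = table.feature(row)
        spike = spike_filter(feat, table.depths, config)
        static = static_filters(feat, config)
        corr = correlation_filter(feat, reference, config)
        passed = spike.passed and static.passed and corr.passed
        if not spike.passed:
            reason = "spike"
        elif not static.passed:
            flags = static.detail
            if not flags["present_all"]:
                reason = "presence"
            elif not flags["above_floor"]:
                reason = "intensity_floor"
            else:
                reason = "blank"
        elif not corr.passed:
            reason = "correlation"
        else:
            reason = ""
        ratios = spike.detail["ratios"]
        audit_rows.append(
            {
                "feature_id": feat.feature_id,
                "passed": passed,
                "spike_pass": spike.passed,
                **{
                    f"ratio_{d:g}m": ratios[d] for d in config.adjacent_depths
                },
                "zero_adjacent": spike.detail["zero_adjacent"],
                "present_all": static.detail["present_all"],
                "above_floor": static.detail["above_floor"],
                "blank_ok": static.detail["blank_ok"],
                "corr_pass": corr.passed,
                "r": corr.detail["r"],
                "r_undefined": corr.detail["undefined"],
                "reject_reason": reason,
                "notes": UNEVALUATED_NOTE,
            }
        )
        if passed:
            keep.append(
                (feat.feature_id, corr.detail["r"], float(feat.intensities.max()))
            )
    audit = pd.DataFrame(audit_rows)
    if keep:
        order = sorted(keep, key=lambda t: (-t[1], -t[2], t[0]))
        ids = [t[0] for t in order]
        selected = (
            table.frame.set_index("feature_id").loc[ids].reset_index().copy()
        )
        selected["r"] = [t[1] for t in order]
    else:
        selected = table.frame.iloc[0:0].copy()
        selected["r"] = pd.Series(dtype=float)
    return selected, audit
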