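"""Mass-flow bookkeeping and load apportionment for a river network.

Loads are discharge x concentration mass flows in g/d
(m^3/d x ng/L x 1000 L/m^3 x 1e-9 g/ng = 1e-6 x Q x C). Input loads
from declared sources (a lake outlet, upstream rivers, a lateral
reach) are summed and compared with the load measured at the basin
outlet: a ratio above 1 points to in-stream transformation or loss,
below 1 to unaccounted sources. Fractional contributions of each
source to the outlet load are aggregated by compound class (wastewater
derived vs mixed source), averaged over compounds per sampling event
and then across events with a spread band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteLoad",
    "ApportionmentResult",
    "mass_flow",
    "aggregate_input_load",
    "input_output_ratio",
    "fractional_contributions",
    "loads_from_network",
    "eligible_compounds",
    "EXPECTED_INPUT_ROLES",
]

#: declared input roles of a fully gauged network
EXPECTED_INPUT_ROLES = ("lake_outlet", "upstream", "lateral")

NG_PER_L_TO_G_PER_M3 = 1e-6  # ng/L x m^3/d -> g/d


def mass_flow(discharge_m3d: float, conc_ngL: float) -> float:
    """Load in g/d from discharge (m^3/d) and concentration (ng/L)."""
    if discharge_m3d < 0 or conc_ngL < 0:
        raise ValueError("discharge and concentration must be >= 0")
    return discharge_m3d * conc_ngL * NG_PER_L_TO_G_PER_M3


@dataclass(frozen=True)
class SiteLoad:
    """One gauged (Q, C) pairing and its mass flow."""

    site: str
    date: object
    discharge_m3d: float
    conc_ngL: float

    @property
    def load_gd(self) -> float:
        return mass_flow(self.discharge_m3d, self.conc_ngL)


def aggregate_input_load(
    source_loads: Mapping[str, float],
    expected_sources: Sequence[str] | None = None,
) -> float:
    """Sum the declared source loads (g/d) into L_input.

    Warns when ``expected_sources`` are declared but absent from the
    mapping (coverage gap); duplicate labels cannot occur in a mapping,
    so pass a sequence of (source, load) pairs to have duplicates
    rejected.
    """
    if isinstance(source_loads, Mapping):
        items = list(source_loads.items())
    else:
        items = list(source_loads)
        labels = [s for s, _ in items]
        dupes = {s for s in labels if labels.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate source labels: {sorted(dupes)}")
    if not items:
        raise ValueError("source set must be non-empty")
    if expected_sources is not None:
        missing = set(expected_sources) - {s for s, _ in items}
        if missing:
            warnings.warn(
                f"input load coverage incomplete, missing: {sorted(missing)}",
                stacklevel=2,
            )
    return float(sum(load for _, load in items))


def input_output_ratio(l_input: float, l_output: float) -> tuple[float, str]:
    """L_input / L_output with an interpretation flag.

    Ratios above 1 suggest in-stream transformation or loss between the
    inputs and the basin outlet; ratios below 1 suggest unidentified
    localized or diffuse sources.
    """
    if l_output <= 0:
        raise ValueError("L_output must be > 0")
    ratio = l_input / l_output
    if ratio > 1.0:
        flag = "loss"
    elif ratio < 1.0:
        flag = "unidentified_sources"
    else:
        flag = "balanced"
    return float(ratio), flag


@dataclass(frozen=True)
class ApportionmentResult:
    """Per-compound ratios/fractions and class-aggregate summaries.

    ``per_compound`` has one row per compound x event with L_input,
    L_output, their ratio, and the percent contribution of each source
    group; ``class_summary`` aggregates the lake vs rivers split per
    compound class as mean +/- SD across events. Source fractions sum
    to ratio x 100%, not forced to 100%.
    """

    per_compound: pd.DataFrame
    class_summary: pd.DataFrame
    sd_convention: str = "population"


def loads_from_network(network: pd.DataFrame) -> pd.DataFrame:
    """Compute per-row loads (g/d) for a tidy gauged-network table.

    Requires columns site, role, date, discharge_m3d, compound,
    conc_ngL; role is one of lake_outlet / upstream / lateral / output.
    """
    required = {"site", "role", "date", "discharge_m3d", "compound", "conc_ngL"}
    missing = required - set(network.columns)
    if missing:
        raise ValueError(f"network table missing columns: {sorted(missing)}")
    bad = set(network["role"]) - set(EXPECTED_INPUT_ROLES) - {"output"}
    if bad:
        raise ValueError(f"unknown roles: {sorted(bad)}")
    out = network.copy()
    out["load_gd"] = [
        mass_flow(q, c) for q, c in zip(out["discharge_m3d"], out["conc_ngL"])
    ]
    return out


def fractional_contributions(
    network: pd.DataFrame,
    classes: Mapping[str, str] | None = None,
    sd_convention: str = "population",
) -> ApportionmentResult:
    """Load apportionment over a gauged network table.

    For every compound and sampling event: L_input is the sum of the
    declared input-site loads, L_output the load at the ``output`` site,
    and each source contributes 100 x L_s / L_output percent. The class
    summary groups sources into the lake outlet vs the rivers
    (upstream + lateral), averages fractions over the compounds of each
    class within an event, and reports mean +/- SD across events
    (population SD by default; 'sample' uses n-1).
    """
    if sd_convention not in ("population", "sample"):
        raise ValueError("sd_convention must be 'population' or 'sample'")
    loads = loads_from_network(network)
    if classes is None:
        if "class" not in loads.columns:
            raise ValueError("need a 'class' column or an explicit classes mapping")
        classes = (
            loads.drop_duplicates("compound").set_index("compound")["class"].to_dict()
        )
    missing_class = set(loads["compound"]) - set(classes)
    if missing_class:
        raise ValueError(f"compounds without a class label: {sorted(missing_class)}")

    rows = []
    for (comp, date), grp in loads.groupby(["compound", "date"]):
        out_rows = grp[grp["role"] == "output"]
        if out_rows.empty:
            raise ValueError(f"no output site for {comp} on {date}")
        l_output = float(out_rows["load_gd"].sum())
        inputs = grp[grp["role"] != "output"]
        dupes = inputs["site"][inputs["site"].duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate source labels: {sorted(set(dupes))}")
        l_input = aggregate_input_load(
            dict(zip(inputs["site"], inputs["load_gd"]))
        )
        ratio, flag = input_output_ratio(l_input, l_output)
        l_lake = float(
            inputs.loc[inputs["role"] == "lake_outlet", "load_gd"].sum()
        )
        l_rivers = float(
            inputs.loc[inputs["role"] != "lake_outlet", "load_gd"].sum()
        )
        rows.append(
            {
                "compound": comp,
                "date": date,
                "class": classes[comp],
                "l_input_gd": l_input,
                "l_output_gd": l_output,
                "ratio": ratio,
                "flag": flag,
                "frac_lake_pct": 100.0 * l_lake / l_output,
                "frac_rivers_pct": 100.0 * l_rivers / l_output,
            }
        )
    per_compound = pd.DataFrame(rows)

    ddof = 0 if sd_convention == "population" else 1
    summary_rows = []
    for cls, cgrp in per_compound.groupby("class"):
        for source_col, source in (
            ("frac_lake_pct", "lake"),
            ("frac_rivers_pct", "rivers"),
        ):
            event_means = cgrp.groupby("date")[source_col].mean()
            mean = float(event_means.mean())
            sd = float(event_means.std(ddof=ddof)) if len(event_means) > 1 else 0.0
            summary_rows.append(
                {
                    "class": cls,
                    "source": source,
                    "mean_frac_pct": mean,
                    "sd_frac_pct": sd,
                    "n_events": int(len(event_means)),
                }
            )
    class_summary = pd.DataFrame(summary_rows)
    return ApportionmentResult(per_compound, class_summary, sd_convention)


def eligible_compounds(
    frame: pd.DataFrame, threshold_pct: float = 80.0
) -> list[str]:
    """Compounds whose detection frequency at gauged sites exceeds
    ``threshold_pct`` (strict), the eligibility gate for apportionment.

    ``frame`` is tidy with compound, value_ngL, censored, loq_ngL.
    """
    keep = []
    for comp, grp in frame.groupby("compound"):
        detected = (~grp["censored"].astype(bool)) & (
            grp["value_ngL"] >= grp["loq_ngL"]
        )
        freq = 100.0 * detected.sum() / len(grp)
        if freq > threshold_pct:
            keep.append(comp)
    return sorted(keep)
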