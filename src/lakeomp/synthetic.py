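"""Seeded generators for synthetic lake-river contaminant scenarios.

Everything downstream (screening, clustering, fate modeling, load
apportionment) is exercised on data from this module. The generators
emulate the statistical structure of a wastewater-impacted, dimictic,
rapidly flushed urban lake draining through a river network:

* a ~12 km^2, mean-depth ~10.9 m basin flushed about four times per
  year, fed by four tributaries and one WWTP outfall;
* sigmoid two-layer summer stratification with a sharp metalimnion;
* negatively buoyant inflows that plunge and imprint a metalimnetic
  (7 m) concentration spike on wastewater-derived compounds;
* compound rosters split into a wastewater-derived class (dominated by
  the WWTP) and a mixed-source class (each elevated in one tributary);
* duplicate field measurements with small multiplicative errors and
  left-censoring at per-compound limits of quantification.

All generators are deterministic under (seed, parameters).
"""

from __future__ import annotations

import datetime as _dt
from typing import Sequence

import numpy as np
import pandas as pd

from . import lakemodel
from .scenario import (
    CompoundSpec,
    InflowRecord,
    LakeGeometry,
    LakeScenario,
    TemperatureProfile,
    conical_geometry,
)
from .screening import FeatureTable, ReferenceProfile, _intensity_column

__all__ = [
    "generate_lake_scenario",
    "generate_temperature_profiles",
    "generate_observations",
    "generate_site_observations",
    "generate_median_matrix",
    "wastewater_profile_shape",
    "reference_profile_for",
    "generate_feature_table",
    "generate_acc_table",
    "generate_river_network",
    "lognormal_factors",
    "TRIBUTARIES",
    "WWTP",
]

TRIBUTARIES = ("Ninemile Creek", "Onondaga Creek", "Ley Creek", "Harbor Brook")
WWTP = "WWTP"
#: relative tributary discharge weights (largest creeks first)
_TRIB_WEIGHTS = np.array([0.40, 0.33, 0.20, 0.07])
#: WWTP treatment capacity, 84 million gallons per day in m^3/d
_WWTP_DISCHARGE = 84e6 * 3.78541e-3

JULY = _dt.date(2017, 7, 15)
OCTOBER = _dt.date(2017, 10, 15)


def lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of
    variation ``cv`` (cv = 0 gives exact ones)."""
    if cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def generate_temperature_profiles(
    depth_grid,
    thermocline_depth: float,
    epi_temp: float,
    hypo_temp: float,
    dates: Sequence,
    sharpness: float = 1.5,
) -> list[TemperatureProfile]:
    """Sigmoid two-layer temperature profiles, one per date.

    T(z) = hypo + (epi - hypo) / (1 + exp(sharpness * (z - thermocline))):
    monotone non-increasing with depth, approaching ``epi_temp`` at the
    surface and ``hypo_temp`` at the bottom. ``epi_temp == hypo_temp``
    degenerates to a uniform profile.
    """
    if epi_temp < hypo_temp:
        raise ValueError("inverted stratification (epi_temp < hypo_temp) unsupported")
    if sharpness <= 0:
        raise ValueError("sharpness must be > 0")
    z = np.asarray(depth_grid, dtype=float)
    if not (z.min() <= thermocline_depth <= z.max()):
        raise ValueError("thermocline_depth must lie inside the depth grid")
    temps = hypo_temp + (epi_temp - hypo_temp) / (
        1.0 + np.exp(sharpness * (z - thermocline_depth))
    )
    return [TemperatureProfile(date=d, temps=temps.copy()) for d in dates]


def generate_lake_scenario(
    n_wastewater: int = 8,
    n_mixed: int = 8,
    stratification_strength: float = 1.0,
    seed: int = 0,
    *,
    geometry: LakeGeometry | None = None,
    flushes_per_year: float = 4.0,
    f_meta_range: tuple[float, float] = (0.1, 0.4),
    thermocline_depth: float = 7.0,
    photolysis_fraction: float = 0.33,
    light_attenuation_Kd: float = 0.5,
    epilimnion_depth: float = 6.0,
) -> LakeScenario:
    """Build a fully consistent synthetic lake scenario.

    ``stratification_strength`` scales the epilimnion-hypolimnion
    temperature contrast (0 gives vertically uniform profiles).
    The water budget is exactly balanced: four tributaries plus a WWTP
    outfall sum to the outlet discharge, which is set so the lake
    flushes ``flushes_per_year`` times per year on a completely mixed
    basis. Metalimnion routing fractions are drawn uniformly from
    ``f_meta_range`` per inflow; a ``photolysis_fraction`` share of the
    compounds receives a nonzero lumped surface photolysis rate.
    """
    if n_wastewater < 0 or n_mixed < 0 or n_wastewater + n_mixed == 0:
        raise ValueError("need at least one compound")
    if stratification_strength < 0:
        raise ValueError("stratification_strength must be >= 0")
    lo, hi = f_meta_range
    if not (0 <= lo <= hi <= 1):
        raise ValueError("f_meta_range must satisfy 0 <= lo <= hi <= 1")
    rng = np.random.default_rng(seed)
    geom = geometry or conical_geometry()

    s = stratification_strength
    july = generate_temperature_profiles(
        geom.depth_grid, thermocline_depth, 8.0 + s * 17.0, 8.0, [JULY], sharpness=3.0
    )[0]
    october = generate_temperature_profiles(
        geom.depth_grid, min(12.0, geom.depth_grid.max()), 10.0 + s * 4.0, 10.0,
        [OCTOBER], sharpness=0.8,
    )[0]

    q_out = flushes_per_year * geom.total_volume / 365.25
    q_wwtp = min(_WWTP_DISCHARGE, 0.3 * q_out)
    q_tribs = (q_out - q_wwtp) * _TRIB_WEIGHTS / _TRIB_WEIGHTS.sum()

    # compound roster with source-partitioned inflow concentrations
    compounds: list[CompoundSpec] = []
    names_ww = [f"ww_{i + 1:02d}" for i in range(n_wastewater)]
    names_mx = [f"mx_{i + 1:02d}" for i in range(n_mixed)]
    sources = [WWTP, *TRIBUTARIES]
    for name in names_ww + names_mx:
        is_ww = name.startswith("ww")
        pattern: dict[str, float] = {}
        if is_ww:
            c_wwtp = float(rng.lognormal(np.log(1500.0), 0.6))
            pattern[WWTP] = c_wwtp
            for trib in TRIBUTARIES:
                pattern[trib] = 0.05 * c_wwtp * float(rng.uniform(0.5, 1.5))
        else:
            home = TRIBUTARIES[int(rng.integers(len(TRIBUTARIES)))]
            c_home = float(rng.lognormal(np.log(300.0), 0.5))
            pattern[WWTP] = 0.1 * c_home
            for trib in TRIBUTARIES:
                pattern[trib] = c_home if trib == home else 0.1 * c_home
        k_photo = (
            float(10 ** rng.uniform(-2.3, -1.3))
            if rng.uniform() < photolysis_fraction
            else 0.0
        )
        loq = (
            float(10 ** rng.uniform(0.0, np.log10(25.0)))
            if rng.uniform() < 0.85
            else float(10 ** rng.uniform(np.log10(25.0), 2.0))
        )
        compounds.append(
            CompoundSpec(
                name=name,
                source_class="wastewater_derived" if is_ww else "mixed_source",
                molecular_weight=float(rng.uniform(120.0, 500.0)),
                photolysis_k_surface=k_photo,
                true_inflow_pattern=pattern,
                loq=loq,
            )
        )

    # inflow temperature near the metalimnetic layer's, so dense inflows
    # plunge to ~thermocline depth under the July profile
    t_meta = float(july.temps[geom.layer_index(thermocline_depth)])
    inflows = []
    for source, q in zip(sources, [q_wwtp, *q_tribs]):
        # the steadily discharged effluent is the densest inflow and
        # plunges most strongly: its fraction sits near the top of the
        # envelope, the tributaries' in the lower half
        if source == WWTP:
            f_lo, f_hi = lo + 0.75 * (hi - lo), hi
        else:
            f_lo, f_hi = lo, lo + 0.5 * (hi - lo)
        inflows.append(
            InflowRecord(
                source_name=source,
                date=JULY,
                discharge=float(q),
                temperature=max(1.0, t_meta + float(rng.normal(0.0, 0.3))),
                concentrations={
                    c.name: c.true_inflow_pattern[source] for c in compounds
                },
                f_meta=float(rng.uniform(f_lo, f_hi)),
            )
        )

    return LakeScenario(
        geometry=geom,
        temperature_profiles=(july, october),
        inflows=tuple(inflows),
        outflow_discharge=float(q_out),
        compounds=tuple(compounds),
        light_attenuation_Kd=light_attenuation_Kd,
        epilimnion_depth=epilimnion_depth,
        rng_seed=int(seed),
    )


def generate_observations(
    scenario: LakeScenario,
    noise_cv: float = 0.05,
    seed: int = 0,
    *,
    duration_days: float = 60.0,
    n_replicates: int = 2,
    kz=None,
    with_photolysis: bool = False,
) -> pd.DataFrame:
    """Forward-simulate truth, then emulate duplicate field measurements.

    The scenario is integrated for ``duration_days`` from a clean
    initial state; the final vertical profile of each compound is the
    ground truth, to which mean-one multiplicative lognormal noise
    (coefficient of variation ``noise_cv``) is applied per replicate.
    Values below the compound's LOQ are flagged censored. ``kz``
    defaults to the two-regime stratified profile derived from the
    scenario's first temperature profile (strong mixed-layer mixing,
    quiescent below the thermocline), which preserves the metalimnetic
    spike imprinted by plunging inflows.

    Returns a tidy frame: compound, date, depth_m, replicate, true_ngL,
    value_ngL, censored, loq_ngL.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if kz is None:
        kz = lakemodel.stratified_kz(
            scenario.geometry, scenario.temperature_profiles[0]
        )
    sim = lakemodel.simulate_lake(
        scenario, kz, duration=duration_days, with_photolysis=with_photolysis
    )
    date = scenario.temperature_profiles[0].date
    rows = []
    for comp in scenario.compounds:
        truth = sim.final_profile(comp.name)
        noise = lognormal_factors(rng, noise_cv, (n_replicates, truth.size))
        for rep in range(n_replicates):
            values = truth * noise[rep]
            for iz, z in enumerate(scenario.geometry.depth_grid):
                v = float(values[iz])
                rows.append(
                    (
                        comp.name,
                        date,
                        float(z),
                        rep + 1,
                        float(truth[iz]),
                        v,
                        v < comp.loq,
                        comp.loq,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "compound",
            "date",
            "depth_m",
            "replicate",
            "true_ngL",
            "value_ngL",
            "censored",
            "loq_ngL",
        ],
    )


def generate_site_observations(
    scenario: LakeScenario,
    noise_cv: float = 0.05,
    seed: int = 0,
    *,
    n_replicates: int = 2,
    river_attenuation: tuple[float, float] = (0.131, 0.331),
) -> pd.DataFrame:
    """Per-site concentration samples across the lake-river system.

    Site groups are the WWTP outfall, the four tributaries, the lake,
    and two downstream river groups; each is sampled on the scenario's
    two profile dates with ``n_replicates`` duplicates. Wastewater-
    derived compounds peak at the WWTP outfall; each mixed-source
    compound peaks in its home tributary; river concentrations are the
    lake outlet level scaled by ``river_attenuation`` (wastewater,
    mixed), emulating dilution by the larger river network.

    Returns tidy columns: compound, site_group, date, depth_m,
    replicate, value_ngL, censored, loq_ngL.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    q_total = scenario.total_inflow
    dates = [p.date for p in scenario.temperature_profiles]
    att_ww, att_mx = river_attenuation
    rows = []
    for comp in scenario.compounds:
        # flow-weighted mixture approximates the lake outlet concentration
        c_lake = (
            sum(
                f.discharge * f.concentrations.get(comp.name, 0.0)
                for f in scenario.inflows
            )
            / q_total
        )
        att = att_ww if comp.source_class == "wastewater_derived" else att_mx
        site_truth = {
            **{f.source_name: f.concentrations.get(comp.name, 0.0)
               for f in scenario.inflows},
            "Lake": c_lake,
            "Seneca River": att * c_lake,
            "Oswego River": att * c_lake,
        }
        for site, truth in site_truth.items():
            for idate, date in enumerate(dates):
                # October concentrations run lower than July
                level = truth * (1.0 if idate == 0 else 0.7)
                noise = lognormal_factors(rng, noise_cv, n_replicates)
                for rep in range(n_replicates):
                    v = float(level * noise[rep])
                    rows.append(
                        (
                            comp.name,
                            site,
                            date,
                            0.0,
                            rep + 1,
                            v,
                            v < comp.loq,
                            comp.loq,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "compound",
            "site_group",
            "date",
            "depth_m",
            "replicate",
            "value_ngL",
            "censored",
            "loq_ngL",
        ],
    )


def generate_median_matrix(
    n_per_block: tuple[int, int] = (12, 12),
    groups: Sequence[str] = (WWTP, "Ninemile Creek", "Lake", "Seneca River"),
    seed: int = 0,
    noise_cv: float = 0.1,
    high: float = 1000.0,
    low: float = 50.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-concentration matrix with two planted source blocks.

    Block 0 compounds are elevated in ``groups[0]``, block 1 compounds
    in ``groups[1]``; all other cells sit at the ``low`` background.
    Returns ``(matrix, labels)`` where ``labels`` maps each compound to
    its planted block (0 or 1) for external scoring of a clustering.
    """
    if len(groups) < 2:
        raise ValueError("need at least two site groups")
    rng = np.random.default_rng(seed)
    names, labels, rows = [], [], []
    for block, count in enumerate(n_per_block):
        for i in range(count):
            name = f"block{block}_{i + 1:02d}"
            base = np.full(len(groups), low)
            base[block] = high
            rows.append(base * lognormal_factors(rng, noise_cv, len(groups)))
            names.append(name)
            labels.append(block)
    matrix = pd.DataFrame(rows, index=names, columns=list(groups))
    matrix.index.name = "compound"
    return matrix, pd.Series(labels, index=names, name="block")


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def wastewater_profile_shape(
    depths,
    spike_depth: float = 7.0,
    epi_level: float = 0.55,
    hypo_level: float = 0.2,
    spike_level: float = 1.0,
    spike_width: float = 0.5,
) -> np.ndarray:
    """Canonical normalized vertical profile of a wastewater-derived
    compound under strong stratification: an epilimnetic plateau, a
    sharp metalimnetic spike, and a decaying hypolimnetic tail."""
    z = np.asarray(depths, dtype=float)
    base = hypo_level + (epi_level - hypo_level) / (
        1.0 + np.exp(2.0 * (z - spike_depth - 0.5))
    )
    bump = (spike_level - base) * np.exp(-0.5 * ((z - spike_depth) / spike_width) ** 2)
    return base + bump


def reference_profile_for(scenario: LakeScenario) -> ReferenceProfile:
    """Reference profile on the scenario grid (max-normalized shape)."""
    shape = wastewater_profile_shape(scenario.geometry.depth_grid)
    return ReferenceProfile(
        depths=scenario.geometry.depth_grid,
        values=shape / shape.max(),
        std=np.zeros_like(shape),
    )


_DECOY_FAMILIES = ("flat", "reversed", "random", "walk")


def generate_feature_table(
    scenario: LakeScenario,
    n_planted: int = 5,
    n_decoys: int = 200,
    intensity_floor: float = 1e5,
    seed: int = 0,
    *,
    noise_cv: float = 0.05,
    decoy_families: Sequence[str] = _DECOY_FAMILIES,
) -> FeatureTable:
    """Synthetic HRMS feature table with known ground truth.

    Planted features track the wastewater reference profile (spike
    ratio >= 1.5 before noise) at intensities safely above
    ``intensity_floor``; decoys are drawn round-robin from profile
    families spanning the null space of the correlation filter: flat,
    reversed (hypolimnion-peaked), i.i.d. random, and random-walk.
    m/z is uniform on [100, 1000] Da and retention time on
    [1.7, 27.1] min. The ``truth`` column labels every feature.
    """
    if n_planted < 0 or n_decoys < 0:
        raise ValueError("counts must be >= 0")
    unknown = set(decoy_families) - set(_DECOY_FAMILIES)
    if unknown:
        raise ValueError(f"unknown decoy families: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    depths = scenario.geometry.depth_grid
    nz = depths.size
    shape = wastewater_profile_shape(depths)
    records = []

    def meta(i: int) -> dict:
        return {
            "feature_id": f"F{i:04d}",
            "mz": float(rng.uniform(100.0, 1000.0)),
            "rt_min": float(rng.uniform(1.7, 27.1)),
        }

    idx = 1
    for _ in range(n_planted):
        scale = 10 ** rng.uniform(np.log10(5.0 * intensity_floor), 7.0)
        profile = shape * scale * lognormal_factors(rng, noise_cv, nz)
        records.append({**meta(idx), "truth": "planted", "profile": profile})
        idx += 1
    for j in range(n_decoys):
        family = decoy_families[j % len(decoy_families)]
        scale = 10 ** rng.uniform(4.5, 6.5)
        if family == "flat":
            base = np.ones(nz)
        elif family == "reversed":
            base = shape[::-1].copy()
        elif family == "random":
            base = rng.uniform(0.1, 1.0, nz)
        else:  # random walk
            base = np.exp(np.cumsum(rng.normal(0.0, 0.25, nz)))
            base /= base.max()
        profile = base * scale * lognormal_factors(rng, noise_cv, nz)
        records.append({**meta(idx), "truth": f"decoy_{family}", "profile": profile})
        idx += 1

    columns = {c: [] for c in ("feature_id", "mz", "rt_min", "truth")}
    intensity_cols = {_intensity_column(z): [] for z in depths}
    for rec in records:
        for c in columns:
            columns[c].append(rec[c])
        for iz, col in enumerate(intensity_cols):
            intensity_cols[col].append(float(rec["profile"][iz]))
    frame = pd.DataFrame({**columns, **intensity_cols})
    return FeatureTable(depths=depths, frame=frame)


def generate_acc_table(
    compounds: Sequence[CompoundSpec],
    seed: int = 0,
    acc_range: tuple[float, float] = (0.05, 50.0),
    max_endpoints: int = 3,
) -> pd.DataFrame:
    """Synthetic activity-concentration table (stand-in for a
    high-throughput screening database extract).

    Each compound gets 1..max_endpoints endpoints with ACC drawn
    log-uniformly from ``acc_range`` (in uM). Columns: compound,
    endpoint, acc_uM, molecular_weight.
    """
    if not compounds:
        raise ValueError("compounds must be non-empty")
    lo, hi = acc_range
    if not 0 < lo <= hi:
        raise ValueError("acc_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    rows = []
    for comp in compounds:
        n_ep = int(rng.integers(1, max_endpoints + 1))
        for e in range(n_ep):
            acc = lo if lo == hi else float(
                10 ** rng.uniform(np.log10(lo), np.log10(hi))
            )
            rows.append((comp.name, f"endpoint_{e + 1}", acc, comp.molecular_weight))
    return pd.DataFrame(
        rows, columns=["compound", "endpoint", "acc_uM", "molecular_weight"]
    )


# ---------------------------------------------------------------------------
# river network
# ---------------------------------------------------------------------------

#: default upstream/lateral river discharges, m^3/d (sized so the lake
#: outlet carries roughly a tenth of the basin-outlet flow)
_RIVER_DISCHARGES = {
    "Seneca River upstream": 5.5e6,
    "Oneida River": 7.5e6,
    "Oswego River reach": 0.9e6,
}


def generate_river_network(
    scenario: LakeScenario,
    seed: int = 0,
    *,
    n_events: int = 2,
    noise_cv: float = 0.0,
    undeclared_load_fraction: float = 0.0,
    river_attenuation: tuple[float, float] = (0.131, 0.331),
) -> pd.DataFrame:
    """Synthetic gauged river-network table for load apportionment.

    Declared input sites are the lake outlet (role ``lake_outlet``),
    two upstream rivers (``upstream``) and one lateral reach
    (``lateral``); the basin outlet (role ``output``) carries exactly
    the sum of the declared input loads (conservative transport), plus
    an optional ``undeclared_load_fraction`` emulating unmonitored
    sources (which drives L_input/L_output below 1). Concentrations at
    river sites are the lake-outlet level scaled by
    ``river_attenuation`` per compound class. Event 2 runs at lower
    concentrations than event 1.

    Columns: site, role, date, discharge_m3d, compound, conc_ngL, class.
    """
    if undeclared_load_fraction < 0:
        raise ValueError("undeclared_load_fraction must be >= 0")
    rng = np.random.default_rng(seed)
    att_ww, att_mx = river_attenuation
    q_lake = scenario.outflow_discharge
    q_total = q_lake + sum(_RIVER_DISCHARGES.values())
    dates = [JULY, OCTOBER, *(JULY + _dt.timedelta(days=365 * k) for k in range(1, 5))]
    rows = []
    for event in range(n_events):
        date = dates[event]
        season = 1.0 if event % 2 == 0 else 0.7
        for comp in scenario.compounds:
            c_lake = season * sum(
                f.discharge * f.concentrations.get(comp.name, 0.0)
                for f in scenario.inflows
            ) / scenario.total_inflow
            att = att_ww if comp.source_class == "wastewater_derived" else att_mx
            noise = lognormal_factors(rng, noise_cv, 1 + len(_RIVER_DISCHARGES))
            site_rows = [
                ("Onondaga Lake outlet", "lake_outlet", q_lake, c_lake * noise[0])
            ]
            for k, (site, q) in enumerate(_RIVER_DISCHARGES.items()):
                role = "lateral" if site == "Oswego River reach" else "upstream"
                site_rows.append((site, role, q, att * c_lake * noise[k + 1]))
            load_in = sum(q * c for _, _, q, c in site_rows)  # m3/d * ng/L
            load_out = load_in * (1.0 + undeclared_load_fraction)
            c_out = load_out / q_total
            site_rows.append(("Oswego River mouth", "output", q_total, c_out))
            for site, role, q, c in site_rows:
                rows.append(
                    (site, role, date, float(q), comp.name, float(c),
                     comp.source_class)
                )
    return pd.DataFrame(
        rows,
        columns=["site", "role", "date", "discharge_m3d", "compound", "conc_ngL",
                 "class"],
    )
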