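"""Domain containers for a stratified lake-river contaminant scenario.

A scenario bundles everything the one-dimensional lake model needs:
hypsography (area as a function of depth), time-ordered vertical
temperature profiles, inflow records (discharge, temperature,
per-compound concentration, metalimnion routing fraction), the outlet
discharge, and the compound roster with source-class labels and
photolysis parameters.

Conventions
-----------
* Depth is positive downward, in metres. The water column is divided
  into uniform horizontal layers of thickness ``dz`` (1 m by default);
  ``depth_grid`` holds the layer *centres* ordered surface to bottom,
  so layer ``i`` occupies the band ``[z_i - dz/2, z_i + dz/2]``.
* Discharges are in m^3/d, concentrations in ng/L, temperatures in
  degrees Celsius.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "LakeGeometry",
    "TemperatureProfile",
    "InflowRecord",
    "CompoundSpec",
    "LakeScenario",
    "conical_geometry",
    "days_between",
]

#: relative tolerance for the steady-flow water balance of a scenario
WATER_BALANCE_RTOL = 1e-6


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass(frozen=True)
class LakeGeometry:
    """Hypsography of the lake on a uniform vertical grid.

    Parameters
    ----------
    depth_grid
        Layer-centre depths in m, strictly increasing, uniform spacing.
    area_of_depth
        Horizontal cross-sectional area in m^2 at each layer centre;
        positive and non-increasing with depth.
    """

    depth_grid: np.ndarray
    area_of_depth: np.ndarray

    def __post_init__(self) -> None:
        depths = _as_float_array(self.depth_grid, "depth_grid")
        areas = _as_float_array(self.area_of_depth, "area_of_depth")
        object.__setattr__(self, "depth_grid", depths)
        object.__setattr__(self, "area_of_depth", areas)
        if depths.size != areas.size:
            raise ValueError("depth_grid and area_of_depth must have equal length")
        spacing = np.diff(depths)
        if depths.size > 1 and (
            np.any(spacing <= 0) or not np.allclose(spacing, spacing[0])
        ):
            raise ValueError("depth_grid must be strictly increasing and uniform")
        if np.any(areas <= 0):
            raise ValueError("areas must be positive")
        if np.any(np.diff(areas) > 0):
            raise ValueError("areas must be non-increasing with depth")

    @property
    def n_layers(self) -> int:
        return self.depth_grid.size

    @property
    def dz(self) -> float:
        """Layer thickness in m."""
        if self.depth_grid.size > 1:
            return float(self.depth_grid[1] - self.depth_grid[0])
        return 1.0

    @property
    def layer_volumes(self) -> np.ndarray:
        """Volume of each layer in m^3 (area x thickness)."""
        return self.area_of_depth * self.dz

    @property
    def total_volume(self) -> float:
        return float(self.layer_volumes.sum())

    @property
    def interface_depths(self) -> np.ndarray:
        """Depths of the n-1 internal layer interfaces in m."""
        return 0.5 * (self.depth_grid[:-1] + self.depth_grid[1:])

    @property
    def interface_areas(self) -> np.ndarray:
        """Horizontal area at each internal interface in m^2."""
        return 0.5 * (self.area_of_depth[:-1] + self.area_of_depth[1:])

    def layer_bounds(self, i: int) -> tuple[float, float]:
        """Top and bottom depth of layer ``i`` in m."""
        z = float(self.depth_grid[i])
        h = self.dz / 2.0
        return (z - h, z + h)

    def layer_index(self, depth: float) -> int:
        """Index of the layer whose centre is nearest ``depth`` (ties up)."""
        return int(np.argmin(np.abs(self.depth_grid - depth)))


def conical_geometry(
    surface_area: float = 12e6,
    max_depth: float = 18.0,
    mean_depth: float = 10.9,
    dz: float = 1.0,
) -> LakeGeometry:
    """Conical-bowl hypsograph: area decreases linearly with depth.

    The bottom-to-surface area ratio is chosen so that the (continuous)
    basin has the requested mean depth. Defaults describe a 12 km^2,
    mean-depth 10.9 m urban lake sampled to 18 m. Layer centres sit at
    the integer sampling depths 1, 2, ..., max_depth m so that model
    layers coincide with the field sampling grid.
    """
    if not 0 < mean_depth <= max_depth:
        raise ValueError("mean_depth must be in (0, max_depth]")
    # continuous basin: mean depth = max_depth * (1 + f) / 2 with
    # f = A(bottom)/A(surface)
    f = 2.0 * mean_depth / max_depth - 1.0
    if f < 0:
        raise ValueError("mean_depth must be at least max_depth / 2 for a conical bowl")
    centers = np.arange(dz, max_depth + dz / 2.0, dz)
    areas = surface_area * (1.0 - (1.0 - f) * centers / max_depth)
    return LakeGeometry(depth_grid=centers, area_of_depth=areas)


def days_between(d0, d1) -> float:
    """Elapsed days between two timestamps (dates or float day stamps)."""
    if isinstance(d0, (int, float)) and isinstance(d1, (int, float)):
        return float(d1) - float(d0)
    if isinstance(d0, _dt.date) and isinstance(d1, _dt.date):
        return float((d1 - d0).days)
    raise TypeError("dates must both be datetime.date or both numeric day stamps")


@dataclass(frozen=True)
class TemperatureProfile:
    """Vertical water temperature profile on the lake's depth grid."""

    date: object  # datetime.date or float day stamp
    temps: np.ndarray  # degC, one per layer, surface to bottom

    def __post_init__(self) -> None:
        temps = _as_float_array(self.temps, "temps")
        object.__setattr__(self, "temps", temps)
        if np.any(temps <= 0.0) or np.any(temps >= 40.0):
            raise ValueError("temperatures must lie strictly within (0, 40) degC")


@dataclass(frozen=True)
class InflowRecord:
    """One steady inflow: discharge, temperature, solute concentrations.

    ``f_meta`` is the fraction of the discharge routed into the
    metalimnion as a plunging interflow when the lake is stratified;
    the remainder mixes into the epilimnion.
    """

    source_name: str
    date: object
    discharge: float  # m3/d
    temperature: float  # degC
    concentrations: Mapping[str, float]  # compound -> ng/L
    f_meta: float = 0.0

    def __post_init__(self) -> None:
        if self.discharge < 0:
            raise ValueError("discharge must be >= 0")
        if not 0.0 <= self.f_meta <= 1.0:
            raise ValueError("f_meta must lie in [0, 1]")
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class CompoundSpec:
    """A micropollutant with its source class and fate parameters."""

    name: str
    source_class: str  # "wastewater_derived" | "mixed_source"
    molecular_weight: float  # g/mol
    photolysis_k_surface: float = 0.0  # 1/d, lumped direct+indirect at z=0
    true_inflow_pattern: Mapping[str, float] = field(default_factory=dict)
    loq: float = 25.0  # ng/L limit of quantification

    _CLASSES = ("wastewater_derived", "mixed_source")

    def __post_init__(self) -> None:
        if self.source_class not in self._CLASSES:
            raise ValueError(f"source_class must be one of {self._CLASSES}")
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")
        if self.photolysis_k_surface < 0:
            raise ValueError("photolysis_k_surface must be >= 0")
        if self.loq < 0:
            raise ValueError("loq must be >= 0")


@dataclass(frozen=True)
class LakeScenario:
    """Complete configuration of the one-dimensional lake system."""

    geometry: LakeGeometry
    temperature_profiles: tuple[TemperatureProfile, ...]
    inflows: tuple[InflowRecord, ...]
    outflow_discharge: float  # m3/d, withdrawn from the surface layer
    compounds: tuple[CompoundSpec, ...]
    light_attenuation_Kd: float = 0.5  # 1/m
    epilimnion_depth: float = 6.0  # m
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "temperature_profiles", tuple(self.temperature_profiles)
        )
        object.__setattr__(self, "inflows", tuple(self.inflows))
        object.__setattr__(self, "compounds", tuple(self.compounds))
        if len(self.temperature_profiles) < 2:
            raise ValueError("a scenario needs at least two temperature profiles")
        n = self.geometry.n_layers
        for prof in self.temperature_profiles:
            if prof.temps.size != n:
                raise ValueError("temperature profile grid does not match geometry")
        if self.outflow_discharge < 0:
            raise ValueError("outflow_discharge must be >= 0")
        total_in = sum(f.discharge for f in self.inflows)
        if self.outflow_discharge == 0:
            if total_in > 0:
                raise ValueError("closed lake (Q_out = 0) cannot have inflows")
        else:
            imbalance = abs(total_in - self.outflow_discharge) / self.outflow_discharge
            if imbalance > WATER_BALANCE_RTOL:
                raise ValueError(
                    "water balance violated: "
                    f"|sum(Q_in) - Q_out|/Q_out = {imbalance:.2e}"
                )
        if self.light_attenuation_Kd < 0:
            raise ValueError("light_attenuation_Kd must be >= 0")

    @property
    def total_inflow(self) -> float:
        return float(sum(f.discharge for f in self.inflows))

    @property
    def compound_names(self) -> list[str]:
        return [c.name for c in self.compounds]

    def compound(self, name: str) -> CompoundSpec:
        for c in self.compounds:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def flushing_rate(self) -> float:
        """First-order flushing rate Q_out / V in 1/d (well-mixed basis)."""
        return self.outflow_discharge / self.geometry.total_volume
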