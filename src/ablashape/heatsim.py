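"""Axisymmetric heat-conduction simulator with a moving volumetric source.

Models the phantom experiment: a water-tempered polyacrylamide cylinder
(D54 × H90 mm) heated by a microwave probe whose emission region (the
feed zone, centered ``feed_zone_offset`` mm above the tip) is retracted
along the cylinder axis while power is modulated.  The gel records the
maximum temperature it ever reached — its thermochromic ink turns
irreversibly magenta above the 60 °C coagulation threshold — so the
simulator keeps a per-node running maximum and thresholds it into the
ablation mask.

The solver integrates ∂T/∂t = α∇²T + q/(ρc) on a node-centered (r, z)
grid with an explicit conservative finite-volume stencil: symmetry at
r = 0, fixed ambient (water-bath) temperature on the outer boundaries.
The material is isotropic, non-perfusing and has no latent coagulation
enthalpy — the phantom neither perfuses nor coagulates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Callable

import numpy as np

from .profiles import ProbeSchedule, ValidationError, probe_position

__all__ = [
    "ThermalParams",
    "SimulationGrid",
    "MaxTemperatureField",
    "ConfigurationError",
    "source_field",
    "step",
    "simulate",
    "ablation_mask",
    "mirror_mask",
    "cell_volumes",
    "thermal_energy",
]


class ConfigurationError(ValueError):
    """Raised for invalid solver configuration (e.g. unstable dt)."""


@dataclass(frozen=True)
class ThermalParams:
    """Material and source parameters of the phantom model.

    Parameters
    ----------
    diffusivity : float
        Thermal diffusivity α in mm²/s.  Default 0.10, calibrated
        against the reported width ranges (water is 0.143; soft hydrogels
        measure somewhat lower).
    volumetric_heat_capacity : float
        ρc in J/(mm³·K); water-like gel ≈ 4.0e-3.
    efficiency : float
        Net fraction η of the planned generator power deposited as heat
        in the gel.  This folds together generator output (85–90 % of
        planned), antenna coupling/reflection losses and unmodeled
        coolant losses; default 0.30 (calibrated so fixed-probe 60 W
        programs produce 20–30 mm widths).  Per-sample generator
        variability is applied on top of this by the cohort generator.
    source_sigma : float
        Spatial spread (mm) of the isotropic Gaussian deposition around
        the feed-zone center.  Default 2.6 mm (calibrated).
    feed_zone_offset : float
        Distance (mm) from the probe tip to the feed-zone center; 18 mm
        for the probes used.
    cooling_sink : float
        Heat sink (W per mm of shaft) along the water-cooled probe shaft
        above the feed zone; 0 disables it.  Default 0.10 (calibrated):
        shaft cooling is what keeps the proximal head of continuously
        moving programs near zero and produces the proximal indents
        attributed to probe cooling.
    ambient_temp, threshold_temp : float
        Water-bath temperature (37 °C) and irreversible coagulation /
        color-change threshold (60 °C).
    """

    diffusivity: float = 0.10
    volumetric_heat_capacity: float = 4.0e-3
    efficiency: float = 0.30
    source_sigma: float = 2.6
    feed_zone_offset: float = 18.0
    cooling_sink: float = 0.10
    ambient_temp: float = 37.0
    threshold_temp: float = 60.0

    def __post_init__(self) -> None:
        if not self.diffusivity > 0:
            raise ConfigurationError("diffusivity must be > 0")
        if not 0 < self.efficiency <= 1:
            raise ConfigurationError("efficiency must be in (0, 1]")
        if not self.source_sigma > 0:
            raise ConfigurationError("source_sigma must be > 0")
        if self.cooling_sink < 0:
            raise ConfigurationError("cooling_sink must be >= 0")
        if not self.threshold_temp > self.ambient_temp:
            raise ConfigurationError("threshold_temp must exceed ambient_temp")


@dataclass(frozen=True)
class SimulationGrid:
    """Node-centered cylindrical (r, z) grid.

    Defaults mirror the sample container: a capped cylinder D54 × H90 mm
    held in a 37 °C bath, i.e. radial extent 27 mm with fixed-temperature
    outer boundaries.  ``dt=None`` auto-selects 0.9× the positivity
    (maximum-principle) limit of the explicit stencil,
    ``1 / (2α(2/dr² + 1/dz²))`` — the axis cell carries a doubled radial
    coefficient, so this is slightly stricter than the plain 2-D FTCS
    bound.
    """

    radial_extent: float = 27.0
    axial_extent: float = 90.0
    dr: float = 0.5
    dz: float = 0.5
    dt: float | None = None

    def __post_init__(self) -> None:
        if min(self.radial_extent, self.axial_extent, self.dr, self.dz) <= 0:
            raise ConfigurationError("grid extents and spacings must be positive")

    @property
    def nr(self) -> int:
        return int(round(self.radial_extent / self.dr)) + 1

    @property
    def nz(self) -> int:
        return int(round(self.axial_extent / self.dz)) + 1

    @property
    def r(self) -> np.ndarray:
        return np.arange(self.nr) * self.dr

    @property
    def z(self) -> np.ndarray:
        return np.arange(self.nz) * self.dz

    def stability_limit(self, diffusivity: float) -> float:
        """Largest positivity-preserving dt (s) for a given α."""
        return 1.0 / (2.0 * diffusivity * (2.0 / self.dr**2 + 1.0 / self.dz**2))

    def resolve_dt(self, diffusivity: float) -> float:
        """Auto dt (0.9× the limit) or the user dt, validated."""
        limit = self.stability_limit(diffusivity)
        if self.dt is None:
            return 0.9 * limit
        if self.dt > limit * (1 + 1e-12):
            raise ConfigurationError(
                f"dt={self.dt} exceeds the stability limit {limit:.4g} s"
            )
        return self.dt


@dataclass
class MaxTemperatureField:
    """Per-node maximum temperature (°C) over a simulation run."""

    values: np.ndarray  # (nr, nz)
    grid: SimulationGrid
    params: ThermalParams
    trajectory_start_z: float  # grid z (mm) of the profile starting point
    trajectory_length: float  # mm


def cell_volumes(grid: SimulationGrid) -> np.ndarray:
    """Finite-volume cell volumes (mm³) per node, shape (nr, 1).

    The axis node owns a cylinder of radius dr/2; interior nodes own
    annuli 2π·r·dr; the outermost node a half annulus.  Broadcastable
    against (nr, nz) fields.
    """
    r = grid.r
    vol = 2.0 * np.pi * r * grid.dr * grid.dz
    vol[0] = np.pi * (grid.dr / 2.0) ** 2 * grid.dz
    vol[-1] = 2.0 * np.pi * r[-1] * (grid.dr / 2.0) * grid.dz
    return vol[:, None]


def thermal_energy(T: np.ndarray, params: ThermalParams, grid: SimulationGrid) -> float:
    """Thermal energy (J) stored above ambient, Σ ρc·V·(T − T_amb)."""
    return float(
        np.sum((T - params.ambient_temp) * cell_volumes(grid))
        * params.volumetric_heat_capacity
    )


@lru_cache(maxsize=16)
def _radial_coeffs(nr: int, dr: float) -> tuple[np.ndarray, np.ndarray]:
    """Conservative radial stencil weights (a_plus, a_minus)/dr² per node."""
    i = np.arange(1, nr - 1, dtype=float)
    a_plus = (i + 0.5) / i / dr**2
    a_minus = (i - 0.5) / i / dr**2
    return a_plus, a_minus


def source_field(
    probe_tip_z: float,
    power: float,
    params: ThermalParams,
    grid: SimulationGrid,
) -> np.ndarray:
    """Volumetric power deposition (W/mm³) on the grid for one probe pose.

    An isotropic Gaussian of spread ``source_sigma`` centered on the axis
    at the feed-zone center (``probe_tip_z + feed_zone_offset``),
    analytically normalized so its full-space integral is η×power.  When
    ``cooling_sink`` > 0 a uniform negative line density is applied to
    the axis cells along the shaft above the feed zone.
    """
    z_src = probe_tip_z + params.feed_zone_offset
    if not 0.0 <= z_src <= grid.axial_extent:
        raise ValidationError(
            f"source center z={z_src} mm outside grid [0, {grid.axial_extent}]"
        )
    q = np.zeros((grid.nr, grid.nz))
    if power > 0:
        sig = params.source_sigma
        amp = params.efficiency * power / ((2.0 * np.pi) ** 1.5 * sig**3)
        radial = np.exp(-(grid.r**2) / (2.0 * sig**2))
        axial = np.exp(-((grid.z - z_src) ** 2) / (2.0 * sig**2))
        q = amp * radial[:, None] * axial[None, :]
    if params.cooling_sink > 0:
        axis_cell_area = np.pi * (grid.dr / 2.0) ** 2
        shaft = grid.z >= z_src
        q[0, shaft] -= params.cooling_sink / axis_cell_area
    return q


def step(
    T: np.ndarray,
    deposition: np.ndarray,
    params: ThermalParams,
    grid: SimulationGrid,
    dt: float | None = None,
) -> np.ndarray:
    """One explicit time step of the conduction equation.

    Returns the updated field; ``T`` is not modified.  Axis symmetry at
    r = 0; Dirichlet ambient at r = R and both z boundaries (water bath).
    """
    if dt is None:
        dt = grid.resolve_dt(params.diffusivity)
    elif dt > grid.stability_limit(params.diffusivity) * (1 + 1e-12):
        raise ConfigurationError("dt exceeds the stability limit")
    alpha = params.diffusivity
    lap = np.zeros_like(T)
    # radial part (conservative cylindrical stencil)
    a_plus, a_minus = _radial_coeffs(grid.nr, grid.dr)
    lap[1:-1, :] += a_plus[:, None] * (T[2:, :] - T[1:-1, :]) - a_minus[:, None] * (
        T[1:-1, :] - T[:-2, :]
    )
    lap[0, :] += 4.0 * (T[1, :] - T[0, :]) / grid.dr**2
    # axial part
    lap[:, 1:-1] += (T[:, 2:] - 2.0 * T[:, 1:-1] + T[:, :-2]) / grid.dz**2
    Tn = T + dt * (alpha * lap + deposition / params.volumetric_heat_capacity)
    Tn[-1, :] = params.ambient_temp
    Tn[:, 0] = params.ambient_temp
    Tn[:, -1] = params.ambient_temp
    return Tn


def simulate(
    schedule: ProbeSchedule,
    power_of_t: Callable[[float], float],
    params: ThermalParams | None = None,
    grid: SimulationGrid | None = None,
    trajectory_start_z: float = 20.0,
) -> MaxTemperatureField:
    """Run a full program and return the maximum-temperature field.

    The source center follows ``probe_position(schedule, t)`` measured
    from ``trajectory_start_z`` (grid mm from the distal boundary) toward
    the entry; power follows ``power_of_t``.  Both are sampled at each
    step's midpoint.  The per-node running maximum is recorded — the
    quantity the irreversible thermochromic gel stores.
    """
    params = params or ThermalParams()
    grid = grid or SimulationGrid()
    if schedule.total_duration <= 0:
        raise ValidationError("schedule duration must be positive")
    z_lo = trajectory_start_z
    z_hi = trajectory_start_z + schedule.total_distance
    tip_lo = z_lo - params.feed_zone_offset
    if tip_lo < 0 or z_hi > grid.axial_extent:
        raise ValidationError(
            "probe trajectory exits the grid: tip range "
            f"[{tip_lo}, {z_hi - params.feed_zone_offset}] mm, source max {z_hi} mm"
        )
    dt = grid.resolve_dt(params.diffusivity)
    T = np.full((grid.nr, grid.nz), params.ambient_temp, dtype=float)
    maxT = T.copy()

    total = schedule.total_duration
    sig = params.source_sigma
    radial = np.exp(-(grid.r**2) / (2.0 * sig**2))[:, None]
    t = 0.0
    last_pose: tuple[float, float] | None = None
    q = np.zeros_like(T)
    while t < total - 1e-9:
        h = min(dt, total - t)
        tm = t + h / 2.0
        pos = float(probe_position(schedule, min(tm, total)))
        pw = float(power_of_t(min(tm, total)))
        pose = (pos, pw)
        if pose != last_pose:
            z_src = z_lo + pos
            if pw > 0:
                amp = params.efficiency * pw / ((2.0 * np.pi) ** 1.5 * sig**3)
                axial = np.exp(-((grid.z - z_src) ** 2) / (2.0 * sig**2))
                q = amp * radial * axial[None, :]
            else:
                q = np.zeros_like(T)
            if params.cooling_sink > 0:
                q = q.copy() if pw > 0 else q
                axis_cell_area = np.pi * (grid.dr / 2.0) ** 2
                q[0, grid.z >= z_src] -= params.cooling_sink / axis_cell_area
            last_pose = pose
        T = step(T, q, params, grid, dt=h)
        np.maximum(maxT, T, out=maxT)
        t += h
    return MaxTemperatureField(
        values=maxT,
        grid=grid,
        params=params,
        trajectory_start_z=trajectory_start_z,
        trajectory_length=schedule.total_distance,
    )


def ablation_mask(
    maxfield: MaxTemperatureField, threshold: float | None = None
) -> np.ndarray:
    """Boolean (nr, nz) mask of nodes whose maximum reached ``threshold``.

    ``threshold`` defaults to the params' coagulation temperature (60 °C).
    """
    if threshold is None:
        threshold = maxfield.params.threshold_temp
    return maxfield.values >= threshold


def mirror_mask(half_mask: np.ndarray) -> np.ndarray:
    """Mirror an (nr, nz) half-plane mask across the axis → (2·nr−1, nz).

    Row ``nr − 1`` of the result is the probe axis; rows run from −R to
    +R laterally.
    """
    return np.concatenate([half_mask[:0:-1, :], half_mask], axis=0)
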