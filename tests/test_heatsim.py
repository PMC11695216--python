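"""Heat solver: stencil correctness, conservation, analytic oracle."""

import numpy as np
import pytest

from ablashape import heatsim
from ablashape.heatsim import (
    ConfigurationError,
    MaxTemperatureField,
    SimulationGrid,
    ThermalParams,
    ablation_mask,
    cell_volumes,
    mirror_mask,
    simulate,
    source_field,
    step,
    thermal_energy,
)
from ablashape.profiles import (
    AblationInterval,
    AblationProfile,
    ValidationError,
    discretize,
    profile_power,
)


def static_schedule(duration):
    prof = AblationProfile(
        "static", [AblationInterval(60, duration, 0)], "OVAL"
    )
    return discretize(prof)


class TestSourceField:
    def test_zero_power_all_zero(self, default_params):
        grid = SimulationGrid()
        q = source_field(20.0, 0.0, ThermalParams(cooling_sink=0.0), grid)
        assert not q.any()

    def test_integral_matches_deposited_power(self):
        """Discrete quadrature of the deposition recovers η×P within 1%."""
        grid = SimulationGrid(dr=0.25, dz=0.25)
        params = ThermalParams(cooling_sink=0.0)
        q = source_field(27.0, 60.0, params, grid)  # source center at 45 mm
        integral = float(np.sum(q * cell_volumes(grid)))
        assert integral == pytest.approx(params.efficiency * 60.0, rel=0.01)

    def test_no_sink_nonnegative(self):
        grid = SimulationGrid()
        q = source_field(20.0, 60.0, ThermalParams(cooling_sink=0.0), grid)
        assert np.all(q >= 0)

    def test_sink_negative_only_along_shaft(self):
        grid = SimulationGrid()
        params = ThermalParams(cooling_sink=0.5)
        q = source_field(10.0, 60.0, params, grid)
        neg_rows, neg_cols = np.nonzero(q < 0)
        assert np.all(neg_rows == 0)  # only on-axis cells
        assert np.all(grid.z[neg_cols] >= 10.0 + params.feed_zone_offset)

    def test_source_outside_grid_rejected(self):
        grid = SimulationGrid()
        with pytest.raises(ValidationError):
            source_field(80.0, 60.0, ThermalParams(), grid)  # center at 98 mm


class TestStep:
    def test_uniform_field_unchanged_without_source(self, default_params, small_grid):
        T = np.full((small_grid.nr, small_grid.nz), default_params.ambient_temp)
        Tn = step(T, np.zeros_like(T), default_params, small_grid)
        np.testing.assert_allclose(Tn, T)

    def test_impulse_conserves_interior_energy(self, default_params):
        """Before boundary contact the FV stencil conserves thermal energy."""
        grid = SimulationGrid(radial_extent=25, axial_extent=50, dr=0.5, dz=0.5)
        T = np.full((grid.nr, grid.nz), default_params.ambient_temp)
        T[0, grid.nz // 2] += 500.0
        e0 = thermal_energy(T, default_params, grid)
        for _ in range(50):
            T = step(T, np.zeros_like(T), default_params, grid)
        e1 = thermal_energy(T, default_params, grid)
        assert e1 == pytest.approx(e0, rel=1e-6)

    def test_maximum_principle_interior_max_decays(self, default_params, small_grid):
        rng = np.random.default_rng(0)
        T = np.full((small_grid.nr, small_grid.nz), default_params.ambient_temp)
        T[2:-2, 2:-2] += rng.uniform(10, 60, T[2:-2, 2:-2].shape)
        prev = T.max()
        for _ in range(20):
            T = step(T, np.zeros_like(T), default_params, small_grid)
            assert T.max() < prev
            prev = T.max()

    def test_unstable_dt_rejected(self, default_params, small_grid):
        T = np.full((small_grid.nr, small_grid.nz), 37.0)
        bad = 2.0 * small_grid.stability_limit(default_params.diffusivity)
        with pytest.raises(ConfigurationError):
            step(T, np.zeros_like(T), default_params, small_grid, dt=bad)
        with pytest.raises(ConfigurationError):
            SimulationGrid(dt=bad).resolve_dt(default_params.diffusivity)


class TestSimulate:
    def test_zero_power_stays_ambient(self, default_params):
        grid = SimulationGrid(radial_extent=20, axial_extent=60, dr=1.0, dz=1.0)
        field = simulate(static_schedule(30.0), lambda t: 0.0, default_params, grid)
        np.testing.assert_allclose(field.values, default_params.ambient_temp)

    def test_short_pulse_matches_point_source_solution(self):
        """Brief compact pulse vs the instantaneous point-source solution.

        T(r,t) − T₀ = E/(ρc (4παt')^{3/2}) exp(−r²/(4αt')) in an
        unbounded medium, with t' = t + σ²/(2α) absorbing the finite
        source spread (the Green's solution started from the actual
        Gaussian deposit); evaluated when the diffusion length dwarfs
        the pulse duration's travel.
        """
        err = greens_function_error(dr=0.25)
        assert err < 0.05

    def test_static_source_symmetric_about_source_plane(self):
        params = ThermalParams(feed_zone_offset=0.0, cooling_sink=0.0)
        grid = SimulationGrid(radial_extent=20, axial_extent=80, dr=1.0, dz=1.0)
        field = simulate(
            static_schedule(60.0), lambda t: 60.0, params, grid, trajectory_start_z=40.0
        )
        v = field.values
        j = int(round(40.0 / grid.dz))
        k = min(j, v.shape[1] - 1 - j)
        np.testing.assert_allclose(
            v[:, j - k : j], v[:, j + k : j : -1], rtol=1e-6, atol=1e-6
        )

    def test_trajectory_exiting_grid_rejected(self, default_params):
        grid = SimulationGrid(radial_extent=20, axial_extent=60, dr=1.0, dz=1.0)
        with pytest.raises(ValidationError):
            # source center beyond the proximal boundary
            simulate(static_schedule(10.0), lambda t: 60.0, default_params, grid,
                     trajectory_start_z=70.0)
        with pytest.raises(ValidationError):
            # probe tip (18 mm below the source) pokes out distally
            simulate(static_schedule(10.0), lambda t: 60.0, default_params, grid,
                     trajectory_start_z=10.0)

    def test_max_field_at_least_ambient_and_bounded_by_history(self, default_params):
        grid = SimulationGrid(radial_extent=20, axial_extent=60, dr=1.0, dz=1.0)
        field = simulate(static_schedule(20.0), lambda t: 60.0, default_params, grid)
        assert np.all(field.values >= default_params.ambient_temp)
        assert field.values.max() > default_params.threshold_temp


def greens_function_error(dr: float, t_obs: float = 40.0, pulse: float = 2.0) -> float:
    """L∞ relative error of the solver against the point-source solution."""
    params = ThermalParams(
        diffusivity=0.143,
        efficiency=1.0,
        source_sigma=1.0,
        feed_zone_offset=0.0,
        cooling_sink=0.0,
    )
    grid = SimulationGrid(radial_extent=27.0, axial_extent=90.0, dr=dr, dz=dr)
    prof = AblationProfile(
        "pulse", [AblationInterval(5.0, pulse, 0), AblationInterval(1e-9, t_obs - pulse, 0)], "OVAL"
    )
    # power_of_t: brief 5 W pulse then off
    field_t = _final_temperature(prof, params, grid, z_src=45.0)
    E = params.efficiency * 5.0 * pulse
    alpha, rhoc = params.diffusivity, params.volumetric_heat_capacity
    t_eff = t_obs - pulse / 2.0  # centroid of the emission interval
    s2 = 2.0 * alpha * t_eff + params.source_sigma**2  # Gaussian initial spread
    rr, zz = np.meshgrid(grid.r, grid.z - 45.0, indexing="ij")
    d2 = rr**2 + zz**2
    analytic = params.ambient_temp + E / (rhoc * (2.0 * np.pi * s2) ** 1.5) * np.exp(
        -d2 / (2.0 * s2)
    )
    peak = analytic.max() - params.ambient_temp
    sel = analytic - params.ambient_temp > 0.05 * peak
    rel = np.abs(field_t - analytic)[sel] / peak
    return float(rel.max())


def _final_temperature(prof, params, grid, z_src):
    """Run the stepper and return the final (not max) field."""
    sched = discretize(prof)
    power = lambda t: 5.0 if t <= 2.0 else 0.0
    dt = grid.resolve_dt(params.diffusivity)
    T = np.full((grid.nr, grid.nz), params.ambient_temp)
    t = 0.0
    total = sched.total_duration
    while t < total - 1e-9:
        h = min(dt, total - t)
        tm = t + h / 2.0
        q = heatsim.source_field(z_src, power(tm), params, grid)
        T = step(T, q, params, grid, dt=h)
        t += h
    return T


class TestAblationMask:
    def test_uniform_ambient_empty(self, default_params):
        grid = SimulationGrid(radial_extent=10, axial_extent=20, dr=1, dz=1)
        f = MaxTemperatureField(
            np.full((grid.nr, grid.nz), 37.0), grid, default_params, 0.0, 0.0
        )
        assert not ablation_mask(f).any()

    def test_threshold_at_ambient_full(self, default_params):
        grid = SimulationGrid(radial_extent=10, axial_extent=20, dr=1, dz=1)
        f = MaxTemperatureField(
            np.full((grid.nr, grid.nz), 37.0), grid, default_params, 0.0, 0.0
        )
        assert ablation_mask(f, threshold=37.0).all()

    def test_area_monotone_in_energy(self, default_params):
        """More delivered energy never shrinks the ablated area."""
        grid = SimulationGrid(radial_extent=20, axial_extent=60, dr=1.0, dz=1.0)
        areas = []
        for dur in (30.0, 60.0, 120.0):
            field = simulate(static_schedule(dur), lambda t: 60.0, default_params, grid)
            areas.append(ablation_mask(field).sum())
        assert areas == sorted(areas)
        assert areas[0] > 0

    def test_mirror_shape(self):
        half = np.zeros((5, 7), dtype=bool)
        half[0:2, 3] = True
        full = mirror_mask(half)
        assert full.shape == (9, 7)
        np.testing.assert_array_equal(full, full[::-1, :])
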