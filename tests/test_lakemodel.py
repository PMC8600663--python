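"""Fate model: density, diffusivity inversion, insertion, photolysis,
mass balance, and skill metrics."""

import dataclasses

import numpy as np
import pytest

from lakeomp import lakemodel, synthetic
from lakeomp.lakemodel import (
    KZ_MAX,
    attenuation_band_mean,
    compute_inflow_insertion,
    density_from_temperature,
    diffuse_temperature,
    estimate_vertical_diffusivity,
    evaluate_profiles,
    flushing_rate_constant,
    nse,
    pbias,
    photolysis_rate_profile,
    simulate_lake,
    steady_state_concentrations,
    stratified_kz,
)
from lakeomp.scenario import TemperatureProfile

from conftest import uniform_inflow_scenario


class TestDensity:
    def test_maximum_near_four_degrees(self):
        assert density_from_temperature(4.0) > density_from_temperature(10.0)
        assert density_from_temperature(4.0) == pytest.approx(999.97, abs=0.1)

    def test_monotone_decreasing_above_maximum(self):
        t = np.linspace(4.0, 30.0, 100)
        rho = density_from_temperature(t)
        assert np.all(np.diff(rho) < 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            density_from_temperature(-1.0)
        with pytest.raises(ValueError):
            density_from_temperature(45.0)


class TestDiffusivityEstimate:
    def test_recovers_constant_kz_within_15_percent(self, geometry):
        # start from a smooth mid-season profile (sharp onset relaxed for
        # 10 d) so the two-profile heat budget time-averaging is valid
        z = geometry.depth_grid
        sharp = TemperatureProfile(
            date=0.0, temps=8 + 17 / (1 + np.exp(0.8 * (z - 7)))
        )
        t0 = diffuse_temperature(sharp, geometry, 5.0, 10.0)
        t0 = TemperatureProfile(date=0.0, temps=t0.temps)
        t1 = diffuse_temperature(t0, geometry, 5.0, 7.0)
        est = estimate_vertical_diffusivity(t0, t1, geometry)
        usable = np.array([f == "" for f in est.flags])
        assert usable.sum() >= 10
        np.testing.assert_allclose(est.kz[usable], 5.0, rtol=0.15)

    def test_no_heat_change_gives_zero(self, geometry):
        z = geometry.depth_grid
        temps = 8 + 17 / (1 + np.exp(0.8 * (z - 7)))
        t0 = TemperatureProfile(date=0.0, temps=temps)
        t1 = TemperatureProfile(date=7.0, temps=temps.copy())
        est = estimate_vertical_diffusivity(t0, t1, geometry)
        unflagged = np.array([f == "" for f in est.flags])
        assert unflagged.any()
        np.testing.assert_array_equal(est.kz[unflagged], 0.0)

    def test_uniform_temperature_all_indeterminate(self, geometry):
        t0 = TemperatureProfile(date=0.0, temps=np.full(geometry.n_layers, 12.0))
        t1 = TemperatureProfile(date=7.0, temps=np.full(geometry.n_layers, 12.5))
        est = estimate_vertical_diffusivity(t0, t1, geometry)
        assert all(f == "indeterminate" for f in est.flags)
        np.testing.assert_array_equal(est.kz, KZ_MAX)

    def test_identical_dates_rejected(self, geometry):
        t = TemperatureProfile(date=0.0, temps=np.full(geometry.n_layers, 12.0))
        with pytest.raises(ValueError, match="later"):
            estimate_vertical_diffusivity(t, t, geometry)


class TestInflowInsertion:
    def test_metalimnetic_routing(self, scenario):
        geom = scenario.geometry
        july = scenario.temperature_profiles[0]
        t7 = float(july.temps[geom.layer_index(7.0)])
        inflow = dataclasses.replace(
            scenario.inflows[0], temperature=t7, f_meta=0.3
        )
        plan = compute_inflow_insertion(inflow, july, geom)
        assert plan.total_discharge == pytest.approx(inflow.discharge)
        assert plan.insertion_layer is not None
        z_ins = geom.depth_grid[plan.insertion_layer]
        assert 6.0 <= z_ins <= 8.0
        assert plan.layer_inflow[plan.insertion_layer] >= 0.3 * inflow.discharge
        epi = geom.depth_grid <= scenario.epilimnion_depth
        assert plan.layer_inflow[epi].sum() == pytest.approx(
            0.7 * inflow.discharge
        )

    def test_f_meta_zero_all_epilimnion(self, scenario):
        geom = scenario.geometry
        inflow = dataclasses.replace(scenario.inflows[0], f_meta=0.0)
        plan = compute_inflow_insertion(
            inflow, scenario.temperature_profiles[0], geom
        )
        epi = geom.depth_grid <= scenario.epilimnion_depth
        assert plan.layer_inflow[~epi].sum() == 0.0

    def test_unstratified_overrides_f_meta(self, scenario):
        geom = scenario.geometry
        uniform = TemperatureProfile(
            date=0.0, temps=np.full(geom.n_layers, 12.0)
        )
        inflow = dataclasses.replace(scenario.inflows[0], f_meta=0.4)
        plan = compute_inflow_insertion(inflow, uniform, geom)
        epi = geom.depth_grid <= scenario.epilimnion_depth
        assert plan.layer_inflow[~epi].sum() == 0.0
        assert plan.insertion_layer is None

    def test_continuity_to_outlet(self, scenario):
        geom = scenario.geometry
        plan = compute_inflow_insertion(
            scenario.inflows[0], scenario.temperature_profiles[0], geom
        )
        # everything inserted below the surface layer crosses the top interface
        assert plan.upward_flow[0] == pytest.approx(
            plan.layer_inflow[1:].sum()
        )


class TestPhotolysis:
    def test_band_mean_closed_form(self):
        expected = (np.exp(-0.5) - np.exp(-1.0)) / 0.5
        assert attenuation_band_mean(0.5, 1.0, 2.0) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(0.4773, abs=1e-3)

    def test_no_attenuation_limit(self, geometry):
        prof = photolysis_rate_profile(0.1, 0.0, 6.0, geometry)
        epi = geometry.depth_grid <= 6.0
        np.testing.assert_allclose(prof.k_photo[epi], 0.1)

    def test_zero_below_epilimnion(self, geometry):
        prof = photolysis_rate_profile(0.1, 0.5, 6.0, geometry)
        deep = geometry.depth_grid > 6.0
        np.testing.assert_array_equal(prof.k_photo[deep], 0.0)
        assert np.all(np.diff(prof.k_photo[~deep]) < 0)  # attenuates downward


class TestSimulateLake:
    def test_conservative_steady_state_uniform(self, scenario):
        sc = uniform_inflow_scenario(scenario, conc=100.0)
        sim = simulate_lake(
            sc, 5.0, duration=10 * sc.geometry.total_volume / sc.outflow_discharge
        )
        np.testing.assert_allclose(sim.final_profile("tracer"), 100.0, rtol=1e-3)

    def test_well_mixed_reactor_closed_form(self, scenario):
        geom = scenario.geometry
        V, Q = geom.total_volume, scenario.outflow_discharge
        for kvq in (0.5, 5.0):
            sc = uniform_inflow_scenario(
                scenario, conc=100.0, k_photo=kvq * Q / V,
                epilimnion_depth=100.0, kd=0.0,
            )
            sim = simulate_lake(
                sc, KZ_MAX, with_photolysis=True, duration=8 * V / Q
            )
            np.testing.assert_allclose(
                sim.final_profile("tracer"), 100.0 / (1 + kvq), rtol=0.01
            )

    def test_closed_lake_conserves_mass(self, scenario):
        sc = uniform_inflow_scenario(scenario, conc=100.0)
        closed = dataclasses.replace(sc, inflows=(), outflow_discharge=0.0)
        c0 = {"tracer": np.linspace(200.0, 10.0, sc.geometry.n_layers)}
        sim = simulate_lake(closed, 5.0, duration=100.0, initial_ngL=c0)
        vols = sc.geometry.layer_volumes
        m0 = (c0["tracer"] * vols).sum()
        m1 = (sim.final_profile("tracer") * vols).sum()
        assert abs(m1 - m0) / m0 <= 1e-3

    def test_diffusion_smooths_closed_system(self, scenario):
        sc = uniform_inflow_scenario(scenario, conc=100.0)
        closed = dataclasses.replace(sc, inflows=(), outflow_discharge=0.0)
        c0 = {"tracer": np.linspace(200.0, 10.0, sc.geometry.n_layers)}
        sim = simulate_lake(
            closed, 5.0, duration=60.0, initial_ngL=c0,
            output_times=np.linspace(0, 60, 7),
        )
        ranges = np.ptp(sim.concentrations["tracer"], axis=1)
        assert np.all(np.diff(ranges) <= 1e-9)

    def test_flushing_mass_balance_closes(self, scenario):
        sc = uniform_inflow_scenario(scenario, conc=100.0)
        times = np.linspace(0.0, 60.0, 241)
        sim = simulate_lake(sc, 5.0, duration=60.0, output_times=times)
        vols = sc.geometry.layer_volumes
        conc = sim.concentrations["tracer"]
        storage = (conc * vols).sum(axis=1)
        mass_in = 60.0 * sum(
            f.discharge * f.concentrations["tracer"] for f in sc.inflows
        )
        outflow_rate = sc.outflow_discharge * conc[:, 0]
        mass_out = np.trapezoid(outflow_rate, times)
        assert (storage[-1] - storage[0]) == pytest.approx(
            mass_in - mass_out, rel=5e-3
        )

    def test_photolysis_monotonically_lowers_epilimnion(self, scenario):
        geom = scenario.geometry
        epi_means = []
        for k in (0.0, 0.02, 0.1):
            sc = uniform_inflow_scenario(scenario, conc=100.0, k_photo=k)
            css = steady_state_concentrations(sc, 5.0, with_photolysis=True)
            epi = geom.depth_grid <= sc.epilimnion_depth
            epi_means.append(css["tracer"][epi].mean())
        assert epi_means[0] > epi_means[1] > epi_means[2]

    def test_tolerance_stability(self, scenario):
        sc = uniform_inflow_scenario(scenario, conc=100.0)
        a = simulate_lake(sc, 5.0, duration=30.0, rtol=1e-6)
        b = simulate_lake(sc, 5.0, duration=30.0, rtol=5e-7)
        np.testing.assert_allclose(
            a.final_profile("tracer"), b.final_profile("tracer"), rtol=1e-3
        )


class TestFlushingRate:
    def test_four_per_year(self):
        assert flushing_rate_constant(4.0) == pytest.approx(0.011, abs=5e-4)

    def test_scenario_consistency(self, scenario):
        assert scenario.flushing_rate == pytest.approx(
            flushing_rate_constant(4.0), rel=1e-9
        )


class TestMetrics:
    def test_pbias_hand_values(self):
        assert pbias([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert pbias([10.0, 10.0], [11.0, 11.0]) == pytest.approx(-10.0, abs=1e-9)

    def test_pbias_sign_convention(self):
        # a model that overestimates (unmodeled loss) must give PBIAS < 0
        assert pbias([5.0, 5.0, 5.0], [6.0, 7.0, 8.0]) < 0

    def test_pbias_undefined(self):
        with pytest.raises(ValueError, match="sum of observations"):
            pbias([0.0, 0.0], [1.0, 1.0])

    def test_nse_hand_values(self):
        assert nse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0
        assert nse([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == 0.0
        assert nse([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(
            0.5, abs=1e-9
        )

    def test_nse_undefined(self):
        with pytest.raises(ValueError, match="zero variance"):
            nse([2.0, 2.0], [1.0, 3.0])

    def test_self_recovery_on_noisy_truth(self, small_scenario):
        kz = stratified_kz(
            small_scenario.geometry, small_scenario.temperature_profiles[0]
        )
        obs = synthetic.generate_observations(
            small_scenario, noise_cv=0.05, seed=21, kz=kz
        )
        sim = simulate_lake(small_scenario, kz, duration=60.0)
        metrics = evaluate_profiles(obs, sim)
        assert len(metrics) == len(small_scenario.compounds)
        assert (metrics["nse"] >= 0.9).all()
        assert (metrics["pbias_pct"].abs() <= 5.0).all()
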