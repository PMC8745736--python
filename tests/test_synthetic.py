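"""Generators: reproducibility, exact closed forms, fit round trips."""

import numpy as np
import pytest

from petkinlab import kinetics as kin
from petkinlab import stability as stab
from petkinlab import synthetic as syn


class TestReproducibility:
    def test_seeded_generation_is_bit_identical(self):
        gt = syn.KineticGroundTruth()
        cfg = syn.SimulationConfig(seed=42, noise_sd_rel=0.05)
        a = syn.simulate_turbidity(gt, cfg, 0.02)
        b = syn.simulate_turbidity(gt, cfg, 0.02)
        np.testing.assert_array_equal(a.od600, b.od600)
        m1 = syn.simulate_melt(syn.MeltGroundTruth(), cfg)
        m2 = syn.simulate_melt(syn.MeltGroundTruth(), cfg)
        np.testing.assert_array_equal(m1.signal, m2.signal)

    def test_different_seeds_differ(self):
        gt = syn.KineticGroundTruth()
        a = syn.simulate_turbidity(gt, syn.SimulationConfig(seed=1,
                                   noise_sd_rel=0.05), 0.02)
        b = syn.simulate_turbidity(gt, syn.SimulationConfig(seed=2,
                                   noise_sd_rel=0.05), 0.02)
        assert not np.array_equal(a.od600, b.od600)


class TestTurbidityForwardModel:
    def test_closed_form_at_ten_minutes_past_lag(self, noise_free_cfg):
        # v = 0.076*37.95*0.04/(1+37.95*0.04) = 0.04582 1/min, so tau/tau0
        # ten minutes after the lag is (1 - 0.4582)^2 = 0.2936
        gt = syn.KineticGroundTruth(k_tau=0.076, K_A=37.95)
        trace = syn.simulate_turbidity(gt, noise_free_cfg, 0.04)
        series = kin.compute_relative_turbidity(trace)
        t_query = noise_free_cfg.lag_time + 10.0
        idx = int(np.argmin(np.abs(series.times - t_query)))
        v = 0.076 * 37.95 * 0.04 / (1 + 37.95 * 0.04)
        assert series.tau_rel[idx] == pytest.approx((1 - 10 * v) ** 2,
                                                    rel=1e-12)
        assert series.tau_rel[idx] == pytest.approx(0.2936, abs=2e-4)

    def test_zero_enzyme_means_no_degradation(self, noise_free_cfg):
        trace = syn.simulate_turbidity(syn.KineticGroundTruth(),
                                       noise_free_cfg, 0.0)
        series = kin.compute_relative_turbidity(trace)
        assert np.all(series.tau_rel == 1.0)

    def test_langmuir_saturation_limit(self):
        gt = syn.KineticGroundTruth(k_tau=0.076, K_A=37.95)
        assert gt.rate_at(1e9) == pytest.approx(0.076, rel=1e-6)

    def test_negative_concentration_rejected_by_name(self, noise_free_cfg):
        with pytest.raises(ValueError, match="e_conc"):
            syn.simulate_turbidity(syn.KineticGroundTruth(),
                                   noise_free_cfg, -0.01)


class TestDecayForwardModel:
    @pytest.mark.parametrize("k,t,expected", [
        (2.46, 1 / 3, 0.440),   # ~40% activity after 20 min
        (8.40, 1 / 3, 0.061),   # almost inactive after 20 min
    ])
    def test_published_constants_reproduce_residual_activity(self, k, t,
                                                             expected):
        gt = syn.DecayGroundTruth(k_in=k)
        series = syn.simulate_decay(gt, np.array([0.0, t]))
        assert series.activity[1] == pytest.approx(expected, abs=5e-4)

    def test_zero_rate_constant_activity(self):
        series = syn.simulate_decay(syn.DecayGroundTruth(k_in=0.0),
                                    np.array([0.0, 1.0, 5.0]))
        assert np.all(series.activity == 1.0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_decay(syn.DecayGroundTruth(), np.array([-1.0, 0.0]))


class TestMeltForwardModel:
    def test_step_limit_for_narrow_transition(self, noise_free_cfg):
        gt = syn.MeltGroundTruth(t_m=55.3, transition_width=1e-6)
        curve = syn.simulate_melt(gt, noise_free_cfg)
        below = curve.signal[curve.temperatures < 55.29]
        above = curve.signal[curve.temperatures > 55.31]
        assert np.allclose(below, 0.0, atol=1e-9)
        assert np.allclose(above, -1.0, atol=1e-9)


class TestGroundTruthRoundTrips:
    def test_noise_free_langmuir_round_trip_within_one_percent(
            self, noise_free_cfg):
        gt = syn.KineticGroundTruth(k_tau=0.124, K_A=75.38)
        points = []
        for e in gt.enzyme_concs:
            trace = syn.simulate_turbidity(gt, noise_free_cfg, e)
            series = kin.compute_relative_turbidity(trace)
            points.append(kin.estimate_initial_rate(series))
        res = kin.fit_langmuir_kinetics(points)
        assert res.k_tau == pytest.approx(gt.k_tau, rel=0.01)
        assert res.K_A == pytest.approx(gt.K_A, rel=0.01)

    def test_noisy_round_trip_within_three_standard_errors(self):
        # 5% relative noise, triplicate measurements per concentration
        gt = syn.KineticGroundTruth()
        cfg = syn.SimulationConfig(seed=99, noise_sd_rel=0.05)
        points = syn.simulate_rate_dataset(gt, cfg, n_replicates=3)
        res = kin.fit_langmuir_kinetics(points, use_sd_weights=True)
        assert abs(res.k_tau - gt.k_tau) <= 3 * res.k_tau_se
        assert abs(res.K_A - gt.K_A) <= 3 * res.K_A_se

    def test_melt_and_decay_round_trips(self, noise_free_cfg):
        melt_fit = stab.fit_melting_curve(
            syn.simulate_melt(syn.MeltGroundTruth(t_m=47.5),
                              noise_free_cfg))
        assert melt_fit.t_m == pytest.approx(47.5, rel=0.01)
        decay_fit = stab.fit_inactivation_decay(
            syn.simulate_decay(syn.DecayGroundTruth(k_in=0.079),
                               np.array([0, 2, 5, 10, 20, 40.0])))
        assert decay_fit.k_in == pytest.approx(0.079, rel=0.01)


class TestPlateGenerator:
    def test_noise_free_parent_wells_score_100(self):
        layout = syn.default_plate_layout()
        cfg = syn.SimulationConfig(seed=0, noise_sd_rel=0.0)
        spec = {w: 1.0 for w in layout.wells_with_role("sample")}
        reading = syn.simulate_plate(layout, spec, cfg)
        from petkinlab.screening import score_plate
        for s in score_plate(reading):
            assert s.activity_pct == pytest.approx(100.0)

    def test_improved_clone_round_trip(self):
        layout = syn.default_plate_layout()
        cfg = syn.SimulationConfig(seed=0, noise_sd_rel=0.0)
        spec = {w: 1.0 for w in layout.wells_with_role("sample")}
        spec["A1"] = 1.65
        reading = syn.simulate_plate(layout, spec, cfg)
        from petkinlab.screening import score_plate
        by_well = {s.well: s for s in score_plate(reading)}
        assert by_well["A1"].activity_pct == pytest.approx(165.0)

    def test_missing_sample_effect_rejected(self):
        layout = syn.default_plate_layout()
        with pytest.raises(ValueError, match="effect_spec"):
            syn.simulate_plate(layout, {}, syn.SimulationConfig())


class TestStructureGenerator:
    def test_empty_scenario_gives_empty_tables(self):
        pose_set, energy, cons = syn.simulate_structures_and_tables(
            syn.HotspotScenario())
        assert energy.empty and cons.empty
        assert pose_set.n_poses == 1

    def test_duplicate_residues_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            syn.HotspotScenario(residues=(syn.ResidueSpec(87, -1.0, 1.0),
                                          syn.ResidueSpec(87, -2.0, 1.0)))

    def test_pose_distances_realised_exactly(self):
        pose_set, _, _ = syn.simulate_structures_and_tables(
            syn.HotspotScenario(poses=(syn.PoseSpec(3.7, 3.1, 2.9),)))
        og = pose_set.receptor_atom(160, "OG")
        n87 = pose_set.receptor_atom(87, "N")
        n161 = pose_set.receptor_atom(161, "N")
        c = pose_set.poses.coord[0][0]
        o = pose_set.poses.coord[0][1]
        assert np.linalg.norm(c - og) == pytest.approx(3.7, abs=1e-6)
        assert np.linalg.norm(o - n87) == pytest.approx(3.1, abs=1e-6)
        assert np.linalg.norm(o - n161) == pytest.approx(2.9, abs=1e-6)
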