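"""Synthetic study generator: input function, kinetics, binning, noise, study draws."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdgquant.core import DEFAULT_BLOOD_TIMES_MIN, FrameSchedule
from fdgquant.errors import ConfigError, InputError
from fdgquant.quantify import QuantConfig, patlak_fit, patlak_points, plasma_exposure
from fdgquant.simulate import (
    InputFunctionModel,
    KineticParams,
    StudyDesign,
    add_measurement_noise,
    aif_on_grid,
    bin_to_frames,
    simulate_aif,
    simulate_glycemia,
    simulate_study,
    simulation_grid,
    tissue_curve,
)


class TestInputFunction:
    def test_peak_time_matches_observed_bolus(self, default_model, grid, dense_cp):
        """The continuous model peaks close to the observed 0.73 min."""
        t_peak = grid[np.argmax(dense_cp)]
        assert 0.5 <= t_peak <= 1.0
        assert t_peak == pytest.approx(0.73, abs=0.05)

    def test_bolus_only_limit_single_mode_decaying(self, grid):
        model = InputFunctionModel(tail_fractions=(0.0, 0.0))
        cp = model.shape(grid)
        peak = int(np.argmax(cp))
        assert np.all(np.diff(cp[:peak + 1]) >= 0)
        assert np.all(np.diff(cp[peak:]) <= 0)
        assert cp[-1] < 1e-6 * cp[peak]

    def test_zero_before_appearance_delay(self, default_model, grid, dense_cp):
        early = grid < default_model.appearance_delay_min
        assert np.all(dense_cp[early] == 0)
        assert np.all(dense_cp >= 0)

    def test_dense_exposure_hits_target(self, dense_cp, grid, meta):
        auc_suv = np.trapezoid(dense_cp, grid) / meta.suv_denominator_kbq_g
        assert auc_suv == pytest.approx(94.1, rel=1e-9)

    def test_sampled_exposure_close_to_dense(self, default_model, meta):
        aif = simulate_aif(default_model, DEFAULT_BLOOD_TIMES_MIN, 169.2, 5.8)
        assert plasma_exposure(aif, meta) == pytest.approx(94.1, rel=0.03)

    def test_input_validation(self, default_model):
        with pytest.raises(InputError):
            simulate_aif(default_model, [1.0, 0.5, 2.0], 169.2, 5.8)
        with pytest.raises(InputError):
            simulate_aif(default_model, [-1.0, 0.5, 2.0], 169.2, 5.8)
        with pytest.raises(InputError):
            aif_on_grid(default_model, simulation_grid(), dose_mbq=0.0, weight_kg=5.8)


class TestTissueCurve:
    def test_constant_input_late_slope_is_ki(self, grid):
        """With Cp = const the trapped compartment grows at rate Ki at late times."""
        params = KineticParams(0.10, 0.13, 0.016)
        cp = np.full(grid.size, 10.0)
        ct = tissue_curve(params, grid, cp)
        late = grid >= 50.0
        slope = np.polyfit(grid[late], ct[late] / 10.0, 1)[0]
        assert slope == pytest.approx(params.ki, rel=0.01)

    def test_no_trapping_gives_flat_patlak(self, grid, dense_cp, default_model,
                                           default_schedule):
        """k3 = 0: reversible kinetics, Patlak slope ~ 0."""
        params = KineticParams(0.10, 0.13, 0.0)
        assert params.ki == 0.0
        ct = tissue_curve(params, grid, dense_cp)
        aif = simulate_aif(default_model, DEFAULT_BLOOD_TIMES_MIN, 169.2, 5.8)
        tac = bin_to_frames(grid, ct, default_schedule, "r")
        fit = patlak_fit(patlak_points(tac, aif))
        # slope is tiny relative to a typical trapping rate
        assert abs(fit.ki_per_min) < 2e-4

    def test_patlak_recovers_ki_within_2pct(self, grid, dense_cp, default_model,
                                            default_schedule):
        """Forward-model curve fitted on [30, 60] min recovers Ki = K1*k3/(k2+k3)."""
        params = KineticParams(0.10, 0.13, 0.016)
        assert params.ki == pytest.approx(0.01096, abs=5e-6)
        ct = tissue_curve(params, grid, dense_cp)
        aif = simulate_aif(default_model, DEFAULT_BLOOD_TIMES_MIN, 169.2, 5.8)
        fit = patlak_fit(patlak_points(bin_to_frames(grid, ct, default_schedule, "r"), aif))
        assert fit.ki_per_min == pytest.approx(params.ki, rel=0.02)
        assert fit.r_squared > 0.99

    def test_trapped_compartment_nondecreasing(self, grid, dense_cp):
        params = KineticParams(0.10, 0.13, 0.03)
        ct = tissue_curve(params, grid, dense_cp)
        assert np.all(ct >= 0)
        # total activity of an irreversible system keeps growing once supplied
        late = grid > 40.0
        assert np.all(np.diff(ct[late]) > -1e-9)

    def test_coarse_grid_rejected(self, dense_cp):
        t_coarse = np.linspace(0, 60, 601)  # 0.1 min step
        with pytest.raises(ConfigError):
            tissue_curve(KineticParams(0.1, 0.13, 0.016), t_coarse,
                         np.interp(t_coarse, simulation_grid(), dense_cp))

    def test_kinetic_params_validation(self):
        with pytest.raises(InputError):
            KineticParams(0.0, 0.13, 0.016)
        with pytest.raises(InputError):
            KineticParams(0.1, 0.13, 0.016, vb=1.0)


class TestFrameBinning:
    def test_default_schedule_21_frames_covering_3600s(self, default_schedule):
        assert default_schedule.n_frames == 21
        assert default_schedule.span_s == 3600.0
        counts = np.unique(default_schedule.durations_s, return_counts=True)
        assert dict(zip(*counts)) == {15.0: 4, 30.0: 4, 60.0: 2, 120.0: 5, 300.0: 3, 600.0: 3}

    def test_constant_curve_bins_to_constant(self, grid, default_schedule):
        tac = bin_to_frames(grid, np.full(grid.size, 5.0), default_schedule, "r")
        assert tac.activity_kbq_ml == pytest.approx(np.full(21, 5.0), rel=1e-12)

    def test_linear_curve_bins_to_midpoints(self, grid, default_schedule):
        tac = bin_to_frames(grid, grid.copy(), default_schedule, "r")
        assert tac.activity_kbq_ml == pytest.approx(default_schedule.midpoints_min, rel=1e-9)

    def test_binning_conserves_time_integral(self, grid, dense_cp, default_schedule):
        params = KineticParams(0.10, 0.13, 0.02)
        ct = tissue_curve(params, grid, dense_cp)
        tac = bin_to_frames(grid, ct, default_schedule, "r")
        frame_integral = np.sum(tac.activity_kbq_ml * default_schedule.durations_s / 60.0)
        dense_integral = np.trapezoid(ct, grid)
        assert frame_integral == pytest.approx(dense_integral, rel=1e-3)

    def test_schedule_beyond_curve_span_rejected(self, default_schedule):
        t = simulation_grid(30.0)
        with pytest.raises(InputError):
            bin_to_frames(t, np.ones(t.size), default_schedule, "r")

    def test_schedule_invariants(self):
        with pytest.raises(InputError):
            FrameSchedule(np.array([0.0, 20.0]), np.array([15.0, 35.0]))  # gap
        with pytest.raises(InputError):
            FrameSchedule(np.array([5.0, 15.0]), np.array([15.0, 30.0]))  # start != 0


class TestMeasurementNoise:
    def _single_long_frame_tac(self, n=10000, value=7.0):
        sched = FrameSchedule(np.arange(n) * 600.0, (np.arange(n) + 1) * 600.0)
        from fdgquant.core import TimeActivityCurve
        return TimeActivityCurve("r", sched, np.full(n, value))

    def test_zero_noise_is_identity(self, grid, default_schedule):
        tac = bin_to_frames(grid, grid + 1.0, default_schedule, "r")
        assert add_measurement_noise(tac, 0.0, np.random.default_rng(0)) is tac

    def test_empirical_cv_matches_nominal(self):
        tac = self._single_long_frame_tac()
        noisy = add_measurement_noise(tac, 0.05, np.random.default_rng(123))
        cv = noisy.activity_kbq_ml.std() / noisy.activity_kbq_ml.mean()
        assert cv == pytest.approx(0.05, rel=0.10)

    def test_noise_scales_with_inverse_sqrt_duration(self):
        sched = FrameSchedule.default()
        from fdgquant.core import TimeActivityCurve
        rng = np.random.default_rng(42)
        reps = np.stack([
            add_measurement_noise(TimeActivityCurve("r", sched, np.full(21, 10.0)),
                                  0.05, rng).activity_kbq_ml
            for _ in range(4000)])
        cv_short = reps[:, 0].std() / 10.0   # 15 s frame
        cv_long = reps[:, -1].std() / 10.0   # 600 s frame
        assert cv_long == pytest.approx(0.05, rel=0.10)
        assert cv_short == pytest.approx(0.05 * np.sqrt(600 / 15), rel=0.10)

    def test_values_clipped_at_zero(self):
        tac = self._single_long_frame_tac(n=5000, value=0.5)
        noisy = add_measurement_noise(tac, 3.0, np.random.default_rng(5))
        assert np.all(noisy.activity_kbq_ml >= 0)
        assert np.any(noisy.activity_kbq_ml == 0)  # clipping actually engaged

    def test_negative_cv_rejected(self, grid, default_schedule):
        tac = bin_to_frames(grid, grid + 1.0, default_schedule, "r")
        with pytest.raises(InputError):
            add_measurement_noise(tac, -0.1, np.random.default_rng(0))


class TestGlycemia:
    def test_deterministic_link_gives_perfect_rank_correlation(self):
        design = StudyDesign(venous_slope=1.0, venous_resid_sd=0.0)
        art, ven = simulate_glycemia(design, np.random.default_rng(3), n=24)
        assert ven == pytest.approx(art)
        from fdgquant.repeatability import spearman
        assert spearman(art, ven).rho == pytest.approx(1.0)

    def test_default_link_strong_rank_correlation(self):
        from fdgquant.repeatability import spearman
        design = StudyDesign()
        rng = np.random.default_rng(77)
        rhos = [spearman(*simulate_glycemia(design, rng, n=24)).rho for _ in range(200)]
        assert np.median(rhos) >= 0.9

    def test_marginal_mean_centered(self):
        design = StudyDesign()
        rng = np.random.default_rng(11)
        means = [simulate_glycemia(design, rng, n=12)[0].mean() for _ in range(1000)]
        assert np.mean(means) == pytest.approx(4.5, abs=0.05)
        assert np.std([simulate_glycemia(design, rng, n=1000)[0].std() for _ in range(5)]
                      ) < 0.1  # sd stable across draws


class TestSimulateStudy:
    def test_variance_free_study_has_identical_sessions(self, variance_free_design):
        study = simulate_study(variance_free_design)
        by_key = {(s.meta.subject_id, s.meta.session): s for s in study.scans}
        for i in range(variance_free_design.n_subjects):
            sid = f"m{i + 1:02d}"
            t, r = by_key[(sid, "test")], by_key[(sid, "retest")]
            for region in t.tacs:
                np.testing.assert_array_equal(t.tacs[region].activity_kbq_ml,
                                              r.tacs[region].activity_kbq_ml)
            np.testing.assert_array_equal(t.aif.plasma_kbq_ml, r.aif.plasma_kbq_ml)
            assert t.meta.glycemia_arterial_mmol_l == r.meta.glycemia_arterial_mmol_l

    def test_same_seed_reproduces_study_exactly(self, small_design):
        s1, s2 = simulate_study(small_design), simulate_study(small_design)
        assert s1.truth.equals(s2.truth)
        for a, b in zip(s1.scans, s2.scans):
            assert a.meta == b.meta
            np.testing.assert_array_equal(a.aif.plasma_kbq_ml, b.aif.plasma_kbq_ml)
            for region in a.tacs:
                np.testing.assert_array_equal(a.tacs[region].activity_kbq_ml,
                                              b.tacs[region].activity_kbq_ml)

    def test_different_seed_changes_study(self, small_design):
        other = dataclasses.replace(small_design, rng_seed=12)
        s1, s2 = simulate_study(small_design), simulate_study(other)
        assert not np.array_equal(s1.scans[0].tacs["pons"].activity_kbq_ml,
                                  s2.scans[0].tacs["pons"].activity_kbq_ml)

    def test_truth_covers_every_scan_and_region(self, small_design):
        study = simulate_study(small_design)
        keys = {(s.meta.subject_id, s.meta.session, r)
                for s in study.scans for r in s.tacs}
        truth_keys = set(map(tuple, study.truth[["subject_id", "session", "region"]]
                             .to_numpy()))
        assert keys == truth_keys

    def test_true_ki_composes_effects(self, small_design):
        study = simulate_study(small_design)
        t = study.truth
        expected = (t["region"].map(small_design.region_ki_map)
                    * np.exp(t["subject_effect"]) * np.exp(t["session_effect"]))
        np.testing.assert_allclose(t["Ki"], expected, rtol=1e-12)

    def test_design_validation(self):
        with pytest.raises(ConfigError):
            StudyDesign(n_subjects=0)
        with pytest.raises(ConfigError):
            StudyDesign(region_ki_map={"pons": 0.012})  # cerebellum missing
        with pytest.raises(ConfigError):
            StudyDesign(region_ki_map={"pons": 0.2, "cerebellum": 0.015})  # Ki >= K1


@settings(deadline=None, max_examples=25, derandomize=True)
@given(scale=st.floats(min_value=0.1, max_value=10.0),
       offset=st.floats(min_value=0.0, max_value=5.0))
def test_binning_is_linear_in_the_curve(scale, offset):
    """bin(a*f + b) == a*bin(f) + b: frame averaging is affine."""
    grid = simulation_grid(10.0)
    sched = FrameSchedule(np.array([0.0, 120.0, 300.0]), np.array([120.0, 300.0, 600.0]))
    f = np.sin(grid / 3.0) + 2.0
    base = bin_to_frames(grid, f, sched, "r").activity_kbq_ml
    combo = bin_to_frames(grid, scale * f + offset, sched, "r").activity_kbq_ml
    np.testing.assert_allclose(combo, scale * base + offset, rtol=1e-9, atol=1e-9)
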