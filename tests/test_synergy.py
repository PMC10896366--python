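"""Disease scaling, deficit pipeline, and baseline calibration."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pingmf as pm
from pingmf.synergy import (CONDITIONS, HEALTHY_STATE, DiseaseScaling,
                            Landmark, PowerSettings, apply_percent_difference,
                            calibrate_reference, gamma_power_at,
                            healthy_state_search, lambda_scale, landmark_values,
                            sz_state, synergy_analysis)


class TestLambdaScaling:
    def test_healthy_endpoint(self):
        assert lambda_scale(1.3, 1.04, 0.0) == 1.3

    def test_sz_endpoint(self):
        assert lambda_scale(1.3, 1.04, 1.0) == pytest.approx(1.04)

    def test_midpoint(self):
        assert lambda_scale(1.3, 1.04, 0.5) == pytest.approx(1.17)

    def test_endpoints_exact_for_all_scaled_parameters(self):
        sc = DiseaseScaling.at_percent(20.0)
        assert sc.at_lambda(0.0) == sc.healthy
        for k, v in sc.at_lambda(1.0).items():
            assert v == pytest.approx(sc.sz[k], rel=1e-15)


class TestPercentDifference:
    def test_strengths_scale_down(self):
        sz = apply_percent_difference({"gbar_e_gaba": 0.6}, 20.0)
        assert sz["gbar_e_gaba"] == pytest.approx(0.48)

    def test_variabilities_scale_up(self):
        sz = apply_percent_difference({"gamma_i_ampa": 0.01}, 20.0)
        assert sz["gamma_i_ampa"] == pytest.approx(0.012)

    def test_zero_percent_is_identity(self):
        assert apply_percent_difference(HEALTHY_STATE, 0.0) == HEALTHY_STATE

    def test_full_sz_state_at_20pct(self):
        sz = sz_state(20.0)
        assert sz["gbar_i_ampa"] == pytest.approx(1.04)
        assert sz["gbar_i_nmda"] == pytest.approx(0.104)
        assert sz["gbar_e_gaba"] == pytest.approx(0.48)
        assert sz["gamma_i_ampa"] == pytest.approx(0.012)
        assert sz["gamma_i_nmda"] == pytest.approx(0.012)

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(ValueError):
            apply_percent_difference(HEALTHY_STATE, 120.0)

    @settings(derandomize=True, max_examples=60)
    @given(pct=st.floats(0.0, 100.0), lam=st.floats(0.0, 1.0))
    def test_lambda_path_stays_between_endpoints(self, pct, lam):
        """For every scaled parameter, the lambda-interpolated value lies
        between its healthy and SZ endpoints and hits them exactly."""
        sc = DiseaseScaling.at_percent(pct)
        for k, v in sc.at_lambda(lam).items():
            lo, hi = sorted((sc.healthy[k], sc.sz[k]))
            assert lo - 1e-12 <= v <= hi + 1e-12
        assert sc.at_lambda(0.0) == sc.healthy

    def test_directionality_invariant(self):
        """Strengths decrease and variabilities increase, healthy -> SZ."""
        sc = DiseaseScaling.at_percent(15.0)
        for k in sc.healthy:
            if k.startswith("gbar"):
                assert sc.sz[k] < sc.healthy[k]
            else:
                assert sc.sz[k] > sc.healthy[k]


@pytest.fixture(scope="module")
def fast_settings():
    """Shorter protocol for tests: same estimator, smaller problem size."""
    return PowerSettings(duration=2500.0, rtol=1e-7)


class TestSynergyAnalysis:
    def test_zero_percent_gives_zero_deficits_and_null_fold(self, reference,
                                                            fast_settings):
        res, = synergy_analysis(reference, [0.0], settings=fast_settings)
        for cond in CONDITIONS:
            assert res.deficits[cond] == pytest.approx(0.0, abs=1e-9)
        assert res.fold_ratio is None

    def test_combined_condition_matches_independent_single_shot(
            self, reference, fast_settings):
        """The pipeline's combined condition must equal a from-scratch run
        with all five SZ values applied at once."""
        res, = synergy_analysis(reference, [20.0], settings=fast_settings)
        p_direct = reference.with_params(HEALTHY_STATE).with_params(sz_state(20.0))
        P_direct, _ = gamma_power_at(p_direct, fast_settings)
        assert res.powers["combined"] == P_direct

    def test_all_conditions_share_frozen_settings(self, reference,
                                                  fast_settings):
        out = synergy_analysis(reference, [10.0, 20.0], settings=fast_settings)
        hashes = {r.settings_hash for r in out}
        assert len(hashes) == 1


class TestHealthyStateSearch:
    def test_single_point_grid_returns_that_point(self, reference,
                                                  fast_settings):
        best, surface = healthy_state_search(
            reference, np.array([1.3]), np.array([0.6]),
            settings=fast_settings)
        assert best["gbar_i_ampa"] == 1.3
        assert best["gbar_e_gaba"] == 0.6
        assert best["gbar_i_nmda"] == pytest.approx(0.13)
        assert surface.shape == (1, 1) and surface[0, 0] > 0

    def test_returned_point_dominates_scanned_grid(self, reference,
                                                   fast_settings):
        g_ei = np.array([1.0, 1.3])
        g_ie = np.array([0.45, 0.6])
        best, surface = healthy_state_search(reference, g_ei, g_ie,
                                             settings=fast_settings)
        i = list(g_ei).index(best["gbar_i_ampa"])
        j = list(g_ie).index(best["gbar_e_gaba"])
        assert surface[i, j] == surface.max()


class TestCalibrateReference:
    def test_empty_free_set_reports_residuals_without_fitting(self, reference):
        lms = (Landmark("onset", "hopf", "gbar_i_ampa", 0.002, 1.29, 0.26,
                        "onset", 30),)
        p_out, report = calibrate_reference(reference, free=(), landmarks=lms)
        assert p_out == reference
        assert set(report) == {"onset"}
        assert np.isfinite(report["onset"])

    def test_recovers_perturbed_constant_from_synthetic_target(self, reference):
        """Generate a landmark from a known config, perturb one free
        constant by 10%, and check the fit recovers it to 1%."""
        lm_def = Landmark("gie_off", "hopf", "gbar_e_gaba", 0.61, 6.0, np.nan,
                          "offset", 25)
        true_val = landmark_values(reference, (lm_def,))["gie_off"]
        assert true_val is not None
        target = dataclasses.replace(lm_def, target=float(true_val))
        p0 = reference.with_param("tau_i", reference.kinetics.tau_i * 1.1)
        p_fit, report = calibrate_reference(
            p0, free=("tau_i",), landmarks=(target,),
            bounds={"tau_i": (2.0, 30.0)}, max_nfev=25)
        assert p_fit.kinetics.tau_i == pytest.approx(
            reference.kinetics.tau_i, rel=0.01)
        assert abs(report["gie_off"]) < 0.005
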