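"""Nondimensionalization, Lorentzian sampling, and config round trips."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import pingmf as pm
from pingmf.params import (BiophysParams, CouplingParams, DriveParams,
                           SynapseKinetics, dimensionalize, load_config,
                           nondimensionalize, sample_lorentzian, save_config)


class TestNondimensionalize:
    def test_reversal_midpoint_maps_to_zero(self):
        bp = BiophysParams(Vl=-65.0, VT=-50.0, Vex=-57.5 + 1e3, Vin=-70.0)
        # a reversal at (VT+Vl)/2 maps to uhat = 0 by construction
        bp_mid = dataclasses.replace(bp, Vex=-57.5 + 60.0)
        rp = nondimensionalize(bp_mid, I_appl=0.0)
        assert rp.Vhat_ex == pytest.approx(60.0 / 7.5)
        assert nondimensionalize(bp_mid, 0.0).Vhat_in == pytest.approx(
            (-70.0 + 57.5) / 7.5)

    def test_leak_and_threshold_map_to_unit_interval(self):
        rp = nondimensionalize(BiophysParams(), I_appl=1.0)
        assert rp.Vhat_in < -1.0 < 1.0 < rp.Vhat_ex
        assert rp.tau == pytest.approx(BiophysParams().C / BiophysParams().gl)

    def test_conductance_normalizes_by_leak(self):
        bp = BiophysParams(gl=0.25)
        # a conductance equal to gl is 1 in reduced units
        assert 0.25 / bp.gl == pytest.approx(1.0)
        rp = nondimensionalize(bp, I_appl=0.5)
        assert rp.drive.Ibar_e == pytest.approx(2 * 0.5 / (0.25 * 15.0))

    def test_roundtrip_is_identity_on_random_valid_sets(self, rng):
        for _ in range(100):
            Vl = -80.0 + 20.0 * rng.random()
            VT = Vl + 5.0 + 20.0 * rng.random()
            bp = BiophysParams(
                C=0.5 + 2.0 * rng.random(),
                gl=0.05 + 0.3 * rng.random(),
                Vl=Vl, VT=VT,
                Vex=VT + 10.0 + 40.0 * rng.random(),
                Vin=Vl - 20.0 * rng.random(),
            )
            I = -2.0 + 6.0 * rng.random()
            bp2, I2 = dimensionalize(nondimensionalize(bp, I))
            for f in ("C", "gl", "Vl", "VT", "Vex", "Vin"):
                assert getattr(bp2, f) == pytest.approx(getattr(bp, f), rel=1e-12)
            assert I2 == pytest.approx(I, rel=1e-12, abs=1e-12)

    def test_degenerate_threshold_rejected(self):
        with pytest.raises(ValueError, match="VT"):
            BiophysParams(Vl=-50.0, VT=-50.0)


class TestLorentzianSampler:
    def test_zero_half_width_is_degenerate(self):
        x = sample_lorentzian(2.5, 0.0, 1000, seed=1)
        assert np.all(x == 2.5)

    def test_seed_reproducibility(self):
        a = sample_lorentzian(0.0, 1.0, 500, seed=42)
        b = sample_lorentzian(0.0, 1.0, 500, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_negative_half_width_rejected(self):
        with pytest.raises(ValueError):
            sample_lorentzian(0.0, -0.1, 10, seed=0)

    def test_median_matches_cauchy_location(self):
        n, mode, hw = 10**5, 2.0, 0.5
        x = sample_lorentzian(mode, hw, n, seed=7)
        # median standard error of a Cauchy sample is gamma*pi/(2 sqrt(n))
        assert abs(np.median(x) - mode) < 4 * hw * np.pi / (2 * np.sqrt(n))

    def test_iqr_matches_cauchy_scale(self):
        x = sample_lorentzian(0.0, 0.7, 10**5, seed=11)
        q1, q3 = np.quantile(x, [0.25, 0.75])
        assert (q3 - q1) / 2 == pytest.approx(0.7, rel=0.05)

    def test_empirical_cdf_matches_cauchy(self):
        x = sample_lorentzian(1.0, 0.3, 10**5, seed=5)
        stat = stats.kstest(x, stats.cauchy(loc=1.0, scale=0.3).cdf).statistic
        assert stat < 1.63 / np.sqrt(10**5)   # 1% critical value

    def test_truncation_flag_removes_negative_draws(self):
        x = sample_lorentzian(1.0, 2.0, 5000, seed=3, truncate_at_zero=True)
        assert np.all(x >= 0)


class TestFlatParameterAccess:
    def test_pathway_aliases_resolve(self, reference):
        p = reference.with_param("g_EtoI", 0.77)
        assert p.coupling.gbar_i_ampa == 0.77
        assert p.get_param("g_EtoI") == 0.77

    def test_unknown_name_raises(self, reference):
        with pytest.raises(KeyError):
            reference.with_param("gbar_x_ampa", 1.0)

    def test_with_param_leaves_original_untouched(self, reference):
        before = reference.coupling.gbar_e_gaba
        reference.with_param("gbar_e_gaba", before + 1.0)
        assert reference.coupling.gbar_e_gaba == before


class TestConfigIO:
    def test_roundtrip(self, tmp_path, reference):
        path = tmp_path / "cfg.yaml"
        save_config(reference, path)
        rp, extras = load_config(path)
        assert rp.tau == pytest.approx(reference.tau)
        assert rp.coupling == reference.coupling
        assert rp.kinetics == reference.kinetics
        assert rp.drive == reference.drive

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("coupling:\n  gbar_i_ampa: 1.0\n  gbar_zz: 2.0\n")
        with pytest.raises(ValueError, match="gbar_zz"):
            load_config(path)

    def test_unknown_section_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("couplings:\n  gbar_i_ampa: 1.0\n")
        with pytest.raises(ValueError, match="unknown config section"):
            load_config(path)


class TestInvariantValidation:
    @pytest.mark.parametrize("kwargs", [
        {"C": -1.0}, {"gl": 0.0}, {"Vin": -60.0, "Vl": -65.0},
    ])
    def test_bad_biophysics_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BiophysParams(**kwargs)

    def test_nmda_slower_than_ampa_enforced(self):
        with pytest.raises(ValueError, match="tau_n"):
            SynapseKinetics(tau_e=5.0, tau_n=4.0)

    def test_negative_coupling_rejected(self):
        with pytest.raises(ValueError):
            CouplingParams(gbar_i_ampa=-0.1)

    def test_negative_drive_width_rejected(self):
        with pytest.raises(ValueError):
            DriveParams(Delta_e=-0.01)
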