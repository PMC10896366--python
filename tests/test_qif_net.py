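"""Spiking-network construction, integration, and rate conversion."""

import numpy as np
import pytest

import pingmf as pm
from pingmf.qif_net import (SpikeRecord, build_network, population_rate,
                            simulate_network, single_neuron_rate_closed_form)


def _quiet_params(tau=10.0, Ibar=0.0, Delta=0.0):
    return pm.ReducedParams(
        tau=tau,
        coupling=pm.CouplingParams(),
        drive=pm.DriveParams(Ibar_e=Ibar, Delta_e=Delta, Ibar_i=0.0, Delta_i=0.0),
    )


class TestBuildNetwork:
    def test_same_seed_gives_bit_identical_networks(self, reference):
        a = build_network(reference, 50, 20, seed=9)
        b = build_network(reference, 50, 20, seed=9)
        for f in ("ge_e", "gn_e", "gi_e", "I_e", "ge_i", "gn_i", "gi_i", "I_i"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_different_seed_differs(self, reference):
        a = build_network(reference, 50, 20, seed=1)
        b = build_network(reference, 50, 20, seed=2)
        assert not np.array_equal(a.I_e, b.I_e)

    def test_zero_half_widths_make_identical_neurons(self):
        p = _quiet_params(Ibar=1.2)
        net = build_network(p, 30, 10, seed=0)
        assert np.ptp(net.I_e) == 0.0
        assert np.ptp(net.ge_i) == 0.0

    def test_default_population_sizes(self, reference):
        net = build_network(reference, seed=0)
        assert (net.N_e, net.N_i) == (800, 200)

    def test_rejects_empty_population(self, reference):
        with pytest.raises(ValueError):
            build_network(reference, 0, 10, seed=0)


class TestSimulateNetwork:
    def test_subthreshold_network_never_spikes(self):
        """Rest initial condition, no drive, no coupling: u = -1 is a fixed
        point below threshold."""
        net = build_network(_quiet_params(), 20, 5, seed=0)
        rec, gates = simulate_network(net, duration=200.0, dt=0.05)
        assert len(rec.times) == 0
        assert np.all(gates["s_e"] == 0.0)

    @pytest.mark.parametrize("Ihat", [0.7, 1.0, 3.0])
    def test_single_neuron_rate_matches_quadrature(self, Ihat):
        """Uncoupled homogeneous neuron vs the closed-form QIF frequency."""
        tau = 10.0
        net = build_network(_quiet_params(tau=tau, Ibar=Ihat), 1, 1, seed=0)
        rec, _ = simulate_network(net, duration=6000.0, dt=0.02)
        n = int((rec.neuron_ids == 0).sum())
        r_expected = single_neuron_rate_closed_form(Ihat, tau)
        assert n / 6000.0 == pytest.approx(r_expected, rel=0.02)

    def test_determinism_under_fixed_seed_and_dt(self, reference):
        net = build_network(reference, 40, 10, seed=5)
        r1, g1 = simulate_network(net, duration=300.0, dt=0.02)
        r2, g2 = simulate_network(net, duration=300.0, dt=0.02)
        np.testing.assert_array_equal(r1.times, r2.times)
        np.testing.assert_array_equal(r1.neuron_ids, r2.neuron_ids)
        np.testing.assert_array_equal(g1["s_n"], g2["s_n"])

    def test_gates_stay_in_bounds(self, reference):
        net = build_network(reference, 100, 25, seed=2)
        _, gates = simulate_network(net, duration=400.0, dt=0.02)
        assert np.all(gates["s_e"] >= 0.0)
        assert np.all(gates["s_i"] >= 0.0)
        assert np.all((gates["s_n"] >= 0.0) & (gates["s_n"] <= 1.0))

    def test_rejects_bad_step(self, reference):
        net = build_network(reference, 10, 5, seed=0)
        with pytest.raises(ValueError):
            simulate_network(net, duration=1.0, dt=-0.1)


class TestPopulationRate:
    def _poisson_record(self, rate_hz, n_neurons, duration, rng):
        n_expected = rng.poisson(rate_hz / 1000.0 * duration * n_neurons)
        times = np.sort(rng.uniform(0, duration, n_expected))
        ids = rng.integers(0, n_neurons, n_expected)
        return SpikeRecord(times=times, neuron_ids=ids, N_e=n_neurons, N_i=1,
                           duration=duration)

    def test_empty_record_gives_zero_trace(self):
        rec = SpikeRecord(times=np.array([]), neuron_ids=np.array([], dtype=int),
                          N_e=10, N_i=5, duration=100.0)
        _, rate = population_rate(rec, "e", bin=1.0)
        assert rate.shape == (100,) and np.all(rate == 0.0)

    def test_spike_count_conservation_is_exact(self, reference):
        net = build_network(reference, 60, 15, seed=3)
        rec, _ = simulate_network(net, duration=300.0, dt=0.02)
        for pop, n_pop in (("e", 60), ("i", 15)):
            _, rate = population_rate(rec, pop, bin=1.0)
            assert np.sum(rate) * n_pop * 1.0 == pytest.approx(
                rec.population(pop).sum(), abs=1e-9)

    def test_homogeneous_poisson_rate_recovered(self, rng):
        rec = self._poisson_record(40.0, 100, 2000.0, rng)
        _, rate = population_rate(rec, "e", bin=1.0)
        mean_hz = 1000.0 * rate.mean()
        se = 1000.0 * np.sqrt(40.0 / 1000.0 / (100 * 2000.0))
        assert abs(mean_hz - 40.0) < 3 * se

    def test_unknown_population_tag(self):
        rec = SpikeRecord(times=np.array([1.0]), neuron_ids=np.array([0]),
                          N_e=1, N_i=1, duration=10.0)
        with pytest.raises(KeyError):
            population_rate(rec, "x")

    def test_smoothing_preserves_total_mass_approximately(self, reference):
        net = build_network(reference, 60, 15, seed=4)
        rec, _ = simulate_network(net, duration=400.0, dt=0.02)
        _, raw = population_rate(rec, "e", bin=1.0)
        _, smooth = population_rate(rec, "e", bin=1.0, smooth_width=2.0)
        assert smooth.sum() == pytest.approx(raw.sum(), rel=1e-6)
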