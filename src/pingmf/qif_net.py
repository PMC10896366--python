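"""Finite-size spiking QIF PING network.

All-to-all coupled populations of regular-spiking excitatory (RSE) and
fast-spiking inhibitory (FSI) quadratic integrate-and-fire neurons with
global AMPA, GABA and NMDA gating.  Each neuron carries quenched
Lorentzian draws of its synaptic strengths and tonic drive, matching the
heterogeneity model of the mean-field reduction.

Integration uses the theta-neuron change of variables u = tan(theta/2),
under which the QIF blow-up/reset at +/- infinity becomes a smooth phase
crossing of theta = pi: no cutoff bias, and spike detection is exact up to
the time step.  The drift near the crossing is d(theta)/dt = 1/tau > 0, so
crossings are always upward.

A spike detected at the end of a step increments the corresponding global
gate by 1/N_pre (presynaptic population size), which is the finite-size
counterpart of the rate terms driving the mean-field gates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .params import ReducedParams, sample_lorentzian

__all__ = ["SpikingNetwork", "SpikeRecord", "build_network", "simulate_network",
           "population_rate", "single_neuron_rate_closed_form"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@dataclass(frozen=True)
class SpikingNetwork:
    """Quenched network realization plus shared dynamical parameters."""

    params: ReducedParams
    N_e: int
    N_i: int
    seed: int
    # per-neuron Lorentzian draws (conductances in units of gl; drives Ihat)
    ge_e: np.ndarray
    gn_e: np.ndarray
    gi_e: np.ndarray
    I_e: np.ndarray
    ge_i: np.ndarray
    gn_i: np.ndarray
    gi_i: np.ndarray
    I_i: np.ndarray

    @property
    def N(self) -> int:
        return self.N_e + self.N_i


@dataclass(frozen=True)
class SpikeRecord:
    """Spike times (ms), flat neuron ids (< N_e excitatory), duration."""

    times: np.ndarray
    neuron_ids: np.ndarray
    N_e: int
    N_i: int
    duration: float

    def population(self, tag: str) -> np.ndarray:
        """Boolean mask of spikes belonging to population ``"e"`` or ``"i"``."""
        if tag == "e":
            return self.neuron_ids < self.N_e
        if tag == "i":
            return self.neuron_ids >= self.N_e
        raise KeyError(f"unknown population tag {tag!r} (use 'e' or 'i')")


def build_network(params: ReducedParams, N_e: int = 800, N_i: int = 200,
                  seed: int = 0, *, truncate_at_zero: bool = False) -> SpikingNetwork:
    """Draw one quenched network realization.

    Heterogeneity is drawn once here and never redrawn during simulation.
    The eight Lorentzian draws consume a single seeded generator in a fixed
    documented order (E: ampa, nmda, gaba, drive; then I likewise), so a
    seed pins down the network bit for bit.
    """
    if N_e < 1 or N_i < 1:
        raise ValueError(f"population sizes must be >= 1, got {N_e}, {N_i}")
    c, d = params.coupling, params.drive
    rng = np.random.default_rng(seed)
    kw = {"truncate_at_zero": truncate_at_zero}
    return SpikingNetwork(
        params=params, N_e=N_e, N_i=N_i, seed=seed,
        ge_e=sample_lorentzian(c.gbar_e_ampa, c.gamma_e_ampa, N_e, rng, **kw),
        gn_e=sample_lorentzian(c.gbar_e_nmda, c.gamma_e_nmda, N_e, rng, **kw),
        gi_e=sample_lorentzian(c.gbar_e_gaba, c.gamma_e_gaba, N_e, rng, **kw),
        I_e=sample_lorentzian(d.Ibar_e, d.Delta_e, N_e, rng, **kw),
        ge_i=sample_lorentzian(c.gbar_i_ampa, c.gamma_i_ampa, N_i, rng, **kw),
        gn_i=sample_lorentzian(c.gbar_i_nmda, c.gamma_i_nmda, N_i, rng, **kw),
        gi_i=sample_lorentzian(c.gbar_i_gaba, c.gamma_i_gaba, N_i, rng, **kw),
        I_i=sample_lorentzian(d.Ibar_i, d.Delta_i, N_i, rng, **kw),
    )


@njit(cache=False)
def _theta_drift(theta, ge, gn, gi, I, s_e, s_i, s_n, tau, vex, vin):
    # tau * dtheta/dt = A(1-cos) + B sin + C(1+cos) with A=1/2 and
    # B, C from the per-neuron nondimensional QIF drift.
    gex = ge * s_e + gn * s_n
    gin_ = gi * s_i
    B = -(gex + gin_)
    C = gex * vex + gin_ * vin + I - 0.5
    return (0.5 * (1.0 - np.cos(theta)) + B * np.sin(theta)
            + C * (1.0 + np.cos(theta))) / tau


@njit(cache=False)
def _run_network(theta_e, theta_i, ge_e, gn_e, gi_e, I_e, ge_i, gn_i, gi_i, I_i,
                 tau, vex, vin, tau_e, tau_i, tau_n, a_n,
                 dt, n_steps, stride,
                 spike_t, spike_id, gate_out, rate_count_e, rate_count_i):
    N_e = theta_e.size
    N_i = theta_i.size
    s_e = 0.0
    s_i = 0.0
    s_n = 0.0
    n_spk = 0
    cap = spike_t.size
    n_out = 0
    for step in range(n_steps):
        t = step * dt
        if step % stride == 0:
            gate_out[n_out, 0] = t
            gate_out[n_out, 1] = s_e
            gate_out[n_out, 2] = s_i
            gate_out[n_out, 3] = s_n
            n_out += 1
        # RK4 on the smooth flow (phases + gate decay); spike kicks applied
        # after the step, summed over simultaneous spikes (order-free).
        k1e = _theta_drift(theta_e, ge_e, gn_e, gi_e, I_e, s_e, s_i, s_n, tau, vex, vin)
        k1i = _theta_drift(theta_i, ge_i, gn_i, gi_i, I_i, s_e, s_i, s_n, tau, vex, vin)
        d1e = -s_e / tau_e
        d1i = -s_i / tau_i
        d1n = a_n * s_e * (1.0 - s_n) - s_n / tau_n

        se2 = s_e + 0.5 * dt * d1e
        si2 = s_i + 0.5 * dt * d1i
        sn2 = s_n + 0.5 * dt * d1n
        k2e = _theta_drift(theta_e + 0.5 * dt * k1e, ge_e, gn_e, gi_e, I_e,
                           se2, si2, sn2, tau, vex, vin)
        k2i = _theta_drift(theta_i + 0.5 * dt * k1i, ge_i, gn_i, gi_i, I_i,
                           se2, si2, sn2, tau, vex, vin)
        d2e = -se2 / tau_e
        d2i = -si2 / tau_i
        d2n = a_n * se2 * (1.0 - sn2) - sn2 / tau_n

        se3 = s_e + 0.5 * dt * d2e
        si3 = s_i + 0.5 * dt * d2i
        sn3 = s_n + 0.5 * dt * d2n
        k3e = _theta_drift(theta_e + 0.5 * dt * k2e, ge_e, gn_e, gi_e, I_e,
                           se3, si3, sn3, tau, vex, vin)
        k3i = _theta_drift(theta_i + 0.5 * dt * k2i, ge_i, gn_i, gi_i, I_i,
                           se3, si3, sn3, tau, vex, vin)
        d3e = -se3 / tau_e
        d3i = -si3 / tau_i
        d3n = a_n * se3 * (1.0 - sn3) - sn3 / tau_n

        se4 = s_e + dt * d3e
        si4 = s_i + dt * d3i
        sn4 = s_n + dt * d3n
        k4e = _theta_drift(theta_e + dt * k3e, ge_e, gn_e, gi_e, I_e,
                           se4, si4, sn4, tau, vex, vin)
        k4i = _theta_drift(theta_i + dt * k3i, ge_i, gn_i, gi_i, I_i,
                           se4, si4, sn4, tau, vex, vin)
        d4e = -se4 / tau_e
        d4i = -si4 / tau_i
        d4n = a_n * se4 * (1.0 - sn4) - sn4 / tau_n

        theta_e += (dt / 6.0) * (k1e + 2.0 * k2e + 2.0 * k3e + k4e)
        theta_i += (dt / 6.0) * (k1i + 2.0 * k2i + 2.0 * k3i + k4i)
        s_e += (dt / 6.0) * (d1e + 2.0 * d2e + 2.0 * d3e + d4e)
        s_i += (dt / 6.0) * (d1i + 2.0 * d2i + 2.0 * d3i + d4i)
        s_n += (dt / 6.0) * (d1n + 2.0 * d2n + 2.0 * d3n + d4n)

        t_spk = t + dt
        ne_spk = 0
        for j in range(N_e):
            if theta_e[j] >= np.pi:
                theta_e[j] -= 2.0 * np.pi
                ne_spk += 1
                if n_spk < cap:
                    spike_t[n_spk] = t_spk
                    spike_id[n_spk] = j
                    n_spk += 1
        ni_spk = 0
        for j in range(N_i):
            if theta_i[j] >= np.pi:
                theta_i[j] -= 2.0 * np.pi
                ni_spk += 1
                if n_spk < cap:
                    spike_t[n_spk] = t_spk
                    spike_id[n_spk] = N_e + j
                    n_spk += 1
        rate_count_e[step] = ne_spk
        rate_count_i[step] = ni_spk
        s_e += ne_spk / N_e
        s_i += ni_spk / N_i
        if not (np.isfinite(s_e) and np.isfinite(s_i) and np.isfinite(s_n)):
            return -(step + 1), n_out
    return n_spk, n_out


def simulate_network(
    net: SpikingNetwork,
    duration: float = 1500.0,
    dt: float | None = None,
    *,
    theta0: np.ndarray | None = None,
    gate_stride_ms: float = 1.0,
) -> tuple[SpikeRecord, dict[str, np.ndarray]]:
    """Integrate the network; returns spikes plus global gating traces.

    ``dt`` defaults to ``0.01 * tau_e``.  Initial phases default to the
    rest potential u = -1 (theta = -pi/2) for every neuron.
    """
    if dt is None:
        dt = 0.01 * net.params.kinetics.tau_e
    if dt <= 0 or duration < dt:
        raise ValueError(f"need dt > 0 and duration >= dt, got dt={dt}, "
                         f"duration={duration}")
    p = net.params
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(gate_stride_ms / dt)))
    theta_e = np.full(net.N_e, -np.pi / 2.0) if theta0 is None \
        else np.array(theta0[:net.N_e], dtype=float)
    theta_i = np.full(net.N_i, -np.pi / 2.0) if theta0 is None \
        else np.array(theta0[net.N_e:], dtype=float)

    cap = int(net.N * duration * 0.25) + 1024     # ~250 Hz/neuron headroom
    spike_t = np.empty(cap)
    spike_id = np.empty(cap, dtype=np.int64)
    gate_out = np.empty((n_steps // stride + 2, 4))
    count_e = np.empty(n_steps, dtype=np.int64)
    count_i = np.empty(n_steps, dtype=np.int64)

    n_spk, n_out = _run_network(
        theta_e, theta_i, net.ge_e, net.gn_e, net.gi_e, net.I_e,
        net.ge_i, net.gn_i, net.gi_i, net.I_i,
        p.tau, p.Vhat_ex, p.Vhat_in,
        p.kinetics.tau_e, p.kinetics.tau_i, p.kinetics.tau_n, p.kinetics.a_n,
        dt, n_steps, stride,
        spike_t, spike_id, gate_out, count_e, count_i)
    if n_spk < 0:
        t_fail = -n_spk * dt
        raise RuntimeError(f"network state became non-finite at t={t_fail:.3f} ms")
    if n_spk >= cap:
        raise RuntimeError("spike buffer overflow: firing rate far above the "
                           "physiological budget (250 Hz per neuron)")
    rec = SpikeRecord(times=spike_t[:n_spk].copy(),
                      neuron_ids=spike_id[:n_spk].copy(),
                      N_e=net.N_e, N_i=net.N_i, duration=duration)
    gates = {
        "t": gate_out[:n_out, 0].copy(),
        "s_e": gate_out[:n_out, 1].copy(),
        "s_i": gate_out[:n_out, 2].copy(),
        "s_n": gate_out[:n_out, 3].copy(),
    }
    return rec, gates


def population_rate(
    rec: SpikeRecord,
    population: str = "e",
    bin: float = 1.0,
    smooth_width: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned per-neuron population rate (1/ms); optionally smoothed.

    Returns ``(bin_centers_ms, rate)``.  The unsmoothed histogram satisfies
    ``sum(rate) * N_pop * bin == total spike count`` exactly; smoothing
    (Gaussian kernel of standard deviation ``smooth_width`` ms, reflected
    at the edges) preserves this up to boundary effects.
    """
    if bin <= 0:
        raise ValueError(f"bin must be positive, got {bin}")
    mask = rec.population(population)
    n_pop = rec.N_e if population == "e" else rec.N_i
    n_bins = int(np.ceil(rec.duration / bin))
    edges = np.arange(n_bins + 1) * bin
    counts, _ = np.histogram(rec.times[mask], bins=edges)
    rate = counts / (n_pop * bin)
    if smooth_width > 0:
        rate = gaussian_filter1d(rate, sigma=smooth_width / bin, mode="reflect")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, rate


def single_neuron_rate_closed_form(Ihat: float, tau: float) -> float:
    """Firing rate (1/ms) of one uncoupled homogeneous QIF neuron.

    Integrating ``tau du/dt = (u^2 - 1)/2 + Ihat`` over the whole real line
    gives the period ``2 pi tau / sqrt(2 Ihat - 1)`` for ``Ihat > 1/2`` and
    quiescence below.
    """
    if Ihat <= 0.5:
        return 0.0
    return np.sqrt(2.0 * Ihat - 1.0) / (2.0 * np.pi * tau)
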