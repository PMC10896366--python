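"""Exact mean-field reduction of the two-population QIF PING network.

In the infinite-size limit, with Lorentzian-distributed synaptic strengths
and tonic drives, the density of membrane states of each population stays
Lorentzian (Ott-Antonsen manifold) and the network closes into seven
coupled ODEs: firing rate and mean potential for the excitatory (RSE) and
inhibitory (FSI) populations, plus three global gating variables (AMPA,
GABA, NMDA).

State vector order: ``[r_e, u_e, s_e, r_i, u_i, s_i, s_n]`` with rates in
1/ms and time in ms.

The quenched-heterogeneity terms enter through ``|u - Vhat|`` (rate
equations) and ``sgn(Vhat - u)`` (potential equations): the sign factors
are fixed by requiring the rate flow to point inward at r = 0, so rates
stay nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import ReducedParams

__all__ = [
    "MeanFieldState",
    "STATE_NAMES",
    "mean_field_rhs",
    "rhs",
    "jacobian_matrix",
    "integrate_mean_field",
    "Trajectory",
    "default_initial_state",
]

STATE_NAMES = ("r_e", "u_e", "s_e", "r_i", "u_i", "s_i", "s_n")
TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class MeanFieldState:
    """Macroscopic state: rates (1/ms), mean potentials, gating fractions."""

    r_e: float
    u_e: float
    s_e: float
    r_i: float
    u_i: float
    s_i: float
    s_n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r_e, self.u_e, self.s_e,
                         self.r_i, self.u_i, self.s_i, self.s_n])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "MeanFieldState":
        return cls(*(float(v) for v in x))


def default_initial_state() -> MeanFieldState:
    """Small positive rates, potentials at rest (u = -1), gates closed."""
    return MeanFieldState(1e-3, -1.0, 0.0, 1e-3, -1.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# packed constants: one flat array so rhs/jacobian stay allocation-light
# ---------------------------------------------------------------------------

def _pack(p: ReducedParams) -> np.ndarray:
    c, k, d = p.coupling, p.kinetics, p.drive
    return np.array([
        p.tau, p.Vhat_ex, p.Vhat_in,
        c.gbar_e_ampa, c.gbar_e_nmda, c.gbar_e_gaba,
        c.gbar_i_ampa, c.gbar_i_nmda, c.gbar_i_gaba,
        c.gamma_e_ampa, c.gamma_e_nmda, c.gamma_e_gaba,
        c.gamma_i_ampa, c.gamma_i_nmda, c.gamma_i_gaba,
        d.Ibar_e, d.Delta_e, d.Ibar_i, d.Delta_i,
        k.tau_e, k.tau_n, k.tau_i, k.a_n,
    ])


def _rhs_packed(x: np.ndarray, pk: np.ndarray) -> np.ndarray:
    (tau, vex, vin,
     gee, gen, gei, gie, gin, gii,
     yee, yen, yei, yie, yin_, yii,
     Ie, De, Ii, Di,
     tau_e, tau_n, tau_i, a_n) = pk
    r_e, u_e, s_e, r_i, u_i, s_i, s_n = x

    out = np.empty(7)
    two_pi_tau2 = TWO_PI * tau * tau
    for (ir, iu, r, u, ga, gn_, gg, ya, yn, yg, Ibar, Delta) in (
        (0, 1, r_e, u_e, gee, gen, gei, yee, yen, yei, Ie, De),
        (3, 4, r_i, u_i, gie, gin, gii, yie, yin_, yii, Ii, Di),
    ):
        g_ex = ga * s_e + gn_ * s_n          # mean conductance toward Vhat_ex
        g_in = gg * s_i                      # mean conductance toward Vhat_in
        h_ex = ya * s_e + yn * s_n           # heterogeneity half-widths, excit.
        h_in = yg * s_i
        abs_ex = abs(u - vex)
        abs_in = abs(u - vin)
        out[ir] = (r * u - (g_ex + g_in) * r) / tau \
            + (Delta + h_ex * abs_ex + h_in * abs_in) / two_pi_tau2
        out[iu] = (0.5 * u * u - g_ex * (u - vex) - g_in * (u - vin)
                   + Ibar - 0.5) / tau \
            - 2.0 * np.pi ** 2 * tau * r * r \
            + TWO_PI * r * (h_ex * np.sign(vex - u) + h_in * np.sign(vin - u))
    out[2] = -s_e / tau_e + r_e
    out[5] = -s_i / tau_i + r_i
    out[6] = a_n * s_e * (1.0 - s_n) - s_n / tau_n
    return out


def _jac_packed(x: np.ndarray, pk: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of :func:`_rhs_packed`.

    The |u - Vhat| and sgn(Vhat - u) terms are differentiated piecewise;
    away from the measure-zero switching manifolds (u = Vhat_ex, u =
    Vhat_in) the expressions below are exact.
    """
    (tau, vex, vin,
     gee, gen, gei, gie, gin, gii,
     yee, yen, yei, yie, yin_, yii,
     Ie, De, Ii, Di,
     tau_e, tau_n, tau_i, a_n) = pk
    r_e, u_e, s_e, r_i, u_i, s_i, s_n = x

    J = np.zeros((7, 7))
    two_pi_tau2 = TWO_PI * tau * tau
    for (ir, iu, r, u, ga, gn_, gg, ya, yn, yg) in (
        (0, 1, r_e, u_e, gee, gen, gei, yee, yen, yei),
        (3, 4, r_i, u_i, gie, gin, gii, yie, yin_, yii),
    ):
        g_ex = ga * s_e + gn_ * s_n
        g_in = gg * s_i
        h_ex = ya * s_e + yn * s_n
        h_in = yg * s_i
        sg_ex = np.sign(u - vex)             # d|u - vex| / du
        sg_in = np.sign(u - vin)
        # rate equation
        J[ir, ir] = (u - g_ex - g_in) / tau
        J[ir, iu] = r / tau + (h_ex * sg_ex + h_in * sg_in) / two_pi_tau2
        J[ir, 2] = -ga * r / tau + ya * abs(u - vex) / two_pi_tau2
        J[ir, 5] = -gg * r / tau + yg * abs(u - vin) / two_pi_tau2
        J[ir, 6] = -gn_ * r / tau + yn * abs(u - vex) / two_pi_tau2
        # potential equation
        J[iu, ir] = -4.0 * np.pi ** 2 * tau * r \
            + TWO_PI * (-h_ex * sg_ex - h_in * sg_in)
        J[iu, iu] = (u - g_ex - g_in) / tau
        J[iu, 2] = -ga * (u - vex) / tau - TWO_PI * r * ya * sg_ex
        J[iu, 5] = -gg * (u - vin) / tau - TWO_PI * r * yg * sg_in
        J[iu, 6] = -gn_ * (u - vex) / tau - TWO_PI * r * yn * sg_ex
    J[2, 0] = 1.0
    J[2, 2] = -1.0 / tau_e
    J[5, 3] = 1.0
    J[5, 5] = -1.0 / tau_i
    J[6, 2] = a_n * (1.0 - s_n)
    J[6, 6] = -a_n * s_e - 1.0 / tau_n
    return J


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

def rhs(x: np.ndarray, p: ReducedParams) -> np.ndarray:
    """Time derivative of the 7D state as a plain array."""
    return _rhs_packed(np.asarray(x, dtype=float), _pack(p))


def mean_field_rhs(x: MeanFieldState, p: ReducedParams) -> MeanFieldState:
    """Time derivative of the macroscopic state (dataclass in/out)."""
    return MeanFieldState.from_array(rhs(x.as_array(), p))


def jacobian_matrix(x: np.ndarray, p: ReducedParams) -> np.ndarray:
    """Analytic 7x7 Jacobian of the reduced system at state ``x``."""
    return _jac_packed(np.asarray(x, dtype=float), _pack(p))


@dataclass(frozen=True)
class Trajectory:
    """Dense-output samples of an integration (time in ms, rates in 1/ms)."""

    t: np.ndarray
    x: np.ndarray        # shape (len(t), 7), columns follow STATE_NAMES

    def __getitem__(self, name: str) -> np.ndarray:
        return self.x[:, STATE_NAMES.index(name)]

    def rate_hz(self, pop: str = "e") -> np.ndarray:
        """Population rate in Hz (model rates are per ms)."""
        return 1000.0 * self[f"r_{pop}"]

    def final_state(self) -> MeanFieldState:
        return MeanFieldState.from_array(self.x[-1])


def integrate_mean_field(
    p: ReducedParams,
    x0: MeanFieldState | np.ndarray | None = None,
    duration: float = 3000.0,
    dt_out: float = 1.0,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "RK45",
    check_potential_window: bool = True,
) -> Trajectory:
    """Integrate the reduced system with adaptive stepping and dense output.

    Parameters
    ----------
    p : ReducedParams
    x0 : initial state; defaults to :func:`default_initial_state`.
    duration : total time (ms).
    dt_out : dense-output sampling step (ms).
    rtol, atol : integration tolerances.
    check_potential_window : verify post hoc that the mean potentials never
        crossed the synaptic reversal levels (the nonsmooth manifolds of
        the right-hand side); a crossing is reported, not fatal.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if x0 is None:
        x0 = default_initial_state()
    x0a = x0.as_array() if isinstance(x0, MeanFieldState) else np.asarray(x0, float)
    pk = _pack(p)
    t_eval = np.arange(0.0, duration + 0.5 * dt_out, dt_out)
    sol = solve_ivp(
        lambda t, x: _rhs_packed(x, pk),
        (0.0, duration),
        x0a,
        t_eval=t_eval,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last_t = sol.t[-1] if len(sol.t) else 0.0
        raise RuntimeError(f"mean-field integration failed at t={last_t:.3f} ms: "
                           f"{sol.message}")
    x = sol.y.T
    if not np.all(np.isfinite(x)):
        bad = np.argmax(~np.all(np.isfinite(x), axis=1))
        raise RuntimeError(f"non-finite state at t={sol.t[bad]:.3f} ms")
    if check_potential_window:
        for iu in (1, 4):
            u = x[:, iu]
            if np.any(u >= p.Vhat_ex) or np.any(u <= p.Vhat_in):
                import warnings
                warnings.warn(
                    "mean potential crossed a synaptic reversal level; the "
                    "piecewise-smooth terms switched branch", RuntimeWarning)
                break
    return Trajectory(t=sol.t, x=x)
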