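"""Equilibria, eigenvalues and Hopf bifurcations of the reduced system.

Gamma oscillations in the reduced PING model are born and die in Hopf
bifurcations: a complex-conjugate eigenvalue pair of the 7x7 Jacobian at
the equilibrium crosses the imaginary axis as a synaptic parameter varies.
The scans here continue the equilibrium along a parameter grid, monitor
the largest real part over the complex eigenvalues, and refine each sign
change by scalar root finding, so every reported Hopf point carries an
eigenvalue certificate (|Re lambda| below tolerance, omega > 0).

Pseudo-arclength continuation is unnecessary at this dimension: Newton
iterations seeded by the previous grid point are robust and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .meanfield import (MeanFieldState, Trajectory, _pack, _rhs_packed,
                        _jac_packed, integrate_mean_field, default_initial_state)
from .params import ReducedParams

__all__ = [
    "HopfPoint", "HopfCurve", "EquilibriumNotFound",
    "find_equilibrium", "jacobian", "max_complex_eig",
    "hopf_scan_1d", "hopf_curve_2d", "oscillation_amplitude",
    "oscillatory_fraction",
]

RHS_TOL = 1e-10
HOPF_RE_TOL = 1e-6


class EquilibriumNotFound(RuntimeError):
    pass


@dataclass(frozen=True)
class HopfPoint:
    """A certified Hopf bifurcation along one parameter.

    ``direction`` is ``"onset"`` when the eigenpair moves into the right
    half-plane as the parameter increases (oscillation born with increasing
    parameter) and ``"offset"`` otherwise.
    """

    parameter: str
    value: float
    state: MeanFieldState
    eigenvalue: complex            # member of the critical pair with Im > 0
    direction: str
    tol: float = 1e-4

    @property
    def omega(self) -> float:
        return float(self.eigenvalue.imag)

    @property
    def frequency_hz(self) -> float:
        """Emergent oscillation frequency at criticality (time unit is ms)."""
        return self.omega / (2.0 * np.pi) * 1000.0


@dataclass(frozen=True)
class HopfCurve:
    """Two-parameter Hopf locus: certified y-critical values on an x grid."""

    x_parameter: str
    y_parameter: str
    points: tuple[HopfPoint, ...]
    x_values: tuple[float, ...]
    gaps: tuple[float, ...] = field(default_factory=tuple)   # x with no root
    context: str = ""

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array(self.x_values), np.array([p.value for p in self.points]))


# ---------------------------------------------------------------------------

def _gates_of_rates(p: ReducedParams, r_e: float, r_i: float):
    """Gate values slaved to the rates at equilibrium."""
    k = p.kinetics
    s_e = k.tau_e * r_e
    s_i = k.tau_i * r_i
    s_n = k.a_n * s_e / (k.a_n * s_e + 1.0 / k.tau_n)
    return s_e, s_i, s_n


def _full_state(p: ReducedParams, y: np.ndarray) -> np.ndarray:
    z_e, u_e, z_i, u_i = y
    r_e, r_i = np.exp(z_e), np.exp(z_i)
    s_e, s_i, s_n = _gates_of_rates(p, r_e, r_i)
    return np.array([r_e, u_e, s_e, r_i, u_i, s_i, s_n])


def find_equilibrium(
    p: ReducedParams,
    guess: MeanFieldState | np.ndarray | None = None,
    *,
    tol: float = RHS_TOL,
    max_iter: int = 200,
) -> MeanFieldState:
    """Newton-solve the reduced system for its physical equilibrium.

    The three gates are slaved to the rates by their equilibrium relations
    and the rates are solved in log space, so the search stays on the
    physical branch (r > 0): the full 7D system also has spurious
    negative-rate equilibria that a naive root search can land on.
    Requires the heterogeneity/drive source terms to be positive (Delta or
    gamma > 0), which holds for every reference-configuration sweep.

    Raises :class:`EquilibriumNotFound` if the residual cannot be driven
    below ``tol`` (callers doing continuation catch this and reseed).
    """
    pk = _pack(p)
    if guess is None:
        guess = _relaxed_guess(p)
    x0 = guess.as_array() if isinstance(guess, MeanFieldState) else np.asarray(guess, float)
    r_floor = 1e-12
    y0 = np.array([np.log(max(x0[0], r_floor)), x0[1],
                   np.log(max(x0[3], r_floor)), x0[4]])
    k = p.kinetics

    def residual(y: np.ndarray) -> np.ndarray:
        f = _rhs_packed(_full_state(p, y), pk)
        return f[[0, 1, 3, 4]]

    def jac(y: np.ndarray) -> np.ndarray:
        x = _full_state(p, y)
        J = _jac_packed(x, pk)[[0, 1, 3, 4], :]
        r_e, _, s_e, r_i = x[0], x[1], x[2], x[3]
        dsn_dse = k.a_n / k.tau_n / (k.a_n * s_e + 1.0 / k.tau_n) ** 2
        D = np.zeros((7, 4))            # dx/dy
        D[0, 0] = r_e
        D[2, 0] = k.tau_e * r_e
        D[6, 0] = dsn_dse * k.tau_e * r_e
        D[1, 1] = 1.0
        D[3, 2] = r_i
        D[5, 2] = k.tau_i * r_i
        D[4, 3] = 1.0
        return J @ D

    y = None
    for attempt in ("hybr", "lm", "relaxed"):
        if attempt == "relaxed":
            g = _relaxed_guess(p).as_array()
            y_try = np.array([np.log(max(g[0], r_floor)), g[1],
                              np.log(max(g[3], r_floor)), g[4]])
            sol = optimize.root(residual, y_try, jac=jac, method="hybr",
                                options={"maxfev": max_iter * 8, "xtol": 1e-13})
        else:
            sol = optimize.root(residual, y0, jac=jac, method=attempt)
        y = sol.x
        if np.linalg.norm(residual(y)) < 1e-8:
            break
    for _ in range(4):                       # Newton polish to machine residual
        f = residual(y)
        if np.linalg.norm(f) < 1e-14:
            break
        try:
            y = y - np.linalg.solve(jac(y), f)
        except np.linalg.LinAlgError:
            break
    x = _full_state(p, y)
    res = np.linalg.norm(_rhs_packed(x, pk))
    if res > tol:     # judged on the residual: hybr's own flag is conservative
        raise EquilibriumNotFound(
            f"no equilibrium: residual {res:.2e} > {tol:.0e} ({sol.message})")
    return MeanFieldState.from_array(x)


def _relaxed_guess(p: ReducedParams, t_relax: float = 1200.0) -> MeanFieldState:
    """Integrate forward and average the attractor.

    On the equilibrium side this converges to the equilibrium itself; on
    the oscillatory side the cycle average is a good seed for the unstable
    focus inside the orbit.
    """
    traj = integrate_mean_field(p, default_initial_state(), duration=t_relax,
                                dt_out=1.0, rtol=1e-6, atol=1e-9,
                                check_potential_window=False)
    tail = traj.x[traj.t >= 0.5 * t_relax]
    return MeanFieldState.from_array(tail.mean(axis=0))


def jacobian(p: ReducedParams, x: MeanFieldState | np.ndarray,
             *, manifold_tol: float = 1e-8) -> np.ndarray:
    """Analytic Jacobian at ``x``; asserts distance from the switching sets."""
    xa = x.as_array() if isinstance(x, MeanFieldState) else np.asarray(x, float)
    for iu in (1, 4):
        d = min(abs(xa[iu] - p.Vhat_ex), abs(xa[iu] - p.Vhat_in))
        if d < manifold_tol:
            raise ValueError(
                f"state is within {d:.1e} of a |u - Vhat| switching manifold; "
                "the Jacobian is not defined there")
    return _jac_packed(xa, _pack(p))


def max_complex_eig(p: ReducedParams, x: MeanFieldState) -> complex:
    """Eigenvalue with the largest real part among the complex pairs.

    Returns the member with positive imaginary part.  Real eigenvalues are
    ignored: Hopf detection tracks oscillatory instabilities only.
    """
    lam = np.linalg.eigvals(jacobian(p, x))
    cplx = lam[np.abs(lam.imag) > 1e-12]
    if cplx.size == 0:
        return complex(-np.inf, 0.0)
    lead = cplx[np.argmax(cplx.real)]
    return complex(lead.real, abs(lead.imag))


# ---------------------------------------------------------------------------
# 1D scan
# ---------------------------------------------------------------------------

def _equilibrium_along(p: ReducedParams, name: str, value: float,
                       guess: MeanFieldState | None) -> MeanFieldState:
    pv = p.with_param(name, value)
    try:
        return find_equilibrium(pv, guess)
    except EquilibriumNotFound:
        return find_equilibrium(pv, None)    # reseed from relaxation


def hopf_scan_1d(
    p: ReducedParams,
    name: str,
    lo: float,
    hi: float,
    n_grid: int = 200,
    tol: float = 1e-4,
) -> list[HopfPoint]:
    """Certified Hopf points of one parameter over ``[lo, hi]``.

    Continues the equilibrium across the grid (each solution seeds the
    next), brackets sign changes of the leading complex eigenvalue's real
    part, refines them with Brent's method, and certifies each root.
    When an inverted-U exists, onset and offset are both returned, in
    parameter order.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got {lo}, {hi}")
    grid = np.linspace(lo, hi, n_grid)
    re_parts = np.empty(n_grid)
    eq_cache: list[MeanFieldState] = []
    guess: MeanFieldState | None = None
    for k, v in enumerate(grid):
        eq = _equilibrium_along(p, name, v, guess)
        eq_cache.append(eq)
        re_parts[k] = max_complex_eig(p.with_param(name, v), eq).real
        guess = eq

    points: list[HopfPoint] = []
    for k in range(n_grid - 1):
        a, b = re_parts[k], re_parts[k + 1]
        if not (np.isfinite(a) and np.isfinite(b)) or a == 0.0 or a * b >= 0.0:
            continue
        points.append(_refine_hopf(p, name, grid[k], grid[k + 1],
                                   eq_cache[k], tol))
    return points


def _refine_hopf(p: ReducedParams, name: str, lo: float, hi: float,
                 seed: MeanFieldState, tol: float) -> HopfPoint:
    guess_holder = {"x": seed}

    def re_lead(v: float) -> float:
        eq = _equilibrium_along(p, name, v, guess_holder["x"])
        guess_holder["x"] = eq
        return max_complex_eig(p.with_param(name, v), eq).real

    root = optimize.brentq(re_lead, lo, hi, xtol=min(tol, 1e-9) * 1e-4,
                           rtol=8.9e-16)
    eq = _equilibrium_along(p, name, root, guess_holder["x"])
    lam = max_complex_eig(p.with_param(name, root), eq)
    # crossing direction from a one-grid-step secant
    h = max(1e-6, (hi - lo) * 0.5)
    lam_right = max_complex_eig(
        p.with_param(name, root + h),
        _equilibrium_along(p, name, root + h, eq)).real
    direction = "onset" if lam_right > lam.real else "offset"
    if abs(lam.real) > HOPF_RE_TOL or lam.imag <= 0:
        raise RuntimeError(
            f"Hopf certificate failed at {name}={root:.6g}: lambda={lam:.3e}")
    return HopfPoint(parameter=name, value=float(root), state=eq,
                     eigenvalue=lam, direction=direction, tol=tol)


# ---------------------------------------------------------------------------
# 2D curve
# ---------------------------------------------------------------------------

def hopf_curve_2d(
    p: ReducedParams,
    x_name: str,
    x_grid: np.ndarray,
    y_name: str,
    y_lo: float,
    y_hi: float,
    *,
    n_grid_y: int = 60,
    tol: float = 1e-4,
    context: str = "",
    which: str = "last",
) -> HopfCurve:
    """Trace the Hopf locus y_c(x) over ``x_grid`` by certified 1D scans.

    ``which`` selects the root reported when a vertical section crosses
    the locus more than once (``"first"``/``"last"`` in y order).  x values
    whose section has no sign change are recorded as gaps, never
    interpolated.
    """
    points: list[HopfPoint] = []
    xs: list[float] = []
    gaps: list[float] = []
    for xv in np.asarray(x_grid, dtype=float):
        px = p.with_param(x_name, xv)
        roots = hopf_scan_1d(px, y_name, y_lo, y_hi, n_grid=n_grid_y, tol=tol)
        if not roots:
            gaps.append(float(xv))
            continue
        pt = roots[0] if which == "first" else roots[-1]
        # independent re-verification of the certificate at the vertex
        eq = find_equilibrium(px.with_param(y_name, pt.value), pt.state)
        lam = max_complex_eig(px.with_param(y_name, pt.value), eq)
        if abs(lam.real) > HOPF_RE_TOL:
            raise RuntimeError(
                f"2D vertex failed re-verification at {x_name}={xv:.4g}, "
                f"{y_name}={pt.value:.4g}: Re lambda = {lam.real:.2e}")
        points.append(pt)
        xs.append(float(xv))
    return HopfCurve(x_parameter=x_name, y_parameter=y_name,
                     points=tuple(points), x_values=tuple(xs),
                     gaps=tuple(gaps), context=context)


def oscillatory_fraction(
    p: ReducedParams,
    x_name: str,
    x_grid: np.ndarray,
    y_name: str,
    y_grid: np.ndarray,
) -> float:
    """Fraction of an (x, y) parameter grid whose equilibrium is an
    unstable focus (i.e. supports oscillations).

    Used to compare oscillation-supporting areas across conditions on a
    fixed grid; the equilibrium is continued down each grid column.  Grid
    cells where no equilibrium can be found are counted as
    non-oscillatory.
    """
    hits = 0
    for xv in np.asarray(x_grid, float):
        px = p.with_param(x_name, float(xv))
        guess: MeanFieldState | None = None
        for yv in np.asarray(y_grid, float):
            try:
                eq = _equilibrium_along(px, y_name, float(yv), guess)
                guess = eq
            except EquilibriumNotFound:
                guess = None
                continue
            lam = max_complex_eig(px.with_param(y_name, float(yv)), eq)
            if lam.real > 0:
                hits += 1
    return hits / (len(x_grid) * len(y_grid))


# ---------------------------------------------------------------------------
# attractor amplitude (bifurcation-diagram ordinate)
# ---------------------------------------------------------------------------

def oscillation_amplitude(
    p: ReducedParams,
    *,
    transient: float = 1500.0,
    window: float = 1000.0,
    dt_out: float = 0.5,
    noise_floor: float = 2e-5,
    x0: MeanFieldState | None = None,
    rtol: float = 1e-8,
) -> tuple[float, float]:
    """(min, max) of the excitatory rate over the post-transient attractor.

    On the equilibrium side of a Hopf the reported span collapses below
    ``noise_floor`` (default 2e-5/ms, i.e. 0.02 Hz - far below any limit
    cycle of interest but above the residue of slowly decaying transients)
    and is clamped to zero width.
    """
    traj = integrate_mean_field(p, x0, duration=transient + window,
                                dt_out=dt_out, rtol=rtol,
                                check_potential_window=False)
    sel = traj.t >= transient
    r = traj["r_e"][sel]
    lo, hi = float(r.min()), float(r.max())
    if hi - lo < noise_floor:
        mid = 0.5 * (hi + lo)
        return mid, mid
    return lo, hi
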