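"""Healthy/schizophrenia synaptic states, gamma-deficit synergy, calibration.

Postmortem findings motivate three synaptic alterations in schizophrenia
(SZ): lower E->I strength (AMPA and NMDA conductance means onto FSIs,
moved together at a fixed 1:10 NMDA:AMPA ratio), greater E->I variability
(the two matching Lorentzian half-widths), and lower I->E strength (GABA
conductance mean onto RSEs).  Strengths scale down and variabilities scale
up by a common percent difference; a scalar lambda interpolates linearly
between the healthy (lambda=0) and SZ (lambda=1) states.

The synergy analysis compares the gamma-power deficit of each alteration
alone with the deficit of all three applied together; a combined deficit
exceeding the additive prediction (the sum of the individual deficits)
marks a super-additive, synergistic interaction.

Because the baseline biophysical constants behind the published sweep
landmarks are free, :func:`calibrate_reference` fits a chosen subset of
them so the model reproduces a list of published 1D landmarks (Hopf
locations and gamma-power peak locations); the shipped reference
configuration is the frozen product of that fit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .bifurcation import hopf_scan_1d
from .meanfield import integrate_mean_field
from .params import ReducedParams
from .spectral import gamma_power_of_trace

__all__ = [
    "HEALTHY_STATE", "STRENGTH_KEYS", "VARIABILITY_KEYS", "CONDITIONS",
    "PowerSettings", "DiseaseScaling", "SynergyResult", "Landmark",
    "PRINTED_LANDMARKS", "lambda_scale", "apply_percent_difference", "sz_state",
    "gamma_power_at", "healthy_state_search", "synergy_analysis",
    "landmark_values", "calibrate_reference",
]

#: Healthy-state synaptic parameters (the gamma-power optimum of the
#: two-dimensional strength search with half-widths pinned at 0.01).
HEALTHY_STATE: dict[str, float] = {
    "gbar_i_ampa": 1.3,
    "gbar_i_nmda": 0.13,
    "gbar_e_gaba": 0.6,
    "gamma_i_ampa": 0.01,
    "gamma_i_nmda": 0.01,
}

STRENGTH_KEYS = ("gbar_i_ampa", "gbar_i_nmda", "gbar_e_gaba")
VARIABILITY_KEYS = ("gamma_i_ampa", "gamma_i_nmda")

#: Condition name -> parameters moved to their SZ values in that condition.
CONDITIONS: dict[str, tuple[str, ...]] = {
    "ei_strength": ("gbar_i_ampa", "gbar_i_nmda"),
    "ei_variability": ("gamma_i_ampa", "gamma_i_nmda"),
    "ie_strength": ("gbar_e_gaba",),
    "combined": ("gbar_i_ampa", "gbar_i_nmda", "gbar_e_gaba",
                 "gamma_i_ampa", "gamma_i_nmda"),
}


def lambda_scale(x_h: float, x_sz: float, lam: float) -> float:
    """Interpolate a parameter between healthy (lam=0) and SZ (lam=1)."""
    return x_h + lam * (x_sz - x_h)


def apply_percent_difference(healthy: dict[str, float], pct: float) -> dict[str, float]:
    """SZ values at a uniform percent difference from the healthy state.

    Strength means scale by (1 - pct/100); variability half-widths scale by
    (1 + pct/100), matching the directionality of the postmortem findings.
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"pct must be in [0, 100], got {pct}")
    out = {}
    for k, v in healthy.items():
        if k.startswith("gbar"):
            out[k] = v * (1.0 - pct / 100.0)
        elif k.startswith("gamma"):
            out[k] = v * (1.0 + pct / 100.0)
        else:
            raise KeyError(f"cannot classify parameter {k!r} as strength/variability")
    return out


def sz_state(pct: float = 20.0) -> dict[str, float]:
    """The SZ parameter state at a given percent difference (default 20%)."""
    return apply_percent_difference(HEALTHY_STATE, pct)


@dataclass(frozen=True)
class DiseaseScaling:
    """Healthy/SZ endpoint pairs with lambda interpolation per parameter."""

    healthy: dict[str, float]
    sz: dict[str, float]
    pct: float

    @classmethod
    def at_percent(cls, pct: float,
                   healthy: dict[str, float] | None = None) -> "DiseaseScaling":
        h = dict(healthy if healthy is not None else HEALTHY_STATE)
        return cls(healthy=h, sz=apply_percent_difference(h, pct), pct=pct)

    def at_lambda(self, lam: float, keys: tuple[str, ...] | None = None) -> dict[str, float]:
        keys = keys if keys is not None else tuple(self.healthy)
        return {k: lambda_scale(self.healthy[k], self.sz[k], lam) for k in keys}


# ---------------------------------------------------------------------------
# frozen gamma-power protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSettings:
    """Integration + spectral settings shared by every condition of a run.

    Freezing these (and asserting the hash match across conditions) makes
    power differences attributable to synaptic parameters only.
    """

    duration: float = 3000.0
    dt_out: float = 1.0           # ms -> fs = 1000 Hz
    rtol: float = 1e-8
    transient_discard: float = 500.0
    nperseg: int = 1024
    band: tuple[float, float] = (30.0, 100.0)
    metric: str = "amplitude"

    @property
    def fs(self) -> float:
        return 1000.0 / self.dt_out

    def config_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


def gamma_power_at(p: ReducedParams,
                   settings: PowerSettings = PowerSettings()) -> tuple[float, float | None]:
    """Gamma power and peak frequency of the excitatory rate at ``p``."""
    traj = integrate_mean_field(p, duration=settings.duration,
                                dt_out=settings.dt_out, rtol=settings.rtol,
                                check_potential_window=False)
    return gamma_power_of_trace(traj["r_e"], fs=settings.fs,
                                transient_discard=settings.transient_discard,
                                band=settings.band, nperseg=settings.nperseg,
                                metric=settings.metric)


# ---------------------------------------------------------------------------
# healthy-state grid search
# ---------------------------------------------------------------------------

def healthy_state_search(
    p: ReducedParams,
    g_ei_grid: np.ndarray,
    g_ie_grid: np.ndarray,
    *,
    ratio: float = 0.1,
    gamma_value: float = 0.01,
    settings: PowerSettings = PowerSettings(),
) -> tuple[dict[str, float], np.ndarray]:
    """Grid-search (E->I, I->E) strengths for maximal gamma power.

    The NMDA E->I mean tracks the AMPA mean at the fixed ``ratio`` (1:10 by
    default); all three manipulated half-widths are pinned at
    ``gamma_value``.  Returns the argmax parameter set and the full power
    surface (shape ``(len(g_ei_grid), len(g_ie_grid))``).  Ties break
    toward smaller parameter values (ascending scan, strict improvement).
    """
    base = p.with_params({"gamma_i_ampa": gamma_value, "gamma_i_nmda": gamma_value,
                          "gamma_e_gaba": gamma_value})
    surface = np.zeros((len(g_ei_grid), len(g_ie_grid)))
    best = (-np.inf, None, None)
    for a, gei in enumerate(g_ei_grid):
        for b, gie in enumerate(g_ie_grid):
            pv = base.with_params({"gbar_i_ampa": gei, "gbar_i_nmda": ratio * gei,
                                   "gbar_e_gaba": gie})
            power, _ = gamma_power_at(pv, settings)
            surface[a, b] = power
            if power > best[0]:
                best = (power, float(gei), float(gie))
    if not best[0] > 0:
        raise RuntimeError("no oscillation anywhere on the searched grid")
    _, gei, gie = best
    return ({"gbar_i_ampa": gei, "gbar_i_nmda": ratio * gei, "gbar_e_gaba": gie,
             "gamma_i_ampa": gamma_value, "gamma_i_nmda": gamma_value},
            surface)


# ---------------------------------------------------------------------------
# synergy pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynergyResult:
    """Per-percent gamma-power deficits and the synergy summary."""

    pct: float
    baseline_power: float
    powers: dict[str, float]            # per condition
    deficits: dict[str, float]          # percent of baseline, per condition
    additive: float                     # sum of the three individual deficits
    combined: float                     # deficit of the combined condition
    fold_ratio: float | None            # combined / additive, None if additive <= 0
    settings_hash: str = ""


def synergy_analysis(
    p: ReducedParams,
    pct_grid,
    *,
    healthy: dict[str, float] | None = None,
    settings: PowerSettings = PowerSettings(),
) -> list[SynergyResult]:
    """Run the four-condition deficit analysis at each percent difference.

    ``p`` must already sit at the healthy state (its coupling block is
    overwritten with ``healthy`` for the baseline).  Every condition of
    every percent uses the identical frozen :class:`PowerSettings`.
    """
    h = dict(healthy if healthy is not None else HEALTHY_STATE)
    p_h = p.with_params(h)
    P_h, _ = gamma_power_at(p_h, settings)
    if not P_h > 0:
        raise RuntimeError("baseline (healthy) configuration does not oscillate")
    out = []
    for pct in np.atleast_1d(np.asarray(pct_grid, dtype=float)):
        sz = apply_percent_difference(h, float(pct))
        powers: dict[str, float] = {}
        deficits: dict[str, float] = {}
        for cond, keys in CONDITIONS.items():
            pv = p_h.with_params({k: sz[k] for k in keys})
            P_c, _ = gamma_power_at(pv, settings)
            powers[cond] = P_c
            deficits[cond] = 100.0 * (P_h - P_c) / P_h
        additive = sum(deficits[c] for c in ("ei_strength", "ei_variability",
                                             "ie_strength"))
        combined = deficits["combined"]
        fold = combined / additive if additive > 0 else None
        out.append(SynergyResult(pct=float(pct), baseline_power=P_h,
                                 powers=powers, deficits=deficits,
                                 additive=additive, combined=combined,
                                 fold_ratio=fold,
                                 settings_hash=settings.config_hash()))
    return out


# ---------------------------------------------------------------------------
# calibration of the unpublished baseline constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Landmark:
    """One published 1D-sweep feature the calibrated model must reproduce.

    ``kind`` is ``"hopf"`` (certified bifurcation location along
    ``parameter`` inside ``(lo, hi)``; ``which`` picks onset/offset) or
    ``"power_peak"`` (argmax of gamma power over a grid on ``(lo, hi)``,
    refined by a local parabola through the argmax neighbours).
    """

    name: str
    kind: str
    parameter: str
    lo: float
    hi: float
    target: float
    which: str = "first"           # "onset" | "offset" | "first" | "last"
    n_grid: int = 25


PRINTED_LANDMARKS: tuple[Landmark, ...] = (
    Landmark("g_EtoI_onset", "hopf", "gbar_i_ampa", 0.005, 0.83, 0.26, "onset"),
    Landmark("g_NtoI_offset", "hopf", "gbar_i_nmda", 0.0, 0.6, 0.15, "offset"),
    Landmark("g_ItoE_offset", "hopf", "gbar_e_gaba", 0.3, 3.0, 1.52, "offset"),
    Landmark("gamma_EtoI_offset", "hopf", "gamma_i_ampa", 0.011, 3.0, 1.55, "offset"),
    Landmark("gamma_NtoI_offset", "hopf", "gamma_i_nmda", 0.011, 0.25, 0.053, "offset"),
    Landmark("g_EtoI_peak", "power_peak", "gbar_i_ampa", 0.3, 2.0, 0.7, "first", 35),
    Landmark("g_ItoE_peak", "power_peak", "gbar_e_gaba", 0.15, 1.1, 0.68, "first", 20),
)


def _power_peak_location(p: ReducedParams, lm: Landmark,
                         settings: PowerSettings) -> float | None:
    grid = np.linspace(lm.lo, lm.hi, lm.n_grid)
    powers = np.array([gamma_power_at(p.with_param(lm.parameter, v), settings)[0]
                       for v in grid])
    if not np.any(powers > 0):
        return None
    k = int(np.argmax(powers))
    if k == 0 or k == len(grid) - 1:
        return float(grid[k])      # boundary maximum: no interior parabola
    y0, y1, y2 = powers[k - 1: k + 2]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(grid[k])
    step = grid[1] - grid[0]
    return float(grid[k] + 0.5 * step * (y0 - y2) / denom)


def landmark_values(
    p: ReducedParams,
    landmarks: tuple[Landmark, ...] = PRINTED_LANDMARKS,
    *,
    settings: PowerSettings = PowerSettings(),
    hopf_n_grid: int | None = None,
    hopf_tol: float = 1e-6,
) -> dict[str, float | None]:
    """Recompute every landmark on configuration ``p`` (None if absent)."""
    out: dict[str, float | None] = {}
    for lm in landmarks:
        if lm.kind == "hopf":
            pts = hopf_scan_1d(p, lm.parameter, lm.lo, lm.hi,
                               n_grid=hopf_n_grid or lm.n_grid, tol=hopf_tol)
            if lm.which in ("onset", "offset"):
                pts = [q for q in pts if q.direction == lm.which]
            if not pts:
                out[lm.name] = None
            else:
                out[lm.name] = pts[0].value if lm.which != "last" else pts[-1].value
        elif lm.kind == "power_peak":
            out[lm.name] = _power_peak_location(p, lm, settings)
        else:
            raise ValueError(f"unknown landmark kind {lm.kind!r}")
    return out


def calibrate_reference(
    p0: ReducedParams,
    free: tuple[str, ...],
    *,
    landmarks: tuple[Landmark, ...] = PRINTED_LANDMARKS,
    bounds: dict[str, tuple[float, float]] | None = None,
    settings: PowerSettings = PowerSettings(),
    max_nfev: int = 60,
    missing_penalty: float = 3.0,
) -> tuple[ReducedParams, dict[str, float]]:
    """Least-squares fit of free baseline constants to published landmarks.

    Free parameters are optimized in log space (all are positive scales:
    time constants, rates, drive width).  The residual for each landmark is
    the relative mismatch; a landmark that disappears from its sweep range
    contributes ``missing_penalty``.  Returns the calibrated configuration
    and the per-landmark relative residuals.

    An empty ``free`` tuple performs no fit and just reports residuals.
    """
    if not landmarks:
        raise ValueError("need at least one landmark")

    def residuals(logx: np.ndarray) -> np.ndarray:
        pv = p0.with_params({k: float(np.exp(v)) for k, v in zip(free, logx)})
        vals = landmark_values(pv, landmarks, settings=settings)
        res = []
        for lm in landmarks:
            v = vals[lm.name]
            res.append(missing_penalty if v is None
                       else (v - lm.target) / lm.target)
        return np.array(res)

    if free:
        x0 = np.log([p0.get_param(k) for k in free])
        if bounds:
            lo = np.log([bounds.get(k, (1e-8, 1e8))[0] for k in free])
            hi = np.log([bounds.get(k, (1e-8, 1e8))[1] for k in free])
        else:
            lo, hi = -np.inf, np.inf
        fit = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                     max_nfev=max_nfev, diff_step=1e-3)
        p_cal = p0.with_params({k: float(np.exp(v)) for k, v in zip(free, fit.x)})
    else:
        p_cal = p0
    vals = landmark_values(p_cal, landmarks, settings=settings)
    report = {lm.name: (np.nan if vals[lm.name] is None
                        else float((vals[lm.name] - lm.target) / lm.target))
              for lm in landmarks}
    return p_cal, report
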