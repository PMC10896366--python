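"""End-to-end experiment recipes behind ``pingmf run-experiment``.

Each function reproduces one headline analysis on a given configuration
with frozen, desk-scale defaults and writes canonical CSV/JSON into an
output directory, returning the list of files written.  Grids here are
deliberately coarser than the library defaults so a full experiment stays
in the minutes range on one core.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bifurcation import hopf_curve_2d, hopf_scan_1d, oscillation_amplitude
from .meanfield import integrate_mean_field
from .params import ReducedParams
from .qif_net import build_network, population_rate, simulate_network
from .spectral import gamma_power_of_trace
from .synergy import (HEALTHY_STATE, PowerSettings, gamma_power_at, sz_state,
                      synergy_analysis)

__all__ = ["network_validation", "strength_sweeps", "variability_sweeps", "synergy_sweep",
           "hopf2d_panels"]


def network_validation(p: ReducedParams, out: Path, seed: int = 1,
                       duration: float = 2500.0, N_e: int = 800,
                       N_i: int = 200) -> list[str]:
    """Spiking network vs mean-field: rate traces and gamma metrics."""
    out = Path(out)
    traj = integrate_mean_field(p, duration=duration)
    net = build_network(p, N_e=N_e, N_i=N_i, seed=seed)
    rec, _ = simulate_network(net, duration=duration)
    t_b, rate_e = population_rate(rec, "e", bin=1.0, smooth_width=2.0)
    _, rate_i = population_rate(rec, "i", bin=1.0, smooth_width=2.0)
    n = min(len(t_b), len(traj.t))
    pd.DataFrame({
        "t": t_b[:n], "net_rate_e": rate_e[:n], "net_rate_i": rate_i[:n],
        "mf_r_e": traj["r_e"][:n], "mf_r_i": traj["r_i"][:n],
    }).to_csv(out / "rates_comparison.csv", index=False)
    summary = {}
    for label, trace in (("network_e", rate_e), ("meanfield_e", traj["r_e"])):
        power, peak = gamma_power_of_trace(trace, fs=1000.0,
                                           transient_discard=500.0)
        summary[label] = {"gamma_power": power, "peak_frequency_hz": peak}
    with open(out / "gamma_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return ["rates_comparison.csv", "gamma_summary.json"]


def _sweep_with_power(p: ReducedParams, name: str, grid: np.ndarray,
                      settings: PowerSettings) -> pd.DataFrame:
    rows = []
    for v in grid:
        pv = p.with_param(name, float(v))
        power, peak = gamma_power_at(pv, settings)
        lo, hi = oscillation_amplitude(pv)
        rows.append({"value": float(v), "gamma_power": power,
                     "peak_frequency_hz": peak, "amplitude": hi - lo})
    return pd.DataFrame(rows)


def _sweeps(p: ReducedParams, out: Path, specs, tag: str) -> list[str]:
    out = Path(out)
    settings = PowerSettings()
    written = []
    for name, lo, hi, n in specs:
        df = _sweep_with_power(p, name, np.linspace(lo, hi, n), settings)
        fn = f"{tag}_{name}.csv"
        df.to_csv(out / fn, index=False)
        written.append(fn)
        pts = hopf_scan_1d(p, name, lo, hi, n_grid=max(n, 60))
        fn_h = f"{tag}_{name}_hopf.json"
        with open(out / fn_h, "w") as fh:
            json.dump([{"value": q.value, "direction": q.direction,
                        "re_lambda": q.eigenvalue.real,
                        "frequency_hz": q.frequency_hz} for q in pts], fh, indent=1)
        written.append(fn_h)
    return written


def strength_sweeps(p: ReducedParams, out: Path, seed: int = 1) -> list[str]:
    """Gamma power and Hopf points vs the three mean synaptic strengths."""
    return _sweeps(p, out, [("gbar_i_ampa", 0.05, 5.0, 40),
                            ("gbar_i_nmda", 1e-3, 0.3, 30),
                            ("gbar_e_gaba", 0.05, 2.0, 40)], "sweep")


def variability_sweeps(p: ReducedParams, out: Path, seed: int = 1) -> list[str]:
    """Gamma power and Hopf points vs the two E->I half-widths."""
    return _sweeps(p, out, [("gamma_i_ampa", 0.01, 2.0, 30),
                            ("gamma_i_nmda", 0.01, 0.08, 30)], "sweep")


def synergy_sweep(p: ReducedParams, out: Path, seed: int = 1) -> list[str]:
    """Deficit table at 20% plus the percent-difference synergy sweep."""
    out = Path(out)
    grid = np.arange(0.0, 40.0 + 1e-9, 2.5)
    results = synergy_analysis(p, grid)
    rows = [{"pct": r.pct, "deficit_EI": r.deficits["ei_strength"],
             "deficit_var": r.deficits["ei_variability"],
             "deficit_IE": r.deficits["ie_strength"],
             "additive": r.additive, "combined": r.combined,
             "fold_ratio": r.fold_ratio} for r in results]
    pd.DataFrame(rows).to_csv(out / "synergy_sweep.csv", index=False)
    at20 = next(r for r in results if abs(r.pct - 20.0) < 1e-9)
    with open(out / "deficits_at_20pct.json", "w") as fh:
        json.dump({"healthy": HEALTHY_STATE, "sz": sz_state(20.0),
                   "deficits": at20.deficits, "additive": at20.additive,
                   "combined": at20.combined, "fold_ratio": at20.fold_ratio},
                  fh, indent=1)
    return ["synergy_sweep.csv", "deficits_at_20pct.json"]


#: (x, x-range, y, y-range, varied third-parameter group) per panel
_HOPF2D_PANELS = (
    ("gbar_e_gaba", (0.1, 1.6), "gamma_i_ampa", (0.011, 3.0),
     ("gbar_i_ampa", "gbar_i_nmda")),
    ("gbar_i_ampa", (0.1, 2.6), "gamma_i_ampa", (0.011, 3.0),
     ("gbar_e_gaba",)),
    ("gbar_i_ampa", (0.1, 2.6), "gbar_e_gaba", (0.05, 2.5),
     ("gamma_i_ampa", "gamma_i_nmda")),
)


def hopf2d_panels(p: ReducedParams, out: Path, seed: int = 1,
                  n_x: int = 16, pct: float = 20.0) -> list[str]:
    """Two-parameter Hopf curves with the third pathway healthy vs SZ."""
    out = Path(out)
    sz = sz_state(pct)
    written = []
    for k, (xn, xr, yn, yr, third) in enumerate(_HOPF2D_PANELS):
        panel = {}
        for label in ("healthy", "sz"):
            pv = p.with_params({t: (HEALTHY_STATE[t] if label == "healthy"
                                    else sz[t]) for t in third})
            curve = hopf_curve_2d(pv, xn, np.linspace(*xr, n_x), yn, *yr,
                                  n_grid_y=40, context=f"{third}:{label}")
            xs, ys = curve.as_arrays()
            panel[label] = {"x": xs.tolist(), "y_critical": ys.tolist(),
                            "gaps": list(curve.gaps)}
        fn = f"hopf2d_panel{k}_{xn}_vs_{yn}.json"
        with open(out / fn, "w") as fh:
            json.dump({"x": xn, "y": yn, "third": third, **panel}, fh, indent=1)
        written.append(fn)
    return written
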