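"""Two-parameter view of the oscillatory region in health and disease.

Traces a Hopf curve in the (I->E strength, E->I variability) plane with
the E->I strength pathway at its healthy value and again at its 20%
schizophrenia value, and compares the fraction of a marker-centred
parameter window that supports gamma oscillations under each of the
three pathway alterations.
"""

import numpy as np

import pingmf as pm
from pingmf.synergy import HEALTHY_STATE, sz_state

p = pm.synergy_config()
sz = sz_state(20.0)
p_h = p.with_params(HEALTHY_STATE)

print("Hopf curve in the (g_I->E, gamma_E->I) plane, E->I strength "
      "healthy vs SZ:")
x_grid = np.linspace(0.2, 1.1, 6)
for label, vals in (("healthy", HEALTHY_STATE), ("sz", sz)):
    pv = p_h.with_params({k: vals[k] for k in ("gbar_i_ampa", "gbar_i_nmda")})
    curve = pm.hopf_curve_2d(pv, "gbar_e_gaba", x_grid,
                             "gamma_i_ampa", 0.011, 3.0, n_grid_y=25,
                             context=f"E->I strength {label}")
    xs, ys = curve.as_arrays()
    pts = ", ".join(f"({x:.2f}, {y:.3f})" for x, y in zip(xs, ys))
    print(f"  {label:8s}: gamma_E->I critical at {pts}")

print()
print("oscillation-supporting fraction of marker-centred windows:")
n = 11
panels = {
    "E->I strength": (("gbar_i_ampa", "gbar_i_nmda"),
                      "gbar_e_gaba", np.linspace(0.05, 1.2, n),
                      "gamma_i_ampa", np.linspace(0.002, 0.05, n)),
    "I->E strength": (("gbar_e_gaba",),
                      "gbar_i_ampa", np.linspace(0.2, 2.0, n),
                      "gamma_i_ampa", np.linspace(0.002, 0.05, n)),
    "E->I variability": (("gamma_i_ampa", "gamma_i_nmda"),
                         "gbar_i_ampa", np.linspace(0.2, 2.0, n),
                         "gbar_e_gaba", np.linspace(0.05, 1.2, n)),
}
for label, (third, xn, xg, yn, yg) in panels.items():
    f_h = pm.oscillatory_fraction(p_h, xn, xg, yn, yg)
    p_sz = p_h.with_params({k: sz[k] for k in third})
    f_sz = pm.oscillatory_fraction(p_sz, xn, xg, yn, yg)
    print(f"  vary {label:18s}: healthy {f_h:.2f} -> sz {f_sz:.2f} "
          f"(shrinkage {100 * (f_h - f_sz) / f_h:+.1f}%)")

print()
print("Moving any pathway toward its disease value contracts the region "
      "that supports gamma near the healthy operating point, so the "
      "remaining pathways sit closer to the oscillation boundary - the "
      "geometric origin of the super-additive combined deficit.")
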