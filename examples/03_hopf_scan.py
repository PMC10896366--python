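"""Locate the Hopf bifurcations that frame the gamma-oscillatory region.

Scans the mean AMPA E->I conductance (oscillation onset) and the mean
GABA I->E conductance (oscillation offset), printing each certified Hopf
point with its eigenvalue and emergent frequency.
"""

import pingmf as pm

p = pm.reference_config()

for name, lo, hi, label in [
    ("gbar_i_ampa", 0.002, 1.29, "AMPA E->I mean (g_E->I)"),
    ("gbar_e_gaba", 0.61, 4.0, "GABA I->E mean (g_I->E)"),
]:
    points = pm.hopf_scan_1d(p, name, lo, hi, n_grid=60)
    print(f"sweep of {label}:")
    for q in points:
        print(f"  {q.direction:6s} Hopf at {q.value:.4f}  "
              f"(Re lambda = {q.eigenvalue.real:+.1e}, "
              f"emergent frequency {q.frequency_hz:.1f} Hz)")
    if not points:
        print("  no eigenvalue crossing inside the sweep range")
    print()

print("Onset/offset here are where a complex eigenvalue pair of the 7x7 "
      "Jacobian crosses the imaginary axis: gamma oscillations are born "
      "or die in Hopf bifurcations as synaptic strength varies.")
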