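"""Gamma-power deficits of schizophrenia-associated synaptic alterations.

Applies the three postmortem-motivated alterations - lower E->I strength,
greater E->I variability, lower I->E strength - one at a time and all
together at a uniform 20% difference, and compares the combined deficit
with the additive prediction.  Runs on the disease-pipeline calibration,
whose healthy state sits at a gamma-power optimum of the tied strength
search.
"""

import pingmf as pm
from pingmf.synergy import synergy_analysis

p = pm.synergy_config()
res, = synergy_analysis(p, [20.0])

print(f"baseline (healthy) gamma power: {res.baseline_power:.3e} a.u.")
print()
print("condition                     deficit (% of healthy power)")
for cond, label in [("ei_strength", "E->I strength alone"),
                    ("ei_variability", "E->I variability alone"),
                    ("ie_strength", "I->E strength alone"),
                    ("combined", "all three combined")]:
    print(f"  {label:28s} {res.deficits[cond]:6.1f}")
print(f"  {'additive prediction':28s} {res.additive:6.1f}")
print(f"\nfold ratio (combined / additive): {res.fold_ratio:.2f}")
print()
print("A fold ratio above 1 marks synergy: the joint effect of the three "
      "alterations exceeds the sum of their individual effects.")
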