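# pingmf

Exact mean-field dynamics of a pyramidal-interneuron gamma (PING)
circuit, for studying how synaptic alterations reshape cortical gamma
oscillations - in particular the schizophrenia-associated triple of
*lower excitatory drive to fast-spiking interneurons (E->I), greater
variability of that drive, and lower inhibitory feedback to pyramidal
cells (I->E)*.

The package is aimed at computational neuroscientists who want a
desk-scale, fully reproducible pipeline from a spiking network to
bifurcation structure: no data downloads, every headline result is
recomputed from the model.

## What is inside

A network of quadratic integrate-and-fire (QIF) neurons - 800
regular-spiking excitatory cells and 200 fast-spiking interneurons,
all-to-all coupled through AMPA, NMDA and GABA synapses - generates
gamma rhythms by the PING mechanism.  Synaptic strengths `g` and tonic
drives `I` vary across neurons with Lorentzian (Cauchy) distributions
(mode `gbar`, half-width `gamma`).  In the thermodynamic limit the
population density over membrane states stays Lorentzian (the
Ott-Antonsen manifold), and the network reduces *exactly* to seven ODEs
for the firing rates `r_e, r_i`, mean potentials `u_e, u_i`, and gates
`s_e, s_i, s_n`; for the excitatory population:

    tau dr_e/dt = r_e u_e - (g_ee s_e + g_ei s_i + g_en s_n) r_e
                  + [Delta_e + (gamma_ee s_e + gamma_en s_n)|u_e - Vex|
                             + gamma_ei s_i |u_e - Vin|] / (2 pi tau)

    tau du_e/dt = u_e^2/2 - (2 pi tau r_e)^2 / 2 - (synaptic terms)
                  + I_e - 1/2            (and likewise for the FSIs)

Gamma oscillations are born and die in Hopf bifurcations of this system.
Modules:

- `pingmf.qif_net` - the finite spiking network (theta-neuron
  integration, quenched Lorentzian heterogeneity, global gates);
- `pingmf.meanfield` - the 7D reduced system with analytic Jacobian;
- `pingmf.spectral` - gamma power and peak gamma frequency (30-100 Hz);
- `pingmf.bifurcation` - certified Hopf points (1D scans, 2D curves,
  eigenvalue certificates `|Re lambda| < 1e-6`);
- `pingmf.synergy` - healthy/disease parameter states,
  percent-difference scaling, gamma-deficit synergy, and calibration of
  unpublished baseline constants;
- `pingmf.cli` - a thin `pingmf` command (`simulate-mf`, `simulate-qif`,
  `spectrum`, `hopf1d`, `hopf2d`, `synergy`, `calibrate`,
  `run-experiment`).

Two frozen calibrations ship with the package: `reference_config()`
(reproduces the published 1D sweep landmarks) and `synergy_config()`
(the disease pipeline, whose healthy state sits at a gamma-power
optimum).  `docs/methods.md` explains why one constant set cannot serve
both.

## Worked example

```python
import pingmf as pm

p = pm.reference_config()                       # calibrated baseline
traj = pm.integrate_mean_field(p, duration=3000.0)
power, peak = pm.gamma_power_of_trace(traj["r_e"])
print(peak)                                      # 68.4 (Hz)

onset = pm.hopf_scan_1d(p, "gbar_i_ampa", 0.002, 0.83)[0]
print(onset.value, onset.direction)              # 0.2694 onset
```

`python examples/04_synergy_at_20pct.py` prints the disease analysis
(output of the shipped calibration):

```
baseline (healthy) gamma power: 4.966e-02 a.u.

condition                     deficit (% of healthy power)
  E->I strength alone             1.7
  E->I variability alone          6.5
  I->E strength alone            18.1
  all three combined             48.3
  additive prediction            26.2

fold ratio (combined / additive): 1.84
```

Three individually mild synaptic alterations (each a 20% change) jointly
remove about half of the gamma power, far beyond their additive
prediction - a super-additive, synergistic interaction.  `examples/`
holds one short script per capability (mean-field rhythm,
network-vs-mean-field concordance, Hopf scans, the synergy table, 2D
bifurcation structure).

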