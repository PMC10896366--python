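# Methods

## Model

`pingmf` implements a pyramidal-interneuron gamma (PING) circuit of
quadratic integrate-and-fire (QIF) neurons at two levels of description
that share a single parameter set.

**Spiking network.** Two all-to-all coupled populations - regular-spiking
excitatory cells (RSE, N_e) and fast-spiking interneurons (FSI, N_i) -
with membrane dynamics

    C dV/dt = gl (V - Vl)(V - VT)/(VT - Vl) + I_appl - I_syn,

spike/reset at +/- infinity, and synaptic current

    I_syn = (g_e s_e + g_n s_n)(V - Vex) + g_i s_i (V - Vin).

The AMPA (s_e) and GABA (s_i) gates are global first-order filters kicked
by presynaptic spikes; the NMDA gate is logistic, driven by the AMPA gate:
ds_n/dt = a_n s_e (1 - s_n) - s_n / tau_n.  Voltage-dependent magnesium
block of NMDA channels is not modelled (the gate is purely presynaptic),
which is what makes an exact reduction possible.

Potentials are nondimensionalized so that leak reversal and threshold sit
at u = -1, +1; conductances are measured in units of the leak conductance
gl; tau = C/gl is the membrane time constant.  Synaptic strengths (per
postsynaptic cell) and the tonic drive are quenched random variables with
Lorentzian (Cauchy) distributions - drawn once at network construction,
never redrawn - parameterized by a mode (gbar, Ibar) and a half-width
(gamma, Delta).

**Mean-field reduction.** In the limit N -> infinity the population
density over u stays Lorentzian (Ott-Antonsen manifold), and the residue
theorem collapses the heterogeneity integrals, closing the dynamics into
seven ODEs: rate and mean potential for each population plus the three
gates.  The heterogeneity half-widths enter the rate equations through
terms proportional to gamma * s * |u - Vhat| (a positive rate source) and
the potential equations through 2 pi r * gamma * s * sgn(Vhat - u); the
sign convention is fixed by requiring the rate flow to point inward at
r = 0, so rates remain nonnegative along trajectories.  The nonsmooth
|.| and sgn(.) factors are evaluated exactly as written; trajectories of
interest keep the mean potentials strictly between the synaptic reversal
levels, and the integrator logs a warning if a crossing ever occurs.

The finite-network gates are incremented by 1/N_pre per presynaptic spike
(presynaptic-population normalization).  This is the finite-size
counterpart of the mean-field gate equations ds_e/dt = -s_e/tau_e + r_e,
ds_i/dt = -s_i/tau_i + r_i, and is required for the two descriptions to
agree at finite N.

**Integration.** The network uses the theta-neuron change of variables
u = tan(theta/2), which turns the QIF blow-up/reset into a smooth phase
crossing of theta = pi (the drift there is 1/tau > 0, so crossings are
always upward): there is no finite-cutoff frequency bias and spike
detection is exact up to the step.  Fixed-step RK4 with dt = 0.01 tau_e
by default; spike increments are applied at the end of the step in which
the crossing is detected, summed over simultaneous spikes
(order-independent).  The mean-field system is integrated with adaptive
RK45 (rtol 1e-8, atol 1e-10) and dense output.

## Spectral quantification

Peak gamma frequency is the location of the maximum Welch spectral
density of a population-rate trace inside 30-100 Hz.  Frozen estimator
settings: 1 kHz sampling of the rate trace, 500 ms transient discard,
mean subtraction, Hann window, 1024-sample segments, 50% overlap,
4x zero-padding (without padding the sampled peak density scallops by up
to ~15% depending on where the rhythm falls between frequency bins).

Gamma power is the squared half-swing of the post-transient rate trace,
``((max - min)/2)^2``, gated on the spectral peak lying in the band: the
power of an oscillation scales with its squared amplitude, and near
strong oscillation the rate waveform is strongly non-sinusoidal, so its
energy spreads across harmonics - an in-band density readout would
measure waveform sharpness as much as rhythm strength.  In-band peak
density, band-integrated density, and trace variance remain available as
metric flags (`metric="peak" | "integral" | "variance"`).  A silent
trace reports power exactly 0 with an undefined peak frequency.  Power
is in arbitrary units; only peak locations, zero crossings and relative
deficits are meaningful, and every comparison in the disease pipeline
shares one frozen settings object (enforced by a settings hash).  All
metrics vanish together at oscillation boundaries, which is what ties
the power sweeps to the Hopf diagrams.

## Bifurcation analysis

Equilibria are found by Newton iteration on a reduced 4-variable system:
the three gates are slaved to the rates by their equilibrium relations
and the rates are solved in log space, which pins the physical branch
(r > 0) - the full 7D algebraic system also has spurious negative-rate
equilibria.  The returned state satisfies |RHS| < 1e-10.

Hopf points are located by continuation: the equilibrium is tracked
across a parameter grid (each solution seeding the next), the real part
of the leading *complex* eigenvalue pair of the analytic 7x7 Jacobian is
monitored, sign changes are bracketed and refined by Brent root finding
on Re(lambda) as a function of the parameter, and every reported point
carries a certificate |Re lambda| < 1e-6 with omega > 0.  Onset/offset
tags come from the crossing direction.  Two-parameter Hopf curves run one
certified 1D scan per grid column; columns without a crossing are
recorded as gaps, never interpolated.  Pseudo-arclength continuation was
deliberately not used: the system is 7-dimensional and inexpensive, and
grid continuation with certificates is simpler to audit.

## Disease pipeline

The healthy state pins the three manipulated pathways at the gamma-power
optimum of a 2D strength search (AMPA E->I mean x GABA I->E mean, NMDA
E->I tracking AMPA at the empirical 1:10 ratio, all three manipulated
half-widths at 0.01):

    g_E->I = 1.3, g_N->I = 0.13, g_I->E = 0.6,
    gamma_E->I = gamma_N->I = 0.01.

A uniform percent difference p maps healthy to disease values: strength
means scale by (1 - p/100), variability half-widths by (1 + p/100); at
p = 20 this gives 1.04 / 0.104 / 0.48 / 0.012 / 0.012.  (Where a summary
table elsewhere lists the 20%-increased variability as 0.12, that value
is inconsistent with 120% of 0.01; 0.012 is used.)  A scalar lambda
interpolates linearly between the endpoints, exact at lambda = 0 and 1.

Deficits are percentages of healthy baseline power,
100 (P_h - P_c)/P_h, computed per condition (E->I strength alone -
AMPA and NMDA means moved together; E->I variability alone - the two
half-widths together; I->E strength alone; all five combined).  gamma_I->E
stays at 0.01 in every condition.  The additive prediction is the sum of
the three individual deficits; the fold ratio is combined/additive
(undefined when additive <= 0, reported as null).  Oscillation death in a
condition is a 100% deficit, not an error.

## Calibration of baseline constants

The literature values that anchor the 1D sweeps (Hopf locations at
g_E->I = 0.26 onset, g_N->I = 0.15, g_I->E = 1.52, gamma_E->I = 1.55,
gamma_N->I = 0.053 offsets; gamma-power peaks at g_E->I = 0.7 and
g_I->E = 0.68) are conditional on baseline constants that are not
themselves published - neither the biophysical constants (tau, tau_e,
tau_i, tau_n, a_n, Delta_e, the nondimensional reversals, the tonic
drive) nor the baseline coupling values that the sweeps are centred on.
`calibrate_reference` therefore treats a chosen subset of these as free
and minimizes the relative mismatch of the recomputed landmarks (damped
Gauss-Newton in log parameter space; landmarks that vanish from their
sweep window contribute a fixed penalty).

A structural point discovered during calibration: the sweep landmarks
and the healthy-state optimum cannot both hold in one configuration of
this model family.  The healthy state is defined as the gamma-power
argmax of the tied 2D strength search (g_N->I = 0.1 g_E->I, half-widths
at 0.01) at (g_E->I, g_I->E) = (1.3, 0.6) - but a configuration whose
untied g_E->I section peaks at 0.7 and whose g_N->I section declines
monotonically from zero places the healthy point far from any power
optimum (the tied-gradient identity dP/dt = dP/dg_EI + 0.1 dP/dg_NI
cannot vanish there).  The package therefore ships two frozen,
versioned calibrations:

- `config/reference.yaml` (`reference_config()`): reproduces the seven
  1D sweep landmarks, each within ~3.5% except the g_I->E power peak
  (see limitations).  Used for all sweep and bifurcation analyses.
- `config/synergy.yaml` (`synergy_config()`): places the healthy state
  at a tied-search gamma-power optimum (vanishing tied and g_I->E
  gradients), with the oscillation in the gamma band and a
  super-additive combined-alteration response inside the published
  7.5-32.5% window.  Used by the disease pipeline.  The individual
  deficit magnitudes at the 20% level are deliberately not calibration
  inputs; they are out-of-sample behaviour of this configuration.

Both calibrations share kinetic structure that the landmark pattern
forces: NMDA activation fast relative to its decay (a_n tau_n >> 1), so
the NMDA gate runs near saturation - which is what reproduces the
order-of-magnitude gap between the AMPA and NMDA variability offsets
(1.55 vs 0.053) - plus a modest recurrent E->E conductance and a small
I->I conductance that shape where the power peaks fall inside the
oscillatory windows.  The calibrated constants are effective model
parameters, not measured biophysics; the membrane time constant in
particular comes out fast (~0.75 ms) because the published landmark
pattern demands a fast E-I loop at gamma frequency with narrow
oscillation windows.

## Synthetic-data scope

The package generates all of its own data.  The spiking module emulates
finite-size realizations of exactly the heterogeneity model the theory
assumes: quenched Lorentzian draws, all-to-all coupling, global gates.
It does not emulate sparse connectivity, conduction delays, synaptic
depression, voltage-dependent NMDA block, or non-Lorentzian (e.g.
Gaussian) variability - so network/mean-field agreement here validates
the reduction, not those biological complications.  Heavy Lorentzian
tails occasionally produce extreme per-neuron parameters; draws are kept
raw by default (the theory integrates over the full real line), with a
clearly flagged truncate-at-zero option that breaks exactness.

## Problem sizes and numerical defaults

Default problem sizes used by the tests, examples and the acceptance
script: mean-field simulations of 3 s sampled at 1 kHz; spiking runs of
1.5-2.5 s with N = 1000 (800 RSE + 200 FSI) at dt = 0.01 tau_e; 1D Hopf
scans on 40-60 point grids refined to |Re lambda| < 1e-6; power-peak
sweeps on grids with 0.02 steps; 2D Hopf curves on 8-16 column grids.
These sizes resolve every reported quantity at its stated tolerance;
larger grids change results only below those tolerances (convergence is
covered by tests that halve integrator tolerances and compare).

## Known limitations

- Gamma power is estimator-dependent (arbitrary units); only locations,
  zeros and ratios are portable.
- The mean-field NMDA closure is approximate at finite N (mean of a
  product replaced by product of means); the network/mean-field
  concordance test bounds the practical error at N = 1000.  Quenched
  Lorentzian draws make single finite-N realizations scatter by a few Hz
  in peak frequency (heavy tails converge slowly), so network metrics
  are reported as trial averages.
- Hopf detection tracks complex eigenvalue pairs only; fold or
  non-oscillatory instabilities would not be reported (none occur in the
  analysed parameter regions).
- Sub/supercritical classification is heuristic (via the amplitude
  branch), not normal-form based.
- Two literature landmarks resist this model family at any calibration
  found.  The gamma-power peak along the I->E mean sits at ~0.52 on the
  reference configuration (reported value 0.68): the power maximum along
  inhibition lands closer to the oscillation onset than reported, under
  every power metric tried.  The NMDA variability offset lands at 0.050
  vs the reported 0.053 (about 6% low), just outside the calibration
  residual target.
- On the disease calibration the fold-ratio maximum of the synergy sweep
  falls at a 25% difference (reported: between 12.5% and 22.5%), and the
  ordering of the two-parameter oscillatory-region shrinkage comes out
  variability > E->I strength > I->E strength rather than the reported
  E->I > I->E > variability.  Both are stable features of this model
  family under the calibration constraints and are surfaced (not hidden)
  by the test suite.
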