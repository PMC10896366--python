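"""Finite spiking network vs its exact mean-field reduction.

Simulates 800 excitatory + 200 inhibitory QIF neurons with quenched
Lorentzian heterogeneity and compares the smoothed population rate with
the mean-field firing rate: peak gamma frequencies should agree to a few
Hz and the cycle-averaged waveforms should be strongly correlated
(finite-size phase diffusion rules out naive long-window correlation).
"""

import numpy as np
from scipy.ndimage import gaussian_filter1d

import pingmf as pm
from pingmf.spectral import cycle_correlation

p = pm.reference_config()
duration = 2500.0

traj = pm.integrate_mean_field(p, duration=duration, dt_out=1.0)
net = pm.build_network(p, N_e=800, N_i=200, seed=7)
rec, _ = pm.simulate_network(net, duration=duration)
t_b, rate_e = pm.population_rate(rec, "e", bin=1.0, smooth_width=2.0)

n = min(len(rate_e), len(traj.t))
mf = gaussian_filter1d(traj["r_e"], 2.0)[:n]   # match the network smoothing
spk = rate_e[:n]
_, f_mf = pm.gamma_power_of_trace(mf, transient_discard=500.0)
_, f_net = pm.gamma_power_of_trace(spk, transient_discard=500.0)
corr = cycle_correlation(mf, spk, transient_discard=500.0)

print(f"network spikes: {len(rec.times)} "
      f"({len(rec.times) / 1000 / (duration / 1000):.1f} Hz per neuron)")
print(f"peak gamma frequency: mean-field {f_mf:.1f} Hz, network {f_net:.1f} Hz")
print(f"cycle-averaged waveform correlation: {corr:.3f}")
print()
print("The reduction is exact in the infinite-size limit; at N = 1000 a "
      "single quenched realization already shares the rhythm and cycle "
      "shape, with a few Hz of realization scatter from the heavy "
      "Lorentzian tails.")
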