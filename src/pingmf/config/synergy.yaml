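biophysics:
  C: 1.0
  gl: 1.123289134376322
  Vl: -65.0
  VT: -50.0
  Vex: -38.689795818426944
  Vin: -71.45155572034132
  Vspike: inf
  VR: -inf
reduced:
  tau: 0.8902427428493064
  Vhat_ex: 2.5080272242097412
  Vhat_in: -1.860207429378842
kinetics:
  tau_e: 1.3816977249414242
  tau_n: 870.2312944430952
  tau_i: 19.481602988122873
  a_n: 1.574938783303218
coupling:
  gbar_e_ampa: 0.07445484129142561
  gbar_e_nmda: 0.09727117300253366
  gbar_e_gaba: 0.4367074094110888
  gbar_i_ampa: 0.9380217978896125
  gbar_i_nmda: 0.16028625407561914
  gbar_i_gaba: 0.09770345875121392
  gamma_e_ampa: 0.0
  gamma_e_nmda: 0.0
  gamma_e_gaba: 0.01
  gamma_i_ampa: 0.01
  gamma_i_nmda: 0.01
  gamma_i_gaba: 0.0
drive:
  Ibar_e: 1.5608771013784373
  Delta_e: 0.0201431601798152
  Ibar_i: 0.0
  Delta_i: 0.0
meta:
  name: calibrated disease-synergy configuration
  version: 1
  comment: baseline constants calibrated so the healthy synaptic state is a gamma-power
    optimum of the tied strength search with a super-additive combined response inside
    the published window; see docs/methods.md
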