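biophysics:
  C: 1.0
  gl: 1.3338080255302402
  Vl: -65.0
  VT: -50.0
  Vex: -31.262466383134758
  Vin: -100.83506193221119
  Vspike: inf
  VR: -inf
reduced:
  tau: 0.7497330806676331
  Vhat_ex: 3.4983378155820324
  Vhat_in: -5.778008257628159
kinetics:
  tau_e: 1.2965923545629978
  tau_n: 550.3236339947049
  tau_i: 7.82199097699365
  a_n: 0.9915743255086595
coupling:
  gbar_e_ampa: 0.2
  gbar_e_nmda: 0.09371455147722324
  gbar_e_gaba: 0.28396370651953184
  gbar_i_ampa: 0.8357955899910546
  gbar_i_nmda: 0.08785761173572781
  gbar_i_gaba: 0.0
  gamma_e_ampa: 0.0
  gamma_e_nmda: 0.0
  gamma_e_gaba: 0.01
  gamma_i_ampa: 0.01
  gamma_i_nmda: 0.01
  gamma_i_gaba: 0.0
drive:
  Ibar_e: 1.1672220940837548
  Delta_e: 0.013412584040757625
  Ibar_i: 0.0
  Delta_i: 0.0
meta:
  name: calibrated reference configuration
  version: 1
  comment: baseline constants calibrated against the published 1D sweep landmarks;
    see docs/methods.md
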