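# Canonical calibrated membrane parameter set.
# Free repulsion/attraction coefficients are fixed by the elastic-constant
# calibration (memrod.calibration); k_bend = k_tilt = 10 and C_0 = 0 are the
# model's printed membrane parameters.
membrane:
  k_bend: 10.0
  k_tilt: 10.0
  c_bd: 0.0
  eps_rep: 4.0
  rep_alpha: 20.0
  rep_cutoff: 1.2
  rep_n: 12.0
  rep_a: 1.0
  eps_att: 2.5
  att_beta: 6.0
  rho_star: 7.68
  att_cutoff: 1.9
  att_n: 12.0
  att_a: 0.462
  wcv_cutoff: 2.4
  wcv_n: 4.0
  wcv_a: 2.0
  kbt: 1.0
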