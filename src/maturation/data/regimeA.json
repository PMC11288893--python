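{
  "chi12": 0.0,
  "chi1s": 3.0,
  "chi2s": 2.1,
  "v1": 1.0,
  "v2": 1.0,
  "vs": 1.0,
  "k1_per_day": 0.2,
  "k2_per_day": 0.1,
  "phi_tot": 0.55,
  "t_max_days": 20.0,
  "n_times": 81
}
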