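{
  "pollen_beta": {
    "mu": 5.0,
    "T_b": 13.0,
    "T_c": 48.0,
    "T_opt": 18.0,
    "T_0": 1.0,
    "N_star": 66100.0
  },
  "viability": {
    "alpha_max": 0.94,
    "theta1": 0.78,
    "theta2": -0.11,
    "T_opt": 18.0
  },
  "germination": {
    "alpha_max": 0.31,
    "theta1": 0.34,
    "theta2": -0.06,
    "T_opt": 18.0
  },
  "seed_link": {
    "slope": 0.0016,
    "intercept": 2.23
  },
  "mass_link": {
    "slope": 0.078,
    "intercept": 2.06
  },
  "conversion": {
    "c_flower_to_fruit": 1.0,
    "vol_chamber_mm3": 0.2,
    "vol_sample_ul": 200.0
  },
  "mass_unit": "g per fruit"
}
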