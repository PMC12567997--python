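{
  "_comment": "Literature-default tissue optical coefficients for the packaged finger model. Units: mu_a and mu_s in 1/mm, g and n dimensionless. Assembled from standard skin/blood/bone optics compilations (Jacques-style spectra); NOT device-calibrated values. Replace via a finger-model config file for quantitative reproduction of any specific published table.",
  "epidermis": {
    "550": {"mu_a": 0.50, "mu_s": 22.0, "g": 0.80, "n": 1.45},
    "628": {"mu_a": 0.25, "mu_s": 18.0, "g": 0.80, "n": 1.45},
    "940": {"mu_a": 0.10, "mu_s": 11.0, "g": 0.85, "n": 1.44}
  },
  "dermis": {
    "550": {"mu_a": 0.12, "mu_s": 19.0, "g": 0.85, "n": 1.40},
    "628": {"mu_a": 0.08, "mu_s": 15.0, "g": 0.85, "n": 1.40},
    "940": {"mu_a": 0.05, "mu_s": 10.0, "g": 0.90, "n": 1.39}
  },
  "microcirculation": {
    "550": {"mu_a": 0.25, "mu_s": 15.0, "g": 0.90, "n": 1.39},
    "628": {"mu_a": 0.06, "mu_s": 12.0, "g": 0.90, "n": 1.39},
    "940": {"mu_a": 0.08, "mu_s": 8.0, "g": 0.92, "n": 1.38}
  },
  "artery": {
    "550": {"mu_a": 24.0, "mu_s": 65.0, "g": 0.98, "n": 1.36},
    "628": {"mu_a": 0.50, "mu_s": 70.0, "g": 0.98, "n": 1.36},
    "940": {"mu_a": 0.65, "mu_s": 55.0, "g": 0.97, "n": 1.36}
  },
  "vein": {
    "550": {"mu_a": 24.0, "mu_s": 65.0, "g": 0.98, "n": 1.36},
    "628": {"mu_a": 0.50, "mu_s": 70.0, "g": 0.98, "n": 1.36},
    "940": {"mu_a": 0.65, "mu_s": 55.0, "g": 0.97, "n": 1.36}
  },
  "bone": {
    "550": {"mu_a": 0.07, "mu_s": 25.0, "g": 0.90, "n": 1.55},
    "628": {"mu_a": 0.05, "mu_s": 20.0, "g": 0.90, "n": 1.55},
    "940": {"mu_a": 0.04, "mu_s": 15.0, "g": 0.92, "n": 1.55}
  }
}
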