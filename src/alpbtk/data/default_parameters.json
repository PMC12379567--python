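{
  "k_in": {
    "liver": 2.9932888630059535,
    "kidney": 1.0003066469343211,
    "rest": 10.0
  },
  "k_out": {
    "liver": 0.003,
    "kidney": 0.0102,
    "rest": 0.001
  },
  "k_brain_in": 0.013528921692003381,
  "kappa_bone": 0.010491919705097061,
  "renal_extraction": 0.05100091427637452,
  "birth_amounts": {
    "plasma": 0.4,
    "bone": 300.0,
    "brain": 80.0,
    "liver": 50.0,
    "kidney": 8.0,
    "rest": 160.0
  },
  "scale_uptake_with_organ_mass": true,
  "provenance": {
    "anchored": [
      "dietary intake tiers and oral bioavailability (dosing module)",
      "adjuvant depot release rates 0.0024864 and 0.0082392 per day",
      "dry-to-wet conversion factors and tissue thresholds (assessment module)"
    ],
    "calibrated": {
      "free_params": [
        "renal_extraction",
        "k_brain_in",
        "kappa_bone",
        "k_in.liver",
        "k_in.kidney"
      ],
      "targets": "dietary-only population-typical medians: plasma 1.4 ug/L (40 y), bone 0.6 ug/g ww (40/50 y), brain 0.23/0.28 ug/g ww (40/50 y), liver 1.0 and kidney 0.5 ug/g ww (adult steady state)",
      "max_abs_rel_error": 0.1094422972207938
    },
    "fixed_by_convention": [
      "k_out return rates",
      "k_in.rest and k_out.rest",
      "birth amounts"
    ],
    "version": 1
  }
}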