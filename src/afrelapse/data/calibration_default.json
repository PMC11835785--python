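{
  "comment": "Dependence strengths of the synthetic-cohort generator. Binary children use additive log-odds shifts per parent state (first state = 0); three-state children use an ordinal association coefficient gamma between the parent score and the child state index. Marginals are matched to the stratified-counts fixture at build time, so these numbers control association strength only.",
  "binary_slopes": {
    "smoking": {"sex": [0.0, 0.8]},
    "alcoholism": {"sex": [0.0, 1.6]},
    "diabetes": {"age": [0.0, 0.5, 0.9], "bmi": [0.0, 0.5, 1.0]},
    "hbp": {"age": [0.0, 0.9, 1.6], "bmi": [0.0, 0.5, 1.0]},
    "osa": {"bmi": [0.0, 0.9, 1.8]},
    "af_type": {"osa": [0.0, 0.9]}
  },
  "ordinal_gamma": {
    "bmi": {"sex": 0.35},
    "epicardial_fat": {"bmi": 0.9},
    "la_volume": {"af_type": 0.7}
  }
}
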