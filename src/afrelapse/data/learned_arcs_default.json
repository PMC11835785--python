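{
  "arcs": [
    ["bmi", "epicardial_fat"],
    ["osa", "af_type"],
    ["af_type", "la_volume"],
    ["sex", "smoking"],
    ["sex", "alcoholism"],
    ["sex", "bmi"]
  ]
}
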