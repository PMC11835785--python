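{
  "whitelist": [
    ["age", "relapse"],
    ["sex", "relapse"],
    ["smoking", "relapse"],
    ["af_type", "relapse"],
    ["la_volume", "relapse"],
    ["epicardial_fat", "relapse"],
    ["osa", "relapse"],
    ["bmi", "diabetes"],
    ["bmi", "hbp"],
    ["bmi", "osa"],
    ["age", "diabetes"],
    ["age", "hbp"]
  ],
  "blacklist": [
    ["relapse", "sex"],
    ["relapse", "age"],
    ["relapse", "alcoholism"],
    ["relapse", "smoking"],
    ["relapse", "diabetes"],
    ["relapse", "hbp"],
    ["relapse", "osa"],
    ["relapse", "bmi"],
    ["relapse", "af_type"],
    ["relapse", "la_volume"],
    ["relapse", "epicardial_fat"]
  ]
}
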