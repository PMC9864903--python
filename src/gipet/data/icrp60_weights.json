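{
  "name": "icrp60",
  "weights": {
    "gonads": 0.20,
    "red_marrow": 0.12,
    "colon": 0.12,
    "lungs": 0.12,
    "stomach_wall": 0.12,
    "urinary_bladder_wall": 0.05,
    "breasts": 0.05,
    "liver": 0.05,
    "esophagus": 0.05,
    "thyroid": 0.05,
    "skin": 0.01,
    "bone_surface": 0.01
  },
  "remainder_weight": 0.05,
  "colon_split": {"uli_wall": 0.57, "lli_wall": 0.43},
  "esophagus_surrogate": "thymus"
}
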