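{
  "sex": "male",
  "body_mass_kg": 73.7,
  "remainder_organs": ["adrenals", "brain", "small_intestine", "kidneys", "muscle", "pancreas", "spleen", "thymus"],
  "provenance": "Cristy-Eckerman adult male reference phantom masses as used by classic internal-dosimetry software; editable"
}
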