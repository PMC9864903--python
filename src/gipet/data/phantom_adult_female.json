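{
  "sex": "female",
  "body_mass_kg": 56.8,
  "remainder_organs": ["adrenals", "brain", "small_intestine", "kidneys", "muscle", "pancreas", "spleen", "thymus", "uterus"],
  "provenance": "adult female reference phantom masses of the Cristy-Eckerman/Stabin phantom series; editable"
}
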