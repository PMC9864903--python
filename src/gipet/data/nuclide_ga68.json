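{
  "name": "Ga-68",
  "half_life_min": 67.71,
  "np_energy_mev": 0.74,
  "branching": 0.889,
  "provenance": "standard nuclear data (DDEP recommended values); np energy is the mean non-penetrating (beta+ and conversion/Auger electron) energy per decay"
}
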