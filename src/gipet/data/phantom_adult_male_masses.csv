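organ,mass_g
adrenals,16.3
brain,1420
breasts,351
gallbladder_wall,10.5
lli_wall,167
small_intestine,677
stomach_wall,158
uli_wall,220
heart_wall,316
kidneys,299
liver,1910
lungs,1000
muscle,28000
pancreas,94.3
red_marrow,1120
bone_surface,120
skin,3010
spleen,183
testes,39.1
thymus,20.9
thyroid,20.7
urinary_bladder_wall,47.6
blood,5300
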