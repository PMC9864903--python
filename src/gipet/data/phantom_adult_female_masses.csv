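organ,mass_g
adrenals,14.0
brain,1200
breasts,360
gallbladder_wall,8.0
lli_wall,160
small_intestine,600
stomach_wall,140
uli_wall,200
heart_wall,240
kidneys,275
liver,1400
lungs,800
muscle,17000
pancreas,85
red_marrow,1050
bone_surface,100
skin,2300
spleen,150
ovaries,8.7
uterus,79
thymus,20
thyroid,17
urinary_bladder_wall,35.9
blood,4100
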