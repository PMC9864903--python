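tissue,male_mSv_per_MBq,female_mSv_per_MBq
Adrenals,0.00936,0.0124
Brain,0.000541,0.000658
Breasts,0.000934,0.00113
Gallbladder Wall,0.00515,0.00555
LLI Wall,0.00166,0.00196
Small Intestine,0.0031,0.00398
Stomach Wall,0.00335,0.00374
ULI Wall,0.00309,0.00371
Heart Wall,0.0319,0.0362
Kidneys,0.713,0.773
Liver,0.006,0.00754
Lungs,0.00576,0.0073
Muscle,0.00227,0.00306
Pancreas,0.00777,0.0089
Red Marrow,0.014,0.0135
Osteogenic Cells,0.0109,0.0145
Skin,0.000859,0.001
Spleen,0.0101,0.0124
Testes/Ovaries,0.00137,0.00189
Thymus,0.00178,0.00198
Thyroid,0.000487,0.000543
Urinary Bladder Wall,0.00152,0.00202
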