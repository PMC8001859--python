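# Fractional tissue composition used for tissue-to-plasma partitioning (v1).
# f_water: total tissue water, f_nlipid: neutral lipid, f_phospholipid: neutral
# phospholipid, f_aphospholipid: acidic phospholipid. Literature-typical values.
tissue,f_water,f_nlipid,f_phospholipid,f_aphospholipid
plasma,0.945,0.0023,0.0013,0.0
lung,0.810,0.0220,0.0128,0.0031
adipose,0.180,0.7900,0.0020,0.0004
bone,0.440,0.0740,0.0011,0.0002
brain,0.770,0.0510,0.0565,0.0040
gut_wall,0.720,0.0490,0.0163,0.0024
heart,0.760,0.0140,0.0111,0.0022
kidney,0.790,0.0120,0.0242,0.0051
liver,0.750,0.0350,0.0250,0.0045
muscle,0.760,0.0100,0.0072,0.0024
skin,0.720,0.0600,0.0044,0.0014
spleen,0.780,0.0077,0.0113,0.0026
rest,0.750,0.0400,0.0100,0.0020
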