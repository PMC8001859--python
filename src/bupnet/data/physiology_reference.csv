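# Reference physiology, adult European male, 73 kg (v1).
# Literature-typical whole-body PBPK values; volumes in L, blood flows in L/min.
# pool1_fraction = vascular + interstitial fraction of organ volume; the remainder is
# the intracellular pool. Blood compartment volumes are whole blood; plasma volumes
# are derived with the hematocrit given in defaults.yaml. Liver flow is the hepatic
# arterial supply; portal inflow is the sum of gut_wall and spleen outflows.
organ,volume_L,flow_blood_L_per_min,pool1_fraction
arterial_blood,1.70,,
venous_blood,3.90,,
lung,0.50,,0.55
adipose,14.00,0.26,0.20
bone,10.00,0.28,0.15
brain,1.45,0.70,0.20
gut_wall,1.10,0.90,0.28
heart,0.33,0.24,0.25
kidney,0.31,1.10,0.35
liver,1.80,0.35,0.35
muscle,29.00,1.05,0.17
skin,3.30,0.30,0.40
spleen,0.19,0.08,0.35
rest,3.50,0.34,0.25
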