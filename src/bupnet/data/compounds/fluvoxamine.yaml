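# Fluvoxamine — perpetrator: strong competitive inhibitor of CYP2C19.
name: fluvoxamine
mw: 318.33
fu: 0.23
role: perpetrator

reduced_model:
  ka_per_min: 0.015
  ke_per_min: 7.70e-4   # half-life ~15 h
  v_L: 1750.0
  f_oral: 0.50

inhibition:
  - {enzyme: CYP2C19, ki: 0.015, provenance: default}  # literature-typical, µmol/L
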