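# Voriconazole — perpetrator: competitive inhibitor of CYP2B6 and CYP2C19.
# The CYP2B6 Ki was an optimized quantity in the source model and was never
# printed; the value below is a package default intended as a fitting target,
# not an authoritative constant.
name: voriconazole
mw: 349.31
fu: 0.42
role: perpetrator

reduced_model:
  ka_per_min: 0.02
  ke_per_min: 1.93e-3   # half-life ~6 h
  v_L: 320.0
  f_oral: 0.96

inhibition:
  - {enzyme: CYP2B6,  ki: 1.0,  provenance: default}   # fit target, µmol/L
  - {enzyme: CYP2C19, ki: 3.5,  provenance: default}   # literature-typical, µmol/L
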