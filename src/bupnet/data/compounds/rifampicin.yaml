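# Rifampicin — perpetrator: inducer of CYP2B6, CYP2C19 and UGT2B7 with
# simultaneous weak competitive inhibition of CYP2B6 and UGT2B7.
# The Ki values are the published interaction constants; induction Emax/EC50 and
# the reduced exposure-model parameters are literature-typical package defaults
# (the original work used a full published perpetrator PBPK model).
name: rifampicin
mw: 822.94
fu: 0.17
role: perpetrator

reduced_model:          # one-compartment oral exposure model (default parameters)
  ka_per_min: 0.025
  ke_per_min: 3.85e-3   # elimination half-life ~3 h
  v_L: 55.0
  f_oral: 0.95

inhibition:
  - {enzyme: CYP2B6, ki: 118.50}    # µmol/L
  - {enzyme: UGT2B7, ki: 554.87}    # µmol/L

induction:              # Emax as fold-increase above baseline; EC50 unbound µmol/L
  - {enzyme: CYP2B6,  emax: 3.8, ec50: 0.34, provenance: default}
  - {enzyme: CYP2C19, emax: 2.2, ec50: 0.34, provenance: default}
  - {enzyme: UGT2B7,  emax: 0.4, ec50: 0.34, provenance: default}
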