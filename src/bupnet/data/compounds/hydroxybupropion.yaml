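# Hydroxybupropion — CYP2B6 metabolite of bupropion, cleared by UGT2B7.
name: hydroxybupropion
mw: 255.74
pka: 7.65
pka_type: base
solubility_mg_ml: 0.91
logp: 1.90
fu: 0.23
intestinal_permeability_cm_min: 2.76e-5   # default: parent value (not printed)
cellular_permeability_cm_min: 0.005       # default (charge-dependent method value not printed)
partition_method: schmitt_charge_dependent
gfr_fraction: 1.00
ehc_continuous_fraction: 1.00

processes:
  - {enzyme: UGT2B7, product: glucuronide_sink, km: 14.64, kcat: 1.09}
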