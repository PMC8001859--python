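# Erythrohydrobupropion — 11β-HSD metabolite of bupropion, cleared by UGT2B7.
name: erythrohydrobupropion
mw: 241.76
pka: 9.71
pka_type: base
solubility_mg_ml: 82.98
logp: 1.89
fu: 0.58
intestinal_permeability_cm_min: 2.76e-5   # default: parent value (not printed)
cellular_permeability_cm_min: 0.005       # default (charge-dependent method value not printed)
partition_method: schmitt_charge_dependent
gfr_fraction: 1.00
ehc_continuous_fraction: 1.00

processes:
  - {enzyme: UGT2B7, product: glucuronide_sink, km: 9.33, kcat: 0.63}
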