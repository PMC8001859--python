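# Bupropion — parent compound of the CYP2B6 interaction network.
# All values marked provenance "literature"/"fitted" are the published model
# parameters; values marked "default" are package defaults standing in for
# parameters that were never printed (non-authoritative, override in config).
name: bupropion
mw: 239.74              # g/mol
pka: 8.75
pka_type: base
solubility_mg_ml: 365.56   # at pH 7.4
logp: 2.57
fu: 0.16                # fraction unbound in plasma
intestinal_permeability_cm_min: 2.76e-5
cellular_permeability_cm_min: 0.1      # default (original value not printed)
partition_method: berezhkovskiy
gfr_fraction: 1.00
ehc_continuous_fraction: 1.00

# CYP2B6 allele-specific Michaelis-Menten kinetics (unbound KM, per-allele kcat).
# kcat for *1 and *6 are half of the optimized homozygous values; *4 is the
# literature per-allele value. *5 kinetics were never printed and default to *1
# (the network predicts *5 carriers to behave like wildtype).
cyp2b6_alleles:
  "*1": {km: 25.80, kcat: 10.87}
  "*4": {km: 12.70, kcat: 18.13}
  "*5": {km: 25.80, kcat: 10.87, provenance: default}
  "*6": {km: 61.26, kcat: 9.52}

processes:
  - {enzyme: CYP2B6, product: hydroxybupropion, km: 25.80, kcat: 10.87, genotype_resolved: true}
  - {enzyme: 11b-HSD, product: erythrohydrobupropion, km: 39.10, kcat: 2.15}
  - {enzyme: 11b-HSD, product: threohydrobupropion, km: 39.10, kcat: 8.18}
  - {enzyme: CYP2C19, product: minor_cyp_sink, km: 8.30, kcat: 2.59}

# Binding to a surrogate neurotransmitter-transporter target (brain, gut wall).
binding:
  kd: 0.44     # µmol/L
  koff: 0.05   # 1/min
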