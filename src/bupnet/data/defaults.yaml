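# Package-wide model defaults (v1).
# Values here stand in for quantities that were never printed in the published
# network (enzyme tissue concentrations, induction turnover, dissolution
# parameters per product, absorption geometry). They are documented in
# docs/methods.md and freely overridable through scenario configuration.

physiology:
  hematocrit: 0.45
  gfr_L_per_min: 0.12
  body_weight_kg: 73.0
  allometric_exponent_volume: 1.0
  allometric_exponent_flow: 0.75

# Enzyme reference concentrations, µmol enzyme / L intracellular volume.
# Calibrated once during model setup so the 150 mg single-dose reference
# simulation reproduces the published fraction-metabolized split and near-
# complete metabolism; frozen thereafter.
enzyme_concentrations:
  CYP2B6:   {liver: 33.0, gut_wall: 3.30}
  11b-HSD:  {liver: 25.0, gut_wall: 2.50}
  CYP2C19:  {liver: 20.0}
  UGT2B7:   {liver: 15.0}

# Surrogate target-binding capacities, µmol binding sites / L intracellular volume.
binding_capacities:
  brain: 2.0
  gut_wall: 2.0

# Enzyme turnover for induction modeling: default degradation half-life 36 h.
enzyme_turnover:
  kdeg_per_min: 3.2083e-4

population:
  default_age_range: [20, 50]
  default_sex: male
  default_ethnicity: european
  variability_cv:              # log-normal coefficients of variation
    enzyme_concentration: 0.35
    organ_volume: 0.16
    blood_flow: 0.16

# Oral absorption geometry: gut lumen transit segments and effective
# absorptive surface (villi-expanded).
absorption:
  n_segments: 5
  transit_time_min: 210.0
  lumen_volume_L: 1.25             # total, split evenly over segments
  surface_area_cm2: 2.0e6          # total effective absorptive area
  cell_surface_area_cm2_per_L: 1.0e5   # organ exchange surface proxy

# Weibull dissolution defaults per release formulation. IR dissolves >90% in
# 1 h, SR over ~6 h, ER over ~12 h; shapes/times are non-authoritative defaults.
formulations:
  solution: {kind: solution}
  IR: {kind: weibull, shape_b: 1.20, t50_min: 15.0,  lag_min: 0.0}
  SR: {kind: weibull, shape_b: 1.10, t50_min: 180.0, lag_min: 0.0}
  ER: {kind: weibull, shape_b: 1.05, t50_min: 420.0, lag_min: 0.0}

simulation:
  rtol: 1.0e-8
  atol: 1.0e-10        # µmol
  method: LSODA

partitioning:
  # association constant heuristic for the cation/acidic-phospholipid term of
  # the charge-dependent method: k_aph = aph_scale * sqrt(10**logP)
  aph_scale: 20.0
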