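# Methods

`bupnet` is a reduced whole-body physiologically based pharmacokinetic (PBPK)
model of bupropion and its three major metabolites — hydroxybupropion (HBup,
formed by CYP2B6), and erythro-/threohydrobupropion (EBup/TBup, formed by
11β-HSD) — embedded in a CYP2B6 interaction network: allele-specific enzyme
kinetics for drug–gene interactions (DGI), competitive inhibition and
enzyme-induction turnover for drug–drug interactions (DDI), and their
combinations (DDGI). This note records the model, its assumptions, the
defaults, and the choices made where the design was genuinely open.

## Model structure

**Distribution.** The body is a fixed organ set: arterial and venous plasma,
lung, and eleven systemic organs (adipose, bone, brain, gut wall, heart,
kidney, liver, muscle, skin, spleen, rest), connected by plasma flows (whole
blood flow × (1 − hematocrit); the drug is assumed confined to plasma within
blood). Gut wall and spleen drain into the portal inflow of the liver. Each
organ is split into two pools: a combined vascular + interstitial pool that
behaves like plasma (the plasma fraction unbound `fu` applies) and an
intracellular pool governed by the tissue-to-plasma partition coefficient
`Kp`. Exchange between the pools is permeability-limited,

    J = PS · (fu·C_vasc − fu·C_cell/Kp),   PS = P_cell · a_cell · V_cell,

with `P_cell` the compound's cellular permeability (cm/min), `a_cell` a
surface-area proxy of 1e5 cm² per litre of cell volume, and the intracellular
unbound concentration *defined* as `Cu_cell = fu·C_cell/Kp`, so the pools
equilibrate at `C_cell = Kp·C_vasc`. All saturable processes read `Cu_cell`.

**Partitioning.** `Kp` is computed from a packaged tissue-composition table
with a lipid-fraction method of the Berezhkovskiy family:

    Kp = [D(f_nl,t + 0.3 f_ph,t) + f_w,t + 0.7 f_ph,t]
         / [D(f_nl,p + 0.3 f_ph,p) + f_w,p + 0.7 f_ph,p] · (1 + fu)/2

where `D` is the pH-7.4 distribution coefficient of the neutral species
(Henderson–Hasselbalch correction of 10^logP) and the final factor is a
protein-binding correction. The charge-dependent variant used for the
metabolites adds a cation–acidic-phospholipid term `k_aph·f_aph,t·(1 − f_n)`
with `k_aph = 20·√(10^logP)` (a documented heuristic, configurable). A
`user_supplied` method passes an explicit map through unchanged. This reduced
scheme underestimates the very large tissue trapping of lipophilic bases such
as bupropion, so absolute distribution volumes and half-lives are smaller
than clinical values; clearance *ratios* — the quantities the network is
built to predict — are unaffected (see Limitations).

**Absorption.** Oral doses enter a Weibull dissolution depot,
`f(t) = 1 − exp(−ln2·((t−lag)/t50)^b)`, applied as a release *rate* so that
multiple doses superpose exactly; `f(lag + t50) = 0.5` by construction. The
gut lumen is five first-order transit segments (total transit 210 min, total
volume 1.25 L). Absorption is a bidirectional permeability flux
`P_eff·A·(C_lumen − Cu_gutwall)` with the fitted transcellular permeability
(2.76e-5 cm/min) and an effective villi-expanded area of 200 m² split evenly
over segments, giving ≈99% absorption for immediate-release dosing. Dissolved
drug leaving the last segment is booked as feces; intestinal secretion (flux
reversal) is therefore a real, small elimination route. Per-formulation
Weibull defaults (IR: b = 1.2, t50 = 15 min; SR: 1.1, 180 min; ER: 1.05,
420 min) are non-authoritative package defaults. Continuous enterohepatic
recirculation plumbing exists (bile fraction continuously released = 1.0) but
the default biliary clearance is zero.

**Metabolism.** Each pathway is Michaelis–Menten in the intracellular unbound
concentration: `v = kcat·E·Cu/(KM + Cu)` with `E` the enzyme amount
(reference concentration × cell volume). Bupropion: CYP2B6 → HBup (genotype
resolved), 11β-HSD → EBup and → TBup, CYP2C19 → a terminal sink standing for
minor CYP routes. Metabolites: UGT2B7 glucuronidation into a terminal sink
(glucuronide disposition is not modeled). Metabolite formation is
stoichiometric 1:1 in moles, and every process integrates a cumulative flux
ledger as an extra ODE state, so pathway fractions are exact to integrator
tolerance. Enzyme expression: all four enzymes in liver; CYP2B6 and 11β-HSD
also in gut wall at a 10:1 liver:gut concentration ratio.

**Genotypes.** A CYP2B6 diplotype is split into two clearance processes, one
per allele, each with the allele's KM and per-allele kcat and *half* the
CYP2B6 enzyme pool — equivalent at the Vmax level to halving kcat for a
homozygote, and generalizing cleanly to heterozygotes. Allele kinetics (KM in
µmol/L unbound, kcat in 1/min): \*1 = (25.80, 10.87), \*4 = (12.70, 18.13),
\*6 = (61.26, 9.52); \*5 is not separately parameterized and defaults to \*1
(the network predicts \*5 carriers to behave like wildtype), overridable.

**Target binding.** Bupropion binds a surrogate neurotransmitter-transporter
pool (KD 0.44 µmol/L, koff 0.05 1/min, kon = koff/KD) represented as explicit
bound-amount states in brain and gut wall with default capacities of
2 µmol/L cell volume (configurable; the original capacity is not published).

**Elimination.** Renal filtration `gfr_fraction · GFR · fu · C_plasma` from
the kidney vascular pool (GFR 0.12 L/min, gfr_fraction 1.0 for all four
compounds); no active secretion. Fecal loss via lumen outflow.

**Interactions.** Perpetrators act as forcing concentration profiles — they
do not consume victim state. Two modes: `forcing_table` (deterministic,
test-friendly interpolation of a supplied unbound-concentration series) and
`model`, a reduced one-compartment oral model (first-order absorption and
elimination) integrated numerically; its parameters are literature-typical
defaults per perpetrator. Competitive inhibition scales every apparent KM by
`1 + Σ I_u/Ki`; rifampicin's published Ki values are 118.50 µmol/L (CYP2B6)
and 554.87 µmol/L (UGT2B7) — weak, and dominated by induction at multiple
dosing. Induction is enzyme turnover per expressing organ:

    dE/dt = kdeg·E_base·(1 + Emax·I_u/(EC50 + I_u)) − kdeg·E,

with a 36 h enzyme degradation half-life and rifampicin defaults
Emax = 3.8 (CYP2B6), 2.2 (CYP2C19), 0.4 (UGT2B7), EC50 = 0.34 µmol/L unbound
— literature-typical stand-ins for values never printed in the source
network. The voriconazole CYP2B6 Ki is a *fitting target*, not a constant;
its default (1.0 µmol/L) is marked non-authoritative in the compound file.

## Physiology and populations

The reference individual is a 73 kg adult European male with
literature-typical organ volumes and blood flows (packaged as a versioned
CSV); organ flows sum exactly to the cardiac output. Allometric scaling:
volumes ∝ BW^1.0, flows and GFR ∝ BW^0.75 (exponents configurable).
Populations apply independent median-1 log-normal multiplicative factors to
enzyme concentrations, organ volumes, and organ flows (default CVs 0.35,
0.16, 0.16), then recompute cardiac output as the sampled flow sum so flow
conservation holds for every individual. The default population when a study
reports no demographics is male, 20–50 years. Population profiles are
summarized as per-time geometric mean and geometric SD.

## Enzyme-concentration calibration (one-time, frozen)

The source model's enzyme tissue concentrations come from an expression
database that is not published. The packaged reference concentrations
(CYP2B6 33, 11β-HSD 25, CYP2C19 20, UGT2B7 15 µmol/L liver cell; gut wall at
10:1 where expressed) were calibrated once during model setup so that the
150 mg single-dose reference simulation reproduces the published
fraction-metabolized split (≈58/28/13% via CYP2B6/11β-HSD/CYP2C19) with
near-complete metabolism (≈99%) and ≈1% unchanged excretion, and then
frozen. Bupropion's cellular permeability (not printed in the source; listed
there as a fitted quantity) defaults to 0.1 cm/min so hepatic uptake is
perfusion- rather than permeability-limited, which is what makes the ≈99%
extent of metabolism attainable against the fixed renal filtration.

## Simulation and numerics

States are amounts in µmol, time in minutes; reported plasma concentrations
are venous plasma in ng/mL via the molar mass. The full network is ~154
states (4 compounds × 33-state blocks + bound pools + enzyme pools + process
ledgers + urine/feces/absorbed trackers); the layout is deterministic and
auditable via `ModelSystem.layout()`. Integration uses stiff-capable LSODA
with rtol 1e-8 and atol 1e-10 µmol by default; dosing is implemented as
integration restarts at event times (no impulse smoothing). Molar mass
balance (dose = Σ compartments + bound + lumen + sinks + urine + feces)
holds to ~1e-15 relative in practice and is asserted at 1e-6. A physical
state below −1e-3 µmol raises an integrity error; the net-absorption ledger
may legitimately go negative under intestinal secretion. A degenerate
one-compartment assembly mode shares the event/integration path and is used
to check the integrator against the closed-form exponential; the reduced
perpetrator model is checked against the Bateman equation.

## Evaluation statistics

Non-compartmental analysis uses the linear trapezoid (switchable design
point: no log-linear down-slope), AUC extrapolation as
`AUC_last + C_last/λz` with λz from a log-linear fit of the last n points,
n ∈ [3, 8] chosen to maximize adjusted r² (the source is silent on terminal
point selection; a poorly determined phase is flagged, not rejected).
Profile accuracy: `MRD = 10^√(Σ(log10 ĉ − log10 c)²/k)`, with zero/BLQ pairs
excluded pairwise and k reduced. Parameter accuracy:
`GMFE = 10^(Σ|log10(pred/obs)|/m)`. Exposure ratios: `AUC_HBup/Bup` and the
interaction effect ratio (interaction / reference). Acceptance helpers: the
2-fold band and the Guest limits `L = (1.25 + 2(R−1))/R` (R folded to ≥ 1),
which tighten to 1.25-fold as the observed ratio approaches 1.

## Synthetic studies

No clinical data ship with the package. The generator emulates digitized
study structure: subjects simulated with inter-individual variability,
proportional log-normal residual error at clinically spaced sampling times
(dense to 12 h, sparse to 96 h), reported as arithmetic mean ± SD per arm —
the convention of published figures. When all IIV CVs are zero, the subjects
are identical and one simulation is shared, with only residual noise
replicated. What passing tests show: the pipeline is self-consistent
(noise-free studies give MRD = GMFE = 1; injected noise raises MRD
monotonically; parameters are recoverable). What they cannot show: agreement
with real clinical profiles, which would require the non-redistributable
digitized dataset.

## Fitting and sensitivity

The objective is the sum of squared log10 residuals between model-mean and
observed-mean profiles, equally weighted per point (mirroring the MRD
geometry; the source's exact training objective is not stated). Multistart:
Latin-hypercube starting values in the log-transformed parameter box, each
polished with MINPACK Levenberg–Marquardt; the log transform enforces
positivity and starts converging outside the box are discarded. The
finite-difference step is fixed at 1e-3 (relative, transformed scale) so the
Jacobian sits well above integrator noise. Local sensitivity is the relative
central difference `(ΔAUC/AUC)/(Δp/p)` with a 10% default step.

## Known limitations

- Distribution volumes (and thus half-lives and absolute Cmax) are
  underestimated for these lipophilic bases; the network's exposure *ratios*
  and pathway fractions are the validated outputs.
- Enzyme tissue concentrations, induction parameters, per-formulation
  dissolution parameters, cellular permeabilities, perpetrator exposure
  models, and binding capacities are documented defaults, not published
  values; all are configurable.
- Glucuronide and minor-CYP products are terminal sinks; no transporters, no
  mechanism-based inhibition, no voriconazole N-oxide, no ontogeny or
  special populations, no pH-dependent solubility or food effects.
- Perpetrator exposure does not feed back from the victim system (no
  victim-on-perpetrator effects), matching the forcing-profile design.
- Enzyme turnover pools converge to the induced steady state within ~10–12
  degradation half-lives at 0.1% accuracy; five half-lives leave ~3% of the
  initial gap by elementary first-order kinetics.
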