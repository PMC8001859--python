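"""Virtual individuals and populations.

The reference individual is a reduced whole-body physiology: a fixed organ set
(arterial/venous blood, lung, liver, gut wall + lumen, kidney, brain, adipose,
muscle, skin, heart, bone, spleen, rest) with organ volumes, blood flows,
glomerular filtration and tissue enzyme/binding-partner concentrations.
Populations are sampled around the reference with independent log-normal
multiplicative factors on enzyme concentrations, organ volumes, and blood flows;
cardiac output is recomputed as the sum of sampled organ flows so that flow
conservation holds for every individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import ConfigurationError, load_defaults, load_packaged_csv

#: Systemic organs in canonical order (lung and the two blood pools are special).
SYSTEMIC_ORGANS = (
    "adipose", "bone", "brain", "gut_wall", "heart", "kidney",
    "liver", "muscle", "skin", "spleen", "rest",
)

KNOWN_SEXES = ("male", "female")


@dataclass
class Demographics:
    """Demographic descriptors of a (virtual) individual."""

    age: float = 30.0
    sex: str = "male"
    ethnicity: str = "european"
    body_weight: float | None = None   # kg
    height: float | None = None        # cm

    def validate(self) -> None:
        if not 0.0 <= self.age <= 120.0:
            raise ValueError(f"age must be in [0, 120], got {self.age}")
        if self.sex not in KNOWN_SEXES:
            raise ConfigurationError(f"unknown sex label: {self.sex!r}")
        if not isinstance(self.ethnicity, str) or not self.ethnicity:
            raise ConfigurationError(f"unknown ethnicity label: {self.ethnicity!r}")
        if self.body_weight is not None and self.body_weight <= 0:
            raise ValueError("body_weight must be positive when given")
        if self.height is not None and self.height <= 0:
            raise ValueError("height must be positive when given")


@dataclass
class PhysiologyParameters:
    """Complete physiological parameter record of one virtual individual."""

    organ_volumes: dict[str, float]          # L, includes blood pools and lung
    blood_flows: dict[str, float]            # L/min whole blood, systemic organs
    cardiac_output: float                    # L/min whole blood
    gfr: float                               # L/min
    hematocrit: float
    body_weight: float                       # kg
    enzyme_reference_concentrations: dict[tuple[str, str], float]  # (enzyme, organ) -> µmol/L cell
    binding_partner_concentrations: dict[str, float]               # organ -> µmol/L cell
    pool1_fractions: dict[str, float] = field(default_factory=dict)

    def validate(self, required_enzymes: tuple[str, ...] = ()) -> None:
        for organ, volume in self.organ_volumes.items():
            if volume <= 0:
                raise ValueError(f"organ volume must be positive: {organ}={volume}")
        for organ, flow in self.blood_flows.items():
            if flow <= 0:
                raise ValueError(f"blood flow must be positive: {organ}={flow}")
        if self.gfr <= 0:
            raise ValueError("gfr must be positive")
        total = sum(self.blood_flows.values())
        if abs(total - self.cardiac_output) > 1e-9 * self.cardiac_output:
            raise ValueError(
                f"organ flows (sum {total:.9g}) do not match cardiac output "
                f"{self.cardiac_output:.9g}"
            )
        expressed = {enzyme for enzyme, _ in self.enzyme_reference_concentrations}
        for enzyme in required_enzymes:
            if enzyme not in expressed:
                raise ConfigurationError(f"enzyme {enzyme!r} has no organ expression entry")

    def plasma_volume(self, organ: str) -> float:
        """Plasma volume of a blood pool (arterial_blood / venous_blood)."""
        return self.organ_volumes[organ] * (1.0 - self.hematocrit)


@dataclass
class PopulationSpec:
    """Specification of a virtual population."""

    n: int = 500
    base: Demographics = field(default_factory=Demographics)
    age_range: tuple[float, float] = (20.0, 50.0)
    variability: dict[str, float] | None = None   # parameter-class -> log-normal CV
    seed: int = 0

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"population size must be >= 0, got {self.n}")
        for key, cv in (self.variability or {}).items():
            if cv < 0:
                raise ValueError(f"CV for {key!r} must be >= 0")
        self.base.validate()


def _reference_tables(defaults: dict | None = None):
    defaults = defaults or load_defaults()
    table = load_packaged_csv("physiology_reference.csv")
    return table, defaults


def build_reference_individual(
    demographics: Demographics | None = None, defaults: dict | None = None
) -> PhysiologyParameters:
    """Construct the reference individual, allometrically scaled to body weight.

    Without an explicit body weight the packaged reference table is returned
    verbatim. With a weight, volumes scale with (BW/BW_ref)**1 and flows and
    GFR with (BW/BW_ref)**0.75 (exponents configurable in defaults.yaml).
    """
    demographics = demographics or Demographics()
    demographics.validate()
    table, defaults = _reference_tables(defaults)
    phys_cfg = defaults["physiology"]

    bw_ref = float(phys_cfg["body_weight_kg"])
    bw = demographics.body_weight if demographics.body_weight is not None else bw_ref
    vol_scale = (bw / bw_ref) ** float(phys_cfg["allometric_exponent_volume"])
    flow_scale = (bw / bw_ref) ** float(phys_cfg["allometric_exponent_flow"])

    volumes, flows, pool1 = {}, {}, {}
    for row in table.itertuples(index=False):
        volumes[row.organ] = float(row.volume_L) * vol_scale
        if not np.isnan(row.flow_blood_L_per_min):
            flows[row.organ] = float(row.flow_blood_L_per_min) * flow_scale
        if not np.isnan(row.pool1_fraction):
            pool1[row.organ] = float(row.pool1_fraction)

    enzymes = {
        (enzyme, organ): float(conc)
        for enzyme, per_organ in defaults["enzyme_concentrations"].items()
        for organ, conc in per_organ.items()
    }
    binding = {organ: float(c) for organ, c in defaults["binding_capacities"].items()}

    individual = PhysiologyParameters(
        organ_volumes=volumes,
        blood_flows=flows,
        cardiac_output=sum(flows.values()),
        gfr=float(phys_cfg["gfr_L_per_min"]) * flow_scale,
        hematocrit=float(phys_cfg["hematocrit"]),
        body_weight=bw,
        enzyme_reference_concentrations=enzymes,
        binding_partner_concentrations=binding,
        pool1_fractions=pool1,
    )
    individual.validate()
    return individual


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Median-1 log-normal multiplicative factors with arithmetic CV ``cv``."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size))


def sample_population(
    spec: PopulationSpec, defaults: dict | None = None
) -> list[PhysiologyParameters]:
    """Sample a virtual population around the reference individual.

    Log-normal factors are applied per individual to every enzyme
    concentration, organ volume and organ blood flow; cardiac output is the
    sum of the sampled flows. Sampling is reproducible from ``spec.seed``.
    """
    spec.validate()
    defaults = defaults or load_defaults()
    cv_cfg = dict(defaults["population"]["variability_cv"])
    cv_cfg.update(spec.variability or {})
    rng = np.random.default_rng(spec.seed)

    lo, hi = spec.age_range
    individuals = []
    for _ in range(spec.n):
        demo = replace(spec.base, age=float(rng.uniform(lo, hi)))
        ref = build_reference_individual(demo, defaults)
        volumes = dict(ref.organ_volumes)
        flows = dict(ref.blood_flows)
        enzymes = dict(ref.enzyme_reference_concentrations)

        vol_f = _lognormal_factor(rng, cv_cfg.get("organ_volume", 0.0), len(volumes))
        for factor, organ in zip(vol_f, sorted(volumes)):
            volumes[organ] *= factor
        flow_f = _lognormal_factor(rng, cv_cfg.get("blood_flow", 0.0), len(flows))
        for factor, organ in zip(flow_f, sorted(flows)):
            flows[organ] *= factor
        enz_f = _lognormal_factor(rng, cv_cfg.get("enzyme_concentration", 0.0), len(enzymes))
        for factor, key in zip(enz_f, sorted(enzymes)):
            enzymes[key] *= factor

        individual = replace(
            ref,
            organ_volumes=volumes,
            blood_flows=flows,
            cardiac_output=sum(flows.values()),
            enzyme_reference_concentrations=enzymes,
        )
        individual.validate()
        individuals.append(individual)
    return individuals
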