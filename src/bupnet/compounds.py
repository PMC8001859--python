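"""Drug-dependent parameters and interaction-kinetics primitives.

This module owns everything that varies per compound: physicochemistry and
ADME parameters, tissue-to-plasma partitioning, CYP2B6 genotype resolution into
allele-specific clearance processes, and the elementary interaction kinetics
(competitive inhibition, induction fold, target-binding rate constants).

Partitioning
------------
Tissue-to-plasma partition coefficients are computed from a packaged tissue
composition table with a lipid-fraction method in the Berezhkovskiy family:

    Kp = [D (f_nl,t + 0.3 f_ph,t) + (f_w,t + 0.7 f_ph,t)]
         / [D (f_nl,p + 0.3 f_ph,p) + (f_w,p + 0.7 f_ph,p)] * (1 + fu) / 2

where ``D`` is the pH-7.4 distribution coefficient of the neutral species
(Henderson-Hasselbalch correction of 10**logP) and the trailing factor is the
plasma/tissue protein-binding correction expressed through the plasma fraction
unbound. The charge-dependent variant adds a cation / acidic-phospholipid
association term for bases, ``k_aph * f_aph,t * (1 - f_neutral)`` with
``k_aph = aph_scale * sqrt(10**logP)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigurationError, load_compound_config, load_defaults, load_packaged_csv

CYP2B6_ALLELES = ("*1", "*4", "*5", "*6")
PARTITION_METHODS = ("berezhkovskiy", "schmitt_charge_dependent", "user_supplied")


@dataclass
class AlleleKinetics:
    """Per-allele CYP2B6 Michaelis-Menten kinetics (unbound KM, per-allele kcat)."""

    allele: str
    km: float                 # µmol/L
    kcat_per_allele: float    # 1/min

    def __post_init__(self):
        if self.km <= 0:
            raise ValueError(f"KM must be > 0 for allele {self.allele}")
        if self.kcat_per_allele < 0:
            raise ValueError(f"kcat must be >= 0 for allele {self.allele}")


@dataclass
class EnzymeProcess:
    """One saturable clearance pathway catalysed by a named enzyme.

    ``enzyme_fraction`` scales the organ enzyme concentration assigned to this
    process; the two processes of a diplotype each carry half of the total
    CYP2B6 pool.
    """

    enzyme: str
    substrate: str
    product: str              # compound name or a terminal "*_sink" label
    km: float                 # µmol/L, unbound
    kcat: float               # 1/min
    allele_label: str | None = None
    enzyme_fraction: float = 1.0

    def __post_init__(self):
        if self.km <= 0:
            raise ValueError(f"KM must be > 0 ({self.process_id})")
        if self.kcat < 0:
            raise ValueError(f"kcat must be >= 0 ({self.process_id})")
        if not 0 < self.enzyme_fraction <= 1:
            raise ValueError("enzyme_fraction must be in (0, 1]")

    @property
    def process_id(self) -> str:
        allele = f"[{self.allele_label}]" if self.allele_label else ""
        return f"{self.enzyme}{allele}:{self.substrate}->{self.product}"

    @property
    def is_sink(self) -> bool:
        return self.product.endswith("_sink")


@dataclass
class BindingPartner:
    """Reversible binding to a surrogate pharmacological target."""

    kd: float                  # µmol/L
    koff: float                # 1/min
    organs: dict[str, float] = field(default_factory=dict)   # organ -> capacity µmol/L

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("KD must be > 0")
        if self.koff < 0:
            raise ValueError("koff must be >= 0")


@dataclass
class InhibitionSpec:
    perpetrator: str
    enzyme: str
    ki: float                  # µmol/L
    mechanism: str = "competitive"

    def __post_init__(self):
        if self.ki <= 0:
            raise ValueError("Ki must be > 0")
        if self.mechanism != "competitive":
            raise ConfigurationError(f"unsupported inhibition mechanism: {self.mechanism}")


@dataclass
class InductionSpec:
    perpetrator: str
    enzyme: str
    ec50: float                # µmol/L unbound
    emax: float                # fold-increase above baseline
    kdeg: float                # 1/min

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("EC50 must be > 0")
        if self.emax < 0:
            raise ValueError("Emax must be >= 0")
        if self.kdeg <= 0:
            raise ValueError("kdeg must be > 0")


@dataclass
class Compound:
    """Physicochemical + ADME parameter record of one modeled species."""

    name: str
    mw: float                          # g/mol
    fu: float                          # fraction unbound in plasma
    logp: float = 0.0
    pka: float | None = None
    pka_type: str = "neutral"          # base | acid | neutral
    solubility_mg_ml: float | None = None
    intestinal_permeability_cm_min: float = 0.0
    cellular_permeability_cm_min: float = 0.01
    partition_method: str = "berezhkovskiy"
    gfr_fraction: float = 1.0
    ehc_continuous_fraction: float = 1.0
    processes: list[EnzymeProcess] = field(default_factory=list)
    cyp2b6_alleles: dict[str, AlleleKinetics] = field(default_factory=dict)
    binding: BindingPartner | None = None
    user_partition: dict[str, float] | None = None

    def __post_init__(self):
        if self.mw <= 0:
            raise ValueError("MW must be > 0")
        if not 0 < self.fu <= 1:
            raise ValueError("fu must be in (0, 1]")
        if not 0 <= self.gfr_fraction <= 1:
            raise ValueError("gfr_fraction must be in [0, 1]")
        if not 0 <= self.ehc_continuous_fraction <= 1:
            raise ValueError("ehc_continuous_fraction must be in [0, 1]")
        if self.intestinal_permeability_cm_min < 0 or self.cellular_permeability_cm_min < 0:
            raise ValueError("permeabilities must be >= 0")
        if self.partition_method not in PARTITION_METHODS:
            raise ConfigurationError(f"unknown partition method: {self.partition_method!r}")


def load_compound(name: str, overrides: dict | None = None) -> Compound:
    """Build a :class:`Compound` from a packaged or user compound file."""
    cfg = load_compound_config(name)
    if overrides:
        from .config import deep_merge

        cfg = deep_merge(cfg, overrides)

    alleles = {
        allele: AlleleKinetics(allele, float(entry["km"]), float(entry["kcat"]))
        for allele, entry in (cfg.get("cyp2b6_alleles") or {}).items()
    }
    processes = [
        EnzymeProcess(
            enzyme=proc["enzyme"],
            substrate=cfg["name"],
            product=proc["product"],
            km=float(proc["km"]),
            kcat=float(proc["kcat"]),
        )
        for proc in cfg.get("processes") or []
        if not proc.get("genotype_resolved")
    ]
    binding = None
    if "binding" in cfg:
        binding = BindingPartner(kd=float(cfg["binding"]["kd"]), koff=float(cfg["binding"]["koff"]))

    return Compound(
        name=cfg["name"],
        mw=float(cfg["mw"]),
        fu=float(cfg["fu"]),
        logp=float(cfg.get("logp", 0.0)),
        pka=cfg.get("pka"),
        pka_type=cfg.get("pka_type", "neutral"),
        solubility_mg_ml=cfg.get("solubility_mg_ml"),
        intestinal_permeability_cm_min=float(cfg.get("intestinal_permeability_cm_min", 0.0)),
        cellular_permeability_cm_min=float(cfg.get("cellular_permeability_cm_min", 0.01)),
        partition_method=cfg.get("partition_method", "berezhkovskiy"),
        gfr_fraction=float(cfg.get("gfr_fraction", 1.0)),
        ehc_continuous_fraction=float(cfg.get("ehc_continuous_fraction", 1.0)),
        processes=processes,
        cyp2b6_alleles=alleles,
        binding=binding,
    )


# ---------------------------------------------------------------------------
# Tissue partitioning


def neutral_fraction(pka: float | None, pka_type: str, ph: float = 7.4) -> float:
    """Henderson-Hasselbalch neutral fraction at the given pH."""
    if pka is None or pka_type == "neutral":
        return 1.0
    if pka_type == "base":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    if pka_type == "acid":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    raise ConfigurationError(f"unknown pKa type: {pka_type!r}")


def load_tissue_composition() -> pd.DataFrame:
    return load_packaged_csv("tissue_composition.csv").set_index("tissue")


def partition_coefficients(
    compound: Compound,
    composition: pd.DataFrame | None = None,
    aph_scale: float | None = None,
) -> dict[str, float]:
    """Tissue-to-plasma partition coefficients for every organ in the table.

    The ``user_supplied`` method returns the compound's own map unchanged.
    """
    if compound.partition_method == "user_supplied":
        if compound.user_partition is None:
            raise ConfigurationError(
                f"{compound.name}: partition_method user_supplied but no map given"
            )
        return dict(compound.user_partition)

    if composition is None:
        composition = load_tissue_composition()
    if aph_scale is None:
        aph_scale = float(load_defaults()["partitioning"]["aph_scale"])
    if "plasma" not in composition.index:
        raise ConfigurationError("tissue composition table is missing the plasma row")

    fn = neutral_fraction(compound.pka, compound.pka_type)
    d_coeff = (10.0 ** compound.logp) * fn
    charged = compound.partition_method == "schmitt_charge_dependent"
    k_aph = aph_scale * np.sqrt(10.0 ** compound.logp) if charged else 0.0

    plasma = composition.loc["plasma"]
    denom = (
        d_coeff * (plasma.f_nlipid + 0.3 * plasma.f_phospholipid)
        + plasma.f_water
        + 0.7 * plasma.f_phospholipid
    )
    binding_factor = (1.0 + compound.fu) / 2.0

    kps: dict[str, float] = {}
    for tissue, row in composition.iterrows():
        if tissue == "plasma":
            continue
        num = (
            d_coeff * (row.f_nlipid + 0.3 * row.f_phospholipid)
            + row.f_water
            + 0.7 * row.f_phospholipid
        )
        if charged and compound.pka_type == "base":
            num += k_aph * row.f_aphospholipid * (1.0 - fn)
        kp = float(num / denom * binding_factor)
        if kp <= 0:
            raise ValueError(f"non-positive Kp computed for {tissue}")
        kps[tissue] = kp
    return kps


# ---------------------------------------------------------------------------
# Genotype machinery


def parse_diplotype(label: str) -> tuple[str, str]:
    """Split a diplotype label like ``"*1|*6"`` into its two allele labels."""
    parts = label.replace("/", "|").split("|")
    if len(parts) != 2:
        raise ConfigurationError(f"cannot parse diplotype label {label!r}")
    return parts[0].strip(), parts[1].strip()


def build_cyp2b6_diplotype(
    allele1: str,
    allele2: str,
    table: dict[str, AlleleKinetics],
    substrate: str = "bupropion",
    product: str = "hydroxybupropion",
) -> tuple[EnzymeProcess, EnzymeProcess]:
    """Resolve a CYP2B6 diplotype into two allele-specific clearance processes.

    Each process carries the allele's own KM and per-allele kcat and half of
    the organ CYP2B6 pool; the result is invariant under allele order swap
    (alleles are sorted into the canonical order).
    """
    for allele in (allele1, allele2):
        if allele not in table:
            raise ConfigurationError(f"unknown CYP2B6 allele: {allele!r}")
    ordered = sorted((allele1, allele2))
    processes = []
    for slot, allele in enumerate(ordered, start=1):
        kin = table[allele]
        processes.append(
            EnzymeProcess(
                enzyme="CYP2B6",
                substrate=substrate,
                product=product,
                km=kin.km,
                kcat=kin.kcat_per_allele,
                allele_label=f"{allele}#{slot}",
                enzyme_fraction=0.5,
            )
        )
    return processes[0], processes[1]


# ---------------------------------------------------------------------------
# Interaction kinetics primitives


def apparent_km(km: float, inhibitor_unbound: float, ki: float) -> float:
    """Apparent KM under competitive inhibition: ``KM * (1 + I/Ki)``."""
    if ki <= 0:
        raise ValueError("Ki must be > 0")
    if km < 0 or inhibitor_unbound < 0:
        raise ValueError("KM and inhibitor concentration must be >= 0")
    return km * (1.0 + inhibitor_unbound / ki)


def induction_fold(inducer_unbound: float, spec: InductionSpec) -> float:
    """Fold-increase of enzyme synthesis: ``1 + Emax * I / (EC50 + I)``."""
    if inducer_unbound < 0:
        raise ValueError("inducer concentration must be >= 0")
    return 1.0 + spec.emax * inducer_unbound / (spec.ec50 + inducer_unbound)


def kon_from_binding(partner: BindingPartner) -> float:
    """Association rate constant ``kon = koff / KD`` in 1/(µmol/L)/min."""
    if partner.kd <= 0:
        raise ValueError("KD must be > 0")
    return partner.koff / partner.kd
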