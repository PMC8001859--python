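"""Assembly of the bupropion parent-metabolite interaction network.

Wires the packaged compound files, a CYP2B6 diplotype, and any perpetrator
drugs into a ready-to-simulate :class:`~bupnet.engine.ModelSystem`: the parent
with its genotype-resolved CYP2B6 pathway plus 11β-HSD and CYP2C19, the three
metabolites with their UGT2B7 glucuronidation, surrogate target binding, and
the competitive-inhibition / induction interaction specs of the perpetrators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compounds import (
    Compound,
    InductionSpec,
    InhibitionSpec,
    build_cyp2b6_diplotype,
    load_compound,
    parse_diplotype,
)
from .config import deep_merge, load_compound_config, load_defaults
from .engine import DoseEvent, Interactions, ModelSystem, PerpetratorRegimen, StudyProtocol
from .physiology import Demographics, PhysiologyParameters, build_reference_individual

VICTIM_COMPOUNDS = (
    "bupropion",
    "hydroxybupropion",
    "erythrohydrobupropion",
    "threohydrobupropion",
)
PERPETRATOR_COMPOUNDS = ("rifampicin", "fluvoxamine", "voriconazole")


@dataclass
class NetworkScenario:
    """A fully specified simulation scenario (compounds, genotype, perpetrators)."""

    genotype: str = "*1|*1"
    perpetrators: tuple[str, ...] = ()
    config: dict = field(default_factory=dict)        # overrides onto defaults.yaml
    compound_overrides: dict = field(default_factory=dict)  # name -> field overrides

    def defaults(self) -> dict:
        return deep_merge(load_defaults(), self.config)


def build_victims(scenario: NetworkScenario) -> list[Compound]:
    return [
        load_compound(name, scenario.compound_overrides.get(name))
        for name in VICTIM_COMPOUNDS
    ]


def build_interactions(scenario: NetworkScenario, defaults: dict) -> Interactions:
    kdeg = float(defaults["enzyme_turnover"]["kdeg_per_min"])
    inhibitions, inductions, configs = [], [], {}
    for name in scenario.perpetrators:
        cfg = load_compound_config(name)
        cfg = deep_merge(cfg, scenario.compound_overrides.get(name, {}))
        configs[name] = cfg
        for entry in cfg.get("inhibition") or []:
            inhibitions.append(
                InhibitionSpec(perpetrator=name, enzyme=entry["enzyme"], ki=float(entry["ki"]))
            )
        for entry in cfg.get("induction") or []:
            inductions.append(
                InductionSpec(
                    perpetrator=name,
                    enzyme=entry["enzyme"],
                    ec50=float(entry["ec50"]),
                    emax=float(entry["emax"]),
                    kdeg=kdeg,
                )
            )
    return Interactions(inhibitions=inhibitions, inductions=inductions, perpetrator_configs=configs)


def assemble_network(
    scenario: NetworkScenario | None = None,
    physiology: PhysiologyParameters | None = None,
) -> ModelSystem:
    """Assemble the four-compound network for one scenario."""
    scenario = scenario or NetworkScenario()
    defaults = scenario.defaults()
    compounds = build_victims(scenario)
    bupropion = compounds[0]

    a1, a2 = parse_diplotype(scenario.genotype)
    p1, p2 = build_cyp2b6_diplotype(a1, a2, bupropion.cyp2b6_alleles)
    processes = [p1, p2]
    for compound in compounds:
        processes.extend(compound.processes)

    interactions = build_interactions(scenario, defaults)
    if physiology is None:
        physiology = build_reference_individual(Demographics(), defaults)
    return ModelSystem(
        compounds=compounds,
        physiology=physiology,
        processes=processes,
        interactions=interactions,
        binding_capacities={
            organ: float(c) for organ, c in defaults["binding_capacities"].items()
        },
        defaults=defaults,
    )


def standard_protocol(
    dose_mg: float = 150.0,
    formulation: str = "IR",
    n_doses: int = 1,
    interval_h: float = 24.0,
    duration_h: float = 96.0,
    genotype: str = "*1|*1",
    perpetrators: tuple[str, ...] = (),
    rifampicin_days: int = 7,
    observation_times_h: np.ndarray | None = None,
) -> StudyProtocol:
    """Standard single/multiple-dose bupropion protocol with optional perpetrators.

    Perpetrator schedules follow the clinical designs: 600 mg rifampicin once
    daily starting several days before the (first) bupropion dose, or single
    doses of 50 mg fluvoxamine + 400 mg voriconazole 2 h before bupropion.
    """
    offset_min = 0.0
    regimens = []
    if "rifampicin" in perpetrators:
        offset_min = rifampicin_days * 1440.0
        doses = [(600.0, 1440.0 * day) for day in range(rifampicin_days + 1)]
        regimens.append(PerpetratorRegimen("rifampicin", doses=doses))
    for name, amount in (("fluvoxamine", 50.0), ("voriconazole", 400.0)):
        if name in perpetrators:
            regimens.append(
                PerpetratorRegimen(name, doses=[(amount, max(offset_min - 120.0, 0.0))])
            )

    victim_doses = [
        DoseEvent(
            "bupropion",
            amount_mg=dose_mg,
            time_min=offset_min + i * interval_h * 60.0,
            route="oral",
            formulation=formulation,
        )
        for i in range(n_doses)
    ]
    duration_min = offset_min + duration_h * 60.0
    if observation_times_h is None:
        dense = np.linspace(0.0, 12.0, 49)
        sparse = np.linspace(13.0, duration_h, max(int(duration_h) - 12, 2))
        observation_times_h = np.unique(np.concatenate([dense, sparse]))
    obs_min = offset_min + np.asarray(observation_times_h, dtype=float) * 60.0
    if offset_min > 0:
        obs_min = np.concatenate([[0.0], obs_min])
    return StudyProtocol(
        victim_doses=victim_doses,
        duration_min=duration_min,
        genotype=genotype,
        perpetrators=regimens,
        observation_times_min=obs_min,
    )
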