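"""Synthetic "observed" clinical studies.

No clinical dataset ships with this package; instead, this module generates
studies with the structure of digitized bupropion trials: arithmetic mean ± SD
concentration profiles at sparse clinical sampling times, per-study
demographics and genotype arms, the three release formulations, and
perpetrator co-administration arms. Inter-individual variability comes from
the virtual-population sampler and measurement noise from a proportional
log-normal residual model, so noise-free studies close the loop exactly
(MRD = GMFE = 1 against the generating model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import ModelSystem, SimSettings, StudyProtocol
from .network import NetworkScenario, assemble_network, standard_protocol
from .physiology import PopulationSpec, sample_population

VICTIMS_REPORTED = ("bupropion", "hydroxybupropion")


@dataclass
class SyntheticStudySpec:
    """How to turn a model truth into one synthetic observed study."""

    protocol: StudyProtocol
    n_subjects: int = 12
    sampling_times_h: np.ndarray | None = None     # relative to first victim dose
    residual_cv: float = 0.15
    iiv_cv: dict[str, float] | None = None         # parameter-class -> CV; None = defaults
    seed: int = 0
    reported_summary: str = "arithmetic_mean_sd"   # or "individual"
    residual_model: str = "proportional_lognormal"
    compounds: tuple[str, ...] = VICTIMS_REPORTED
    lloq_ng_ml: float | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.residual_cv < 0:
            raise ValueError("residual_cv must be >= 0")
        for key, cv in (self.iiv_cv or {}).items():
            if cv < 0:
                raise ValueError(f"IIV CV for {key!r} must be >= 0")
        if self.residual_model != "proportional_lognormal":
            raise ValueError(f"unknown residual model: {self.residual_model!r}")


@dataclass
class StudyArm:
    label: str
    compound: str
    times_h: np.ndarray
    mean_ng_ml: np.ndarray
    sd_ng_ml: np.ndarray

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.mean_ng_ml = np.asarray(self.mean_ng_ml, dtype=float)
        self.sd_ng_ml = np.asarray(self.sd_ng_ml, dtype=float)
        if np.any(self.mean_ng_ml < 0) or np.any(self.sd_ng_ml < 0):
            raise ValueError("means and SDs must be >= 0")


@dataclass
class ObservedStudy:
    """One synthetic study: arms of mean ± SD profiles plus metadata."""

    study_id: str
    arms: list[StudyArm]
    protocol: StudyProtocol | None = None
    metadata: dict = field(default_factory=dict)

    def arm(self, compound: str, label: str | None = None) -> StudyArm:
        for arm in self.arms:
            if arm.compound == compound and (label is None or arm.label == label):
                return arm
        raise KeyError(f"no arm for {compound!r} ({label!r})")


def _default_sampling(duration_h: float) -> np.ndarray:
    """Clinical-style grid: dense to 12 h, sparse out to the study end."""
    dense = np.array([0.5, 1, 1.5, 2, 3, 4, 6, 8, 10, 12])
    sparse = np.array([16, 24, 36, 48, 72, 96])
    grid = np.concatenate([dense, sparse[sparse <= duration_h]])
    return grid[grid <= duration_h]


def generate_observed_study(
    system: ModelSystem,
    spec: SyntheticStudySpec,
    study_id: str = "synthetic_study",
    settings: SimSettings | None = None,
) -> ObservedStudy:
    """Simulate subjects under the protocol and report mean ± SD profiles.

    With all inter-individual CVs at zero every subject is the reference
    individual, so a single simulation is shared across subjects and only the
    residual noise differs; otherwise each sampled individual is simulated.
    Reproducible from ``spec.seed``.
    """
    protocol = spec.protocol
    rng = np.random.default_rng(spec.seed)
    t0_dose = min(d.time_min for d in protocol.victim_doses)
    duration_h = (protocol.duration_min - t0_dose) / 60.0
    times_h = (
        np.asarray(spec.sampling_times_h, dtype=float)
        if spec.sampling_times_h is not None
        else _default_sampling(duration_h)
    )
    if times_h.size and times_h.max() > duration_h + 1e-9:
        raise ValueError("sampling times extend beyond the protocol duration")

    obs_min = t0_dose + times_h * 60.0
    proto = StudyProtocol(
        victim_doses=protocol.victim_doses,
        duration_min=protocol.duration_min,
        genotype=protocol.genotype,
        perpetrators=protocol.perpetrators,
        observation_times_min=np.unique(np.concatenate([[0.0], obs_min])),
    )

    iiv = spec.iiv_cv
    homogeneous = iiv is not None and all(cv == 0 for cv in iiv.values())
    if homogeneous or spec.n_subjects == 1:
        result = system.simulate(proto, settings=settings)
        base = {
            name: np.interp(obs_min, result.times, result.plasma_concentrations[name])
            for name in spec.compounds
        }
        subject_profiles = {name: np.tile(base[name], (spec.n_subjects, 1)) for name in base}
    else:
        pop_spec = PopulationSpec(n=spec.n_subjects, variability=iiv, seed=spec.seed)
        population = sample_population(pop_spec)
        subject_profiles = {name: [] for name in spec.compounds}
        for individual in population:
            result = system.simulate(proto, individual=individual, settings=settings)
            for name in spec.compounds:
                subject_profiles[name].append(
                    np.interp(obs_min, result.times, result.plasma_concentrations[name])
                )
        subject_profiles = {k: np.asarray(v) for k, v in subject_profiles.items()}

    arms = []
    for name in spec.compounds:
        profiles = subject_profiles[name]
        if spec.residual_cv > 0:
            sigma = np.sqrt(np.log1p(spec.residual_cv**2))
            noise = np.exp(rng.normal(0.0, sigma, size=profiles.shape))
            profiles = profiles * noise
        if spec.lloq_ng_ml is not None:
            profiles = np.where(profiles < spec.lloq_ng_ml, 0.0, profiles)
        mean = profiles.mean(axis=0)
        sd = profiles.std(axis=0, ddof=1) if profiles.shape[0] > 1 else np.zeros_like(mean)
        arms.append(StudyArm("treatment", name, times_h, mean, sd))

    metadata = {
        "n_subjects": spec.n_subjects,
        "genotype": protocol.genotype,
        "perpetrators": [r.compound for r in protocol.perpetrators],
        "residual_cv": spec.residual_cv,
        "seed": spec.seed,
        "reported_summary": spec.reported_summary,
    }
    return ObservedStudy(study_id=study_id, arms=arms, protocol=proto, metadata=metadata)


# ---------------------------------------------------------------------------
# Serialization (tidy CSV + YAML sidecar, the schema the metrics reader uses)


def write_study(study: ObservedStudy, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for arm in study.arms:
        for t, m, s in zip(arm.times_h, arm.mean_ng_ml, arm.sd_ng_ml):
            rows.append(
                {"study_id": study.study_id, "arm": arm.label, "compound": arm.compound,
                 "time_h": t, "mean_ng_ml": m, "sd_ng_ml": s}
            )
    csv_path = directory / f"{study.study_id}.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)

    sidecar = {"study_id": study.study_id, "metadata": study.metadata}
    if study.protocol is not None:
        sidecar["protocol"] = {
            "genotype": study.protocol.genotype,
            "duration_min": float(study.protocol.duration_min),
            "victim_doses": [
                {"compound": d.compound, "amount_mg": d.amount_mg, "time_min": d.time_min,
                 "route": d.route, "formulation": d.formulation
                 if isinstance(d.formulation, (str, type(None))) else "custom"}
                for d in study.protocol.victim_doses
            ],
            "perpetrators": [
                {"compound": r.compound, "doses": [[a, t] for a, t in r.doses], "mode": r.mode}
                for r in study.protocol.perpetrators
            ],
        }
    with open(directory / f"{study.study_id}.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
    return csv_path


def read_study(directory: str | Path, study_id: str) -> ObservedStudy:
    directory = Path(directory)
    table = pd.read_csv(directory / f"{study_id}.csv")
    sidecar = yaml.safe_load((directory / f"{study_id}.yaml").read_text(encoding="utf-8"))
    arms = []
    for (label, compound), group in table.groupby(["arm", "compound"], sort=False):
        group = group.sort_values("time_h")
        arms.append(
            StudyArm(label, compound, group["time_h"].to_numpy(),
                     group["mean_ng_ml"].to_numpy(), group["sd_ng_ml"].to_numpy())
        )
    protocol = None
    if "protocol" in sidecar:
        from .engine import DoseEvent, PerpetratorRegimen

        pc = sidecar["protocol"]
        protocol = StudyProtocol(
            victim_doses=[DoseEvent(**d) for d in pc["victim_doses"]],
            duration_min=pc["duration_min"],
            genotype=pc["genotype"],
            perpetrators=[
                PerpetratorRegimen(r["compound"], doses=[tuple(x) for x in r["doses"]],
                                   mode=r.get("mode", "model"))
                for r in pc["perpetrators"]
            ],
        )
    return ObservedStudy(study_id=study_id, arms=arms, protocol=protocol,
                         metadata=sidecar.get("metadata", {}))


# ---------------------------------------------------------------------------
# Fixture suite


def make_fixture_suite(
    seed: int = 0,
    outdir: str | Path | None = None,
    include: tuple[str, ...] = ("formulations", "doses", "genotypes", "ddi"),
    n_subjects: int = 1,
    residual_cv: float = 0.0,
    duration_h: float = 48.0,
    settings: SimSettings | None = None,
    protocols_only: bool = False,
) -> dict[str, ObservedStudy] | dict[str, StudyProtocol]:
    """Generate the packaged study fixtures.

    Covers the three release formulations, single doses over the 20-300 mg
    range, the four genotype arms, the rifampicin arm, and the fluvoxamine +
    voriconazole arm. The drug-drug-gene grid (all ten diplotypes with and
    without rifampicin) is available through the workflow layer, which emits
    its protocols directly.
    """
    rng = np.random.default_rng(seed)
    protocols: dict[str, StudyProtocol] = {}
    scenarios: dict[str, NetworkScenario] = {}

    def add(study_id, genotype="*1|*1", perps=(), **kwargs):
        protocols[study_id] = standard_protocol(
            genotype=genotype, perpetrators=perps, duration_h=duration_h, **kwargs
        )
        scenarios[study_id] = NetworkScenario(genotype=genotype, perpetrators=perps)

    if "formulations" in include:
        add("form_ir_100tid", dose_mg=100, formulation="IR", n_doses=3, interval_h=8)
        add("form_sr_150bid", dose_mg=150, formulation="SR", n_doses=2, interval_h=12)
        add("form_er_300qd", dose_mg=300, formulation="ER", n_doses=1)
    if "doses" in include:
        for dose in (20, 75, 150, 300):
            add(f"dose_{dose}mg_ir", dose_mg=dose, formulation="IR")
    if "genotypes" in include:
        for genotype in ("*1|*1", "*1|*4", "*1|*6", "*6|*6"):
            tag = genotype.replace("*", "").replace("|", "_")
            add(f"dgi_{tag}", genotype=genotype, dose_mg=150, formulation="IR")
    if "ddi" in include:
        add("ddi_rifampicin", perps=("rifampicin",), dose_mg=150, formulation="SR",
            rifampicin_days=7)
        add("ddi_fluvo_vori", perps=("fluvoxamine", "voriconazole"), dose_mg=150,
            formulation="IR")

    if protocols_only:
        return protocols

    studies: dict[str, ObservedStudy] = {}
    for study_id, protocol in protocols.items():
        system = assemble_network(scenarios[study_id])
        spec = SyntheticStudySpec(
            protocol=protocol,
            n_subjects=n_subjects,
            residual_cv=residual_cv,
            iiv_cv={"enzyme_concentration": 0.0, "organ_volume": 0.0, "blood_flow": 0.0},
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        studies[study_id] = generate_observed_study(system, spec, study_id, settings=settings)
        if outdir is not None:
            write_study(studies[study_id], outdir)
    return studies
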