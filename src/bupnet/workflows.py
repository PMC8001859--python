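"""Scenario workflows: simulate / dgi / ddi / ddgi / synth / fit / report.

Thin orchestration over the library: each workflow builds a scenario from a
configuration mapping (or YAML file), runs the relevant simulations, and
writes tidy CSV artifacts plus a JSON run manifest carrying the seed and a
hash of the configuration, so reruns with the same seed and config are
reproducible byte for byte.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import config_hash
from .engine import SimSettings, fraction_metabolized
from .fitting import FitParameter, FitSpec, fit_parameters
from .network import NetworkScenario, assemble_network, standard_protocol
from .pk import (
    ConcentrationProfile,
    auc_last,
    gmfe,
    hbup_bup_ratio,
    mrd,
    nca,
    within_guest,
    within_twofold,
)
from .synthetic import make_fixture_suite, read_study

DIPLOTYPES = ["|".join(pair) for pair in
              itertools.combinations_with_replacement(("*1", "*4", "*5", "*6"), 2)]
COMMANDS = ("simulate", "dgi", "ddi", "ddgi", "synth", "fit", "report")


def _load_config(config) -> dict:
    if config is None:
        return {}
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text(encoding="utf-8")) or {}
    return dict(config)


def _scenario_from(cfg: dict, genotype=None, perpetrators=None) -> NetworkScenario:
    scen = cfg.get("scenario", {})
    return NetworkScenario(
        genotype=genotype if genotype is not None else scen.get("genotype", "*1|*1"),
        perpetrators=tuple(perpetrators if perpetrators is not None
                           else scen.get("perpetrators", ())),
        config=cfg.get("model", {}),
        compound_overrides=cfg.get("compounds", {}),
    )


def _protocol_from(cfg: dict, genotype="*1|*1", perpetrators=()) -> "StudyProtocol":
    pc = dict(cfg.get("protocol", {}))
    pc.setdefault("dose_mg", 150.0)
    pc.setdefault("formulation", "IR")
    pc.setdefault("duration_h", 96.0)
    return standard_protocol(genotype=genotype, perpetrators=tuple(perpetrators), **pc)


def _settings_from(cfg: dict) -> SimSettings | None:
    sim = cfg.get("simulation")
    if not sim:
        return None
    return SimSettings(rtol=float(sim.get("rtol", 1e-8)), atol=float(sim.get("atol", 1e-10)))


def _auc_ratio_for(scenario: NetworkScenario, cfg: dict, settings) -> tuple[float, dict]:
    protocol = _protocol_from(cfg, scenario.genotype, scenario.perpetrators)
    system = assemble_network(scenario)
    result = system.simulate(protocol, settings=settings)
    t0 = min(d.time_min for d in protocol.victim_doses)
    mask = result.times >= t0
    t_h = (result.times[mask] - t0) / 60.0
    summaries = {}
    for name in ("bupropion", "hydroxybupropion"):
        summaries[name] = nca(
            ConcentrationProfile(t_h, result.plasma_concentrations[name][mask])
        )
    ratio = hbup_bup_ratio(summaries["hydroxybupropion"], summaries["bupropion"])
    return ratio, {"summaries": summaries, "result": result}


def run_ddgi_grid(
    config=None,
    seed: int = 0,
    outdir: str | Path | None = None,
    genotypes: list[str] | None = None,
    settings: SimSettings | None = None,
) -> pd.DataFrame:
    """Drug-drug-gene grid: every diplotype with and without rifampicin.

    Emits the metabolite-parent AUC ratio per cell and its effect ratio
    against the wildtype no-inducer reference. Deterministic given seed.
    """
    cfg = _load_config(config)
    settings = settings or _settings_from(cfg)
    cfg.setdefault("protocol", {})
    cfg["protocol"].setdefault("formulation", "SR")
    genotypes = genotypes or cfg.get("genotypes") or DIPLOTYPES
    rows = []
    for genotype in genotypes:
        for perps in ((), ("rifampicin",)):
            scenario = _scenario_from(cfg, genotype=genotype, perpetrators=perps)
            ratio, _ = _auc_ratio_for(scenario, cfg, settings)
            rows.append(
                {"genotype": genotype, "rifampicin": bool(perps), "auc_hbup_bup": ratio}
            )
    table = pd.DataFrame(rows)
    ref_mask = (table.genotype == "*1|*1") & (~table.rifampicin)
    if ref_mask.any():
        reference = float(table.loc[ref_mask, "auc_hbup_bup"].iloc[0])
        table["effect_ratio"] = table["auc_hbup_bup"] / reference
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "ddgi_grid.csv", index=False)
        _write_manifest(outdir, "ddgi", cfg, seed)
    return table


def _write_manifest(outdir: Path, command: str, cfg: dict, seed: int) -> None:
    manifest = {"command": command, "seed": seed, "config_hash": config_hash(cfg)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")


def plot_profiles(result, path: Path, compounds=None) -> None:
    """Semilog plasma concentration-time plot (PNG/SVG by file suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    t_h = result.times / 60.0
    for name in compounds or result.plasma_concentrations:
        ax.plot(t_h, result.plasma_concentrations[name], label=name)
    ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("plasma concentration (ng/mL)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_result_csv(result, outdir: Path, stem: str) -> None:
    rows = []
    for (compound, compartment), series in result.concentrations.items():
        if compartment != "venous_plasma":
            continue
        for t, c in zip(result.times, series):
            rows.append({"time_min": t, "compound": compound, "compartment": compartment,
                         "value": c, "unit": "umol_per_L"})
    pd.DataFrame(rows).to_csv(outdir / f"{stem}_profiles.csv", index=False)
    ledger_rows = [
        {"process": pid, "cumulative_umol": float(series[-1])}
        for pid, series in result.flux_ledger.items()
    ]
    pd.DataFrame(ledger_rows).to_csv(outdir / f"{stem}_flux_ledger.csv", index=False)


def run_pipeline(command: str, config=None, outdir: str | Path = "out", seed: int = 0) -> Path:
    """Run one named workflow and write its artifacts under ``outdir``."""
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}; expected one of {COMMANDS}")
    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    settings = _settings_from(cfg)

    if command == "simulate":
        scenario = _scenario_from(cfg)
        protocol = _protocol_from(cfg, scenario.genotype, scenario.perpetrators)
        system = assemble_network(scenario)
        result = system.simulate(protocol, settings=settings)
        _write_result_csv(result, outdir, "simulate")
        plot_profiles(result, outdir / "simulate_profiles.png")
        fm = fraction_metabolized(result, "bupropion")
        (outdir / "fraction_metabolized.json").write_text(
            json.dumps({"fractions": fm["fractions"],
                        "fraction_unchanged": fm["fraction_unchanged"]}, indent=2),
            encoding="utf-8",
        )

    elif command == "dgi":
        rows = []
        reference = None
        for genotype in cfg.get("genotypes", ["*1|*1", "*1|*4", "*1|*6", "*6|*6"]):
            scenario = _scenario_from(cfg, genotype=genotype)
            ratio, _ = _auc_ratio_for(scenario, cfg, settings)
            if genotype == "*1|*1":
                reference = ratio
            rows.append({"genotype": genotype, "auc_hbup_bup": ratio})
        table = pd.DataFrame(rows)
        if reference:
            table["effect_ratio"] = table["auc_hbup_bup"] / reference
        table.to_csv(outdir / "dgi_ratios.csv", index=False)

    elif command == "ddi":
        perps = tuple(cfg.get("scenario", {}).get("perpetrators") or ("rifampicin",))
        control, _ = _auc_ratio_for(_scenario_from(cfg, perpetrators=()), cfg, settings)
        treated, _ = _auc_ratio_for(_scenario_from(cfg, perpetrators=perps), cfg, settings)
        pd.DataFrame(
            [{"perpetrators": "+".join(perps), "auc_hbup_bup_control": control,
              "auc_hbup_bup_ddi": treated, "effect_ratio": treated / control}]
        ).to_csv(outdir / "ddi_ratios.csv", index=False)

    elif command == "ddgi":
        run_ddgi_grid(cfg, seed=seed, outdir=outdir, settings=settings)

    elif command == "synth":
        synth_cfg = cfg.get("synth", {})
        make_fixture_suite(
            seed=seed,
            outdir=outdir / "studies",
            include=tuple(synth_cfg.get("include", ("formulations", "doses", "genotypes"))),
            n_subjects=int(synth_cfg.get("n_subjects", 1)),
            residual_cv=float(synth_cfg.get("residual_cv", 0.0)),
            duration_h=float(synth_cfg.get("duration_h", 48.0)),
            settings=settings,
        )

    elif command == "fit":
        fit_cfg = cfg.get("fit", {})
        studies_dir = Path(fit_cfg.get("studies_dir", outdir / "studies"))
        study_ids = fit_cfg.get("studies") or [
            p.stem for p in sorted(studies_dir.glob("*.csv"))
        ]
        datasets = [read_study(studies_dir, sid) for sid in study_ids]
        parameters = [
            FitParameter(p["path"], float(p["lower"]), float(p["upper"]),
                         p.get("transform", "log"))
            for p in fit_cfg.get("parameters", [])
        ]
        spec = FitSpec(parameters=parameters, datasets=datasets,
                       n_starts=int(fit_cfg.get("n_starts", 3)), seed=seed)
        fit = fit_parameters(spec, _scenario_from(cfg))
        pd.DataFrame(fit.trace).to_csv(outdir / "fit_trace.csv", index=False)
        (outdir / "fit_estimates.json").write_text(
            json.dumps({"estimates": fit.estimates, "objective": fit.objective}, indent=2),
            encoding="utf-8",
        )

    elif command == "report":
        report_cfg = cfg.get("report", {})
        studies_dir = Path(report_cfg.get("studies_dir", outdir / "studies"))
        rows = []
        for csv_path in sorted(studies_dir.glob("*.csv")):
            study = read_study(studies_dir, csv_path.stem)
            if study.protocol is None:
                continue
            meta = study.metadata
            scenario = NetworkScenario(
                genotype=study.protocol.genotype,
                perpetrators=tuple(meta.get("perpetrators", ())),
            )
            system = assemble_network(scenario)
            t0 = min(d.time_min for d in study.protocol.victim_doses)
            arm_times = np.unique(np.concatenate(
                [[0.0]] + [t0 + arm.times_h * 60.0 for arm in study.arms]
            ))
            study.protocol.observation_times_min = arm_times
            result = system.simulate(study.protocol, settings=settings)
            for arm in study.arms:
                pred_values = np.interp(
                    t0 + arm.times_h * 60.0,
                    result.times,
                    result.plasma_concentrations[arm.compound],
                )
                obs = ConcentrationProfile(arm.times_h, arm.mean_ng_ml, arm.compound)
                pred = ConcentrationProfile(arm.times_h, pred_values, arm.compound)
                auc_pair = (auc_last(pred), auc_last(obs))
                cmax_pair = (float(pred_values.max()), float(arm.mean_ng_ml.max()))
                rows.append(
                    {"study_id": study.study_id, "compound": arm.compound,
                     "mrd": mrd(obs, pred),
                     "gmfe_auc": gmfe([auc_pair]), "gmfe_cmax": gmfe([cmax_pair]),
                     "within_2fold_auc": within_twofold(auc_pair[0] / auc_pair[1]),
                     "within_2fold_cmax": within_twofold(cmax_pair[0] / cmax_pair[1]),
                     "within_guest_auc": within_guest(auc_pair[0], auc_pair[1])}
                )
        table = pd.DataFrame(rows)
        table.to_csv(outdir / "metrics.csv", index=False)
        if len(table):
            summary = {
                "n_profiles": int(len(table)),
                "pct_auc_within_2fold": 100.0 * float(table.within_2fold_auc.mean()),
                "pct_cmax_within_2fold": 100.0 * float(table.within_2fold_cmax.mean()),
                "pct_mrd_le_2": 100.0 * float((table.mrd <= 2.0).mean()),
                "overall_gmfe_auc": float(
                    gmfe([(r, 1.0) for r in table.gmfe_auc])
                ),
            }
            (outdir / "summary.json").write_text(json.dumps(summary, indent=2), encoding="utf-8")

    _write_manifest(outdir, command, cfg, seed)
    return outdir
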