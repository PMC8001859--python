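import numpy as np
import pytest

from bupnet.compounds import Compound, EnzymeProcess
from bupnet.engine import (
    DoseEvent,
    ModelSystem,
    PerpetratorRegimen,
    SimSettings,
    StudyProtocol,
    fraction_metabolized,
    geometric_summary,
    perpetrator_exposure,
)
from bupnet.network import NetworkScenario, assemble_network, standard_protocol
from bupnet.physiology import build_reference_individual
from tests.conftest import FAST


def _bare_compound(**overrides):
    kw = dict(name="probe", mw=200.0, fu=0.5, logp=1.0, pka=8.0, pka_type="base",
              intestinal_permeability_cm_min=2.76e-5, cellular_permeability_cm_min=0.05)
    kw.update(overrides)
    return Compound(**kw)


# ---------------------------------------------------------------------------
# layout and assembly


def test_state_layout_formula_and_idempotent_assembly(reference_system):
    layout = reference_system.layout()
    nc = len(layout["compounds"])
    block = 4 + 2 * len(layout["organs"]) + 1 + layout["lumen_segments"] + 1
    expected = (
        nc * block
        + layout["bound_pools"]
        + len(layout["enzyme_pools"])
        + len(layout["process_ledger"])
        + 3 * nc
    )
    assert layout["per_compound_block"] == block
    assert reference_system.state_count == expected
    again = assemble_network()
    assert again.layout() == layout


def test_induction_adds_one_enzyme_pool_per_enzyme_per_expressing_organ(reference_system):
    with_rif = assemble_network(NetworkScenario(perpetrators=("rifampicin",)))
    # rifampicin induces CYP2B6 (liver + gut wall), CYP2C19 (liver), UGT2B7 (liver)
    added = with_rif.state_count - reference_system.state_count
    assert added == 4
    assert set(with_rif.layout()["enzyme_pools"]) == {
        ("CYP2B6", "liver"), ("CYP2B6", "gut_wall"), ("CYP2C19", "liver"), ("UGT2B7", "liver"),
    }


def test_dangling_product_is_a_configuration_error():
    from bupnet.config import ConfigurationError

    phys = build_reference_individual()
    comp = _bare_compound()
    proc = EnzymeProcess(enzyme="CYP2B6", substrate="probe", product="ghost", km=10, kcat=1)
    with pytest.raises(ConfigurationError, match="dangling product"):
        ModelSystem([comp], phys, [proc])


# ---------------------------------------------------------------------------
# conservation and degenerate oracles


def test_zero_dose_protocol_gives_identically_zero_output(reference_system):
    protocol = StudyProtocol(victim_doses=[], duration_min=600.0,
                             observation_times_min=np.linspace(0, 600, 11))
    result = reference_system.simulate(protocol, settings=FAST)
    for series in result.plasma_concentrations.values():
        assert np.all(series == 0.0)
    for series in result.flux_ledger.values():
        assert np.all(series == 0.0)


def test_iv_bolus_with_all_clearances_disabled_conserves_moles():
    phys = build_reference_individual()
    comp = _bare_compound(gfr_fraction=0.0)
    system = ModelSystem([comp], phys, processes=[])
    protocol = StudyProtocol(
        victim_doses=[DoseEvent("probe", 50.0, 0.0, route="iv")],
        duration_min=1440.0,
        observation_times_min=np.linspace(0, 1440, 25),
    )
    result = system.simulate(protocol)
    assert result.mass_balance_rel_error.max() <= 1e-6
    # no metabolism/filtration: everything is still in the body or, via
    # intestinal secretion (the absorption flux is bidirectional), in feces
    recovered = result.amount_remaining["probe"] + result.excreted["probe"]["feces"]
    assert recovered == pytest.approx(result.dose_administered["probe"], rel=1e-7)
    assert result.excreted["probe"]["urine"] == 0.0


def test_one_compartment_degenerate_matches_exponential_closed_form():
    comp = _bare_compound(fu=1.0)
    volume, clearance, dose_mg = 40.0, 0.5, 100.0
    system = ModelSystem.one_compartment(comp, volume, clearance)
    obs = np.linspace(0.0, 1440.0, 97)
    protocol = StudyProtocol(victim_doses=[DoseEvent("probe", dose_mg, 0.0, route="iv")],
                             duration_min=1440.0, observation_times_min=obs)
    result = system.simulate(protocol, settings=SimSettings(rtol=1e-11, atol=1e-13))
    dose = dose_mg / comp.mw * 1000.0
    analytic = dose / volume * np.exp(-clearance * result.times / volume)
    numeric = result.concentrations[("probe", "central")]
    assert np.max(np.abs(numeric - analytic) / analytic) < 1e-6


def test_competing_clearances_split_three_to_one():
    phys = build_reference_individual()
    comp = _bare_compound()
    shared = dict(substrate="probe", km=30.0, enzyme="CYP2B6")
    fast = EnzymeProcess(product="fast_sink", kcat=3.0, **shared)
    slow = EnzymeProcess(product="slow_sink", kcat=1.0, **shared)
    system = ModelSystem([comp], phys, [fast, slow])
    protocol = StudyProtocol(
        victim_doses=[DoseEvent("probe", 50.0, 0.0, route="oral", formulation="IR")],
        duration_min=72 * 60.0,
        observation_times_min=np.linspace(0, 72 * 60.0, 73),
    )
    result = system.simulate(protocol, settings=FAST)
    fm = fraction_metabolized(result, "probe")
    assert fm["fractions"] == pytest.approx({"CYP2B6": 1.0})
    flux_fast = result.flux_ledger[fast.process_id][-1]
    flux_slow = result.flux_ledger[slow.process_id][-1]
    share = flux_fast / (flux_fast + flux_slow)
    assert share == pytest.approx(0.75, abs=1e-6)


def test_single_pathway_fraction_is_one(reference_run_48h):
    protocol, result = reference_run_48h
    fm = fraction_metabolized(result, "hydroxybupropion")
    assert fm["fractions"] == pytest.approx({"UGT2B7": 1.0})


# ---------------------------------------------------------------------------
# dosing, mass balance and linearity


def test_oral_fixture_mass_balance_and_nonnegative_ledger(reference_run_48h):
    _, result = reference_run_48h
    assert result.mass_balance_rel_error.max() <= 1e-6
    for series in result.flux_ledger.values():
        assert np.all(np.diff(series) >= -1e-9)
        assert np.all(series >= 0.0)


def test_dose_linearity_in_the_linear_regime(reference_system):
    aucs = {}
    for dose in (1.0, 2.0):
        protocol = standard_protocol(dose_mg=dose, formulation="IR", duration_h=48.0)
        result = reference_system.simulate(protocol, settings=FAST)
        aucs[dose] = np.trapezoid(result.plasma_concentrations["bupropion"], result.times) / dose
    assert aucs[1.0] == pytest.approx(aucs[2.0], rel=0.02)


# ---------------------------------------------------------------------------
# perpetrators and interactions


def test_forcing_table_reproduces_supplied_values_and_checks_window():
    reg = PerpetratorRegimen("x", mode="forcing_table",
                             forcing_times=np.array([0.0, 100.0, 200.0]),
                             forcing_unbound=np.array([1.0, 1.0, 1.0]))
    exposure = perpetrator_exposure(reg, {}, 200.0)
    assert exposure.unbound(0.0) == 1.0 and exposure.unbound(137.5) == 1.0
    with pytest.raises(ValueError, match="cover"):
        perpetrator_exposure(reg, {}, 500.0)


def test_zero_dose_perpetrator_regimen_gives_zero_series():
    from bupnet.config import load_compound_config

    reg = PerpetratorRegimen("rifampicin", doses=[])
    exposure = perpetrator_exposure(reg, load_compound_config("rifampicin"), 600.0)
    assert all(exposure.unbound(t) == 0.0 for t in (0.0, 100.0, 599.0))


def test_reduced_perpetrator_model_matches_bateman_closed_form():
    from bupnet.config import load_compound_config

    cfg = load_compound_config("rifampicin")
    rm = cfg["reduced_model"]
    ka, ke, v, f = (rm["ka_per_min"], rm["ke_per_min"], rm["v_L"], rm["f_oral"])
    reg = PerpetratorRegimen("rifampicin", doses=[(600.0, 0.0)])
    exposure = perpetrator_exposure(reg, cfg, 1440.0)
    dose = 600.0 / cfg["mw"] * 1000.0 * f
    t = np.linspace(1.0, 1440.0, 200)
    bateman = cfg["fu"] * dose / v * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))
    numeric = np.array([exposure.unbound(ti) for ti in t])
    assert np.max(np.abs(numeric - bateman)) / bateman.max() < 1e-6
    tmax = np.log(ka / ke) / (ka - ke)
    cmax = cfg["fu"] * dose / v * ka / (ka - ke) * (np.exp(-ke * tmax) - np.exp(-ka * tmax))
    assert exposure.unbound(tmax) == pytest.approx(cmax, rel=1e-6)


def test_cyp2b6_inhibition_never_increases_hydroxybupropion_exposure():
    protocol_kw = dict(dose_mg=150, formulation="IR", duration_h=48.0)
    control_sys = assemble_network()
    control = control_sys.simulate(standard_protocol(**protocol_kw), settings=FAST)
    inhibited_sys = assemble_network(NetworkScenario(perpetrators=("voriconazole",)))
    protocol = standard_protocol(perpetrators=("voriconazole",), **protocol_kw)
    inhibited = inhibited_sys.simulate(protocol, settings=FAST)

    def auc(result):
        return np.trapezoid(result.plasma_concentrations["hydroxybupropion"], result.times)

    assert auc(inhibited) < auc(control)


def test_cyp2b6_induction_never_decreases_hydroxybupropion_exposure():
    protocol_kw = dict(dose_mg=150, formulation="SR", duration_h=48.0)
    control = assemble_network().simulate(standard_protocol(**protocol_kw), settings=FAST)
    # rifampicin stripped down to pure CYP2B6 induction
    overrides = {"rifampicin": {"inhibition": [],
                                "induction": [{"enzyme": "CYP2B6", "emax": 3.8, "ec50": 0.34}]}}
    scenario = NetworkScenario(perpetrators=("rifampicin",), compound_overrides=overrides)
    system = assemble_network(scenario)
    protocol = standard_protocol(perpetrators=("rifampicin",), **protocol_kw)
    induced = system.simulate(protocol, settings=FAST)

    t0 = min(d.time_min for d in protocol.victim_doses)

    def auc(result, t_start):
        mask = result.times >= t_start
        return np.trapezoid(result.plasma_concentrations["hydroxybupropion"][mask],
                            result.times[mask])

    assert auc(induced, t0) > auc(control, 0.0)


def test_enzyme_pool_converges_to_induction_fold_under_constant_inducer():
    scenario = NetworkScenario(perpetrators=("rifampicin",))
    system = assemble_network(scenario)
    duration = 12 * 36.0 * 60.0  # twelve enzyme degradation half-lives
    iu = 1.0
    reg = PerpetratorRegimen("rifampicin", mode="forcing_table",
                             forcing_times=np.array([0.0, duration]),
                             forcing_unbound=np.array([iu, iu]))
    protocol = StudyProtocol(victim_doses=[], duration_min=duration, perpetrators=[reg],
                             observation_times_min=np.linspace(0, duration, 25))
    result = system.simulate(protocol, settings=FAST)
    pool = result.enzyme_pools[("CYP2B6", "liver")]
    expected = 1.0 + 3.8 * iu / (0.34 + iu)
    assert pool[-1] == pytest.approx(expected, rel=1e-3)
    assert np.all(np.diff(pool) >= -1e-9)


# ---------------------------------------------------------------------------
# population summaries


def test_population_of_identical_individuals_has_unit_geometric_sd(reference_system):
    protocol = standard_protocol(dose_mg=150, formulation="IR", duration_h=12.0,
                                 observation_times_h=np.array([1.0, 4.0, 12.0]))
    ref = build_reference_individual()
    pop_result = reference_system.simulate_population(protocol, [ref, ref], settings=FAST)
    single = reference_system.simulate(protocol, settings=FAST)
    mask = single.plasma_concentrations["bupropion"] > 0
    assert pop_result.geo_mean["bupropion"][mask] == pytest.approx(
        single.plasma_concentrations["bupropion"][mask], rel=1e-9
    )
    assert pop_result.geo_sd["bupropion"] == pytest.approx(np.ones_like(pop_result.times))


def test_two_point_geometric_statistics():
    c = np.array([1.0, 2.0, 4.0])
    geo_mean, geo_sd = geometric_summary(np.vstack([c, 4 * c]))
    assert geo_mean == pytest.approx(2 * c)
    assert geo_sd == pytest.approx(np.full(3, 2.0))


def test_empty_population_is_rejected(reference_system):
    protocol = standard_protocol(duration_h=6.0, observation_times_h=np.array([1.0]))
    with pytest.raises(ValueError, match="nonempty"):
        reference_system.simulate_population(protocol, [])
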