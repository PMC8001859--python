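import numpy as np
import pytest

from bupnet.network import standard_protocol
from bupnet.pk import ConcentrationProfile, mrd
from bupnet.synthetic import (
    SyntheticStudySpec,
    generate_observed_study,
    make_fixture_suite,
    read_study,
    write_study,
)
from tests.conftest import FAST

ZERO_IIV = {"enzyme_concentration": 0.0, "organ_volume": 0.0, "blood_flow": 0.0}
TIMES = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])


@pytest.fixture(scope="module")
def base_protocol():
    return standard_protocol(dose_mg=150, formulation="IR", duration_h=24.0,
                             observation_times_h=TIMES)


def _spec(protocol, **kw):
    kwargs = dict(protocol=protocol, n_subjects=1, residual_cv=0.0, iiv_cv=ZERO_IIV,
                  seed=0, sampling_times_h=TIMES)
    kwargs.update(kw)
    return SyntheticStudySpec(**kwargs)


def test_noise_free_single_subject_reproduces_the_model(reference_system, base_protocol):
    study = generate_observed_study(reference_system, _spec(base_protocol), settings=FAST)
    result = reference_system.simulate(study.protocol, settings=FAST)
    arm = study.arm("bupropion")
    predicted = np.interp(arm.times_h * 60.0, result.times,
                          result.plasma_concentrations["bupropion"])
    assert arm.mean_ng_ml == pytest.approx(predicted, rel=1e-9)
    assert np.all(arm.sd_ng_ml == 0.0)
    # pipeline closure: MRD of the generating model against its own study is 1
    obs = ConcentrationProfile(arm.times_h, arm.mean_ng_ml)
    pred = ConcentrationProfile(arm.times_h, predicted)
    assert mrd(obs, pred) == pytest.approx(1.0)


def test_same_seed_reproduces_the_study(reference_system, base_protocol):
    spec = _spec(base_protocol, residual_cv=0.25, n_subjects=8, seed=99)
    one = generate_observed_study(reference_system, spec, settings=FAST)
    two = generate_observed_study(reference_system, spec, settings=FAST)
    for a, b in zip(one.arms, two.arms):
        assert a.mean_ng_ml == pytest.approx(b.mean_ng_ml, rel=0.0)
        assert a.sd_ng_ml == pytest.approx(b.sd_ng_ml, rel=0.0)


def test_residual_noise_model_recovers_configured_cv(reference_system, base_protocol):
    cv, n = 0.2, 500
    study = generate_observed_study(
        reference_system, _spec(base_protocol, residual_cv=cv, n_subjects=n, seed=3),
        settings=FAST,
    )
    arm = study.arm("bupropion")
    empirical_cv = arm.sd_ng_ml / arm.mean_ng_ml
    se = cv / np.sqrt(2 * (n - 1))
    assert np.all(np.abs(empirical_cv - cv) < 4 * se)
    assert abs(empirical_cv.mean() - cv) < 3 * se


def test_expected_mrd_grows_with_residual_cv(reference_system, base_protocol):
    mrds = []
    for cv in (0.0, 0.1, 0.3):
        study = generate_observed_study(
            reference_system, _spec(base_protocol, residual_cv=cv, n_subjects=6, seed=7),
            settings=FAST,
        )
        result = reference_system.simulate(study.protocol, settings=FAST)
        arm = study.arm("bupropion")
        predicted = np.interp(arm.times_h * 60.0, result.times,
                              result.plasma_concentrations["bupropion"])
        mrds.append(mrd(ConcentrationProfile(arm.times_h, arm.mean_ng_ml),
                        ConcentrationProfile(arm.times_h, predicted)))
    assert mrds[0] < mrds[1] < mrds[2]


def test_sampling_beyond_protocol_duration_is_rejected(reference_system, base_protocol):
    spec = _spec(base_protocol, sampling_times_h=np.array([1.0, 48.0]))
    with pytest.raises(ValueError, match="beyond"):
        generate_observed_study(reference_system, spec, settings=FAST)


def test_study_roundtrips_through_the_serializer(tmp_path, reference_system, base_protocol):
    study = generate_observed_study(reference_system, _spec(base_protocol, seed=5),
                                    "roundtrip", settings=FAST)
    write_study(study, tmp_path)
    back = read_study(tmp_path, "roundtrip")
    assert back.study_id == study.study_id
    for a, b in zip(study.arms, back.arms):
        assert b.compound == a.compound
        assert b.mean_ng_ml == pytest.approx(a.mean_ng_ml)
    assert back.protocol.genotype == study.protocol.genotype
    assert back.protocol.victim_doses[0].formulation == "IR"
    assert back.metadata["seed"] == 5


def test_fixture_suite_covers_required_arms():
    protocols = make_fixture_suite(seed=0, include=("formulations", "doses", "genotypes", "ddi"),
                                   protocols_only=True)
    genotypes = {p.genotype for p in protocols.values()}
    assert {"*1|*1", "*1|*4", "*1|*6", "*6|*6"} <= genotypes
    perp_arms = [p for p in protocols.values() if p.perpetrators]
    assert len(perp_arms) >= 2
    doses = {d.amount_mg for p in protocols.values() for d in p.victim_doses}
    assert {20, 300} <= doses
    formulations = {d.formulation for p in protocols.values() for d in p.victim_doses}
    assert {"IR", "SR", "ER"} <= formulations


def test_rifampicin_fixture_places_all_perpetrator_doses_before_or_with_bupropion():
    protocols = make_fixture_suite(seed=0, include=("ddi",), protocols_only=True)
    rif = protocols["ddi_rifampicin"]
    bup_time = min(d.time_min for d in rif.victim_doses)
    rif_times = [t for reg in rif.perpetrators if reg.compound == "rifampicin"
                 for _, t in reg.doses]
    assert rif_times and all(t <= bup_time for t in rif_times)
    assert rif.victim_doses[0].formulation == "SR"
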