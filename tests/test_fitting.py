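import numpy as np
import pytest

from bupnet.compounds import Compound
from bupnet.config import ConfigurationError
from bupnet.engine import DoseEvent, ModelSystem, SimSettings, StudyProtocol
from bupnet.fitting import (
    FitParameter,
    FitSpec,
    fit_parameters,
    local_sensitivity,
    objective_value,
)
from bupnet.network import NetworkScenario, standard_protocol
from bupnet.synthetic import SyntheticStudySpec, generate_observed_study
from tests.conftest import FAST

ZERO_IIV = {"enzyme_concentration": 0.0, "organ_volume": 0.0, "blood_flow": 0.0}
TIMES = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 18.0, 24.0])
KCAT_PATH = "compounds.bupropion.cyp2b6_alleles.*1.kcat"
KCAT_TRUTH = 10.87


@pytest.fixture(scope="module")
def truth_study(reference_system):
    protocol = standard_protocol(dose_mg=150, formulation="IR", duration_h=24.0,
                                 observation_times_h=TIMES)
    spec = SyntheticStudySpec(protocol=protocol, n_subjects=1, residual_cv=0.0,
                              iiv_cv=ZERO_IIV, seed=2, sampling_times_h=TIMES)
    return generate_observed_study(reference_system, spec, "truth", settings=FAST)


def test_unresolvable_parameter_path_is_a_configuration_error(truth_study):
    spec = FitSpec([FitParameter("compounds.bupropion.no_such_field", 1.0, 2.0)],
                   [truth_study], n_starts=1)
    with pytest.raises(ConfigurationError):
        fit_parameters(spec, settings=FAST)


def test_objective_dominance_and_dataset_order_invariance(truth_study, reference_system):
    protocol = standard_protocol(dose_mg=150, formulation="IR", duration_h=24.0,
                                 observation_times_h=TIMES)
    spec2 = SyntheticStudySpec(protocol=protocol, n_subjects=1, residual_cv=0.0,
                               iiv_cv=ZERO_IIV, seed=4, sampling_times_h=TIMES[:5])
    other = generate_observed_study(reference_system, spec2, "other", settings=FAST)
    fit_spec = FitSpec([FitParameter(KCAT_PATH, 2.0, 50.0)], [truth_study, other], n_starts=1)
    at_truth = objective_value({KCAT_PATH: KCAT_TRUTH}, fit_spec, settings=FAST)
    perturbed = objective_value({KCAT_PATH: 2 * KCAT_TRUTH}, fit_spec, settings=FAST)
    assert at_truth <= perturbed
    reordered = FitSpec([FitParameter(KCAT_PATH, 2.0, 50.0)], [other, truth_study], n_starts=1)
    assert objective_value({KCAT_PATH: KCAT_TRUTH}, reordered, settings=FAST) == pytest.approx(
        at_truth, abs=1e-12
    )


def test_start_at_truth_converges_immediately(truth_study):
    # a box collapsed around the truth forces the single start onto it
    param = FitParameter(KCAT_PATH, KCAT_TRUTH * 0.999, KCAT_TRUTH * 1.001)
    fit = fit_parameters(FitSpec([param], [truth_study], n_starts=1, seed=0), settings=FAST)
    assert fit.objective < 1e-10
    assert fit.estimates[KCAT_PATH] == pytest.approx(KCAT_TRUTH, rel=1e-3)


def test_sensitivity_of_parameter_not_entering_the_model_is_zero():
    scenario = NetworkScenario()
    protocol = standard_protocol(dose_mg=150, formulation="IR", duration_h=24.0,
                                 observation_times_h=TIMES)
    # threohydrobupropion disposition cannot feed back into the parent
    result = local_sensitivity(scenario, protocol, "compounds.threohydrobupropion.fu",
                               compound="bupropion", settings=FAST)
    assert abs(result.s_coefficient) < 1e-4


def test_linear_one_compartment_clearance_sensitivity_is_minus_one():
    comp = Compound(name="probe", mw=200.0, fu=1.0)
    volume, dose_mg = 40.0, 100.0
    obs = np.linspace(0.0, 4800.0, 241)
    protocol = StudyProtocol(victim_doses=[DoseEvent("probe", dose_mg, 0.0, route="iv")],
                             duration_min=4800.0, observation_times_min=obs)

    def auc_of_clearance(cl):
        system = ModelSystem.one_compartment(comp, volume, cl)
        result = system.simulate(protocol, settings=SimSettings(rtol=1e-10, atol=1e-12))
        return np.trapezoid(result.concentrations[("probe", "central")], result.times)

    sens = local_sensitivity(NetworkScenario(), protocol, 0.5, auc_fn=auc_of_clearance)
    assert sens.s_coefficient == pytest.approx(-1.0, abs=0.02)
    # antisymmetry: the same clearance expressed as its reciprocal flips the sign
    sens_inv = local_sensitivity(
        NetworkScenario(), protocol, 2.0, auc_fn=lambda r: auc_of_clearance(1.0 / r)
    )
    assert sens_inv.s_coefficient == pytest.approx(-sens.s_coefficient, abs=0.04)


def test_fraction_unbound_dominates_bupropion_auc_sensitivity():
    """The parent AUC is most sensitive to its fraction unbound (IR regimen)."""
    scenario = NetworkScenario()
    protocol = standard_protocol(dose_mg=150, formulation="IR", duration_h=24.0,
                                 observation_times_h=TIMES)
    paths = [
        "compounds.bupropion.fu",
        KCAT_PATH,
        "compounds.bupropion.logp",
        "compounds.bupropion.binding.kd",
    ]
    coefficients = {
        path: abs(local_sensitivity(scenario, protocol, path, settings=FAST).s_coefficient)
        for path in paths
    }
    assert max(coefficients, key=coefficients.get) == "compounds.bupropion.fu"
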