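"""Parameter recovery: fitting the CYP2B6 catalytic rate constant.

Generates a noise-free synthetic study at the packaged truth, then refits the
wildtype CYP2B6 kcat by multistart Levenberg-Marquardt least squares on the
log-scale residuals and prints the recovered value.
"""

import numpy as np

from bupnet.engine import SimSettings
from bupnet.fitting import FitParameter, FitSpec, fit_parameters
from bupnet.network import assemble_network, standard_protocol
from bupnet.synthetic import SyntheticStudySpec, generate_observed_study

fast = SimSettings(rtol=1e-6, atol=1e-8)
times = np.array([0.5, 1, 2, 4, 8, 12, 18, 24.0])
system = assemble_network()
protocol = standard_protocol(dose_mg=150, formulation="IR", duration_h=24.0,
                             observation_times_h=times)
spec = SyntheticStudySpec(protocol=protocol, n_subjects=1, residual_cv=0.0,
                          iiv_cv={"enzyme_concentration": 0.0, "organ_volume": 0.0,
                                  "blood_flow": 0.0},
                          seed=2, sampling_times_h=times)
truth_study = generate_observed_study(system, spec, "truth", settings=fast)

path = "compounds.bupropion.cyp2b6_alleles.*1.kcat"
fit = fit_parameters(
    FitSpec([FitParameter(path, lower=2.0, upper=50.0)], [truth_study],
            n_starts=2, seed=3),
    settings=fast,
)
print(f"true kcat  : 10.87 1/min")
print(f"fitted kcat: {fit.estimates[path]:.4f} 1/min  (objective {fit.objective:.2e})")
for entry in fit.trace:
    print(f"  start {entry['start']}: estimate {entry['estimates'][0]:.3f}, "
          f"objective {entry['objective']:.2e}")
# Noise-free data and a correct model make the objective vanish at the truth;
# the multistart trace shows each local search landing on the same optimum.
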