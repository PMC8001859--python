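"""Synthetic observed study and model-performance statistics.

Generates a synthetic clinical study (12 subjects, 20% proportional residual
noise) from the model itself, then scores the model against it with the mean
relative deviation (MRD) of the profile and the geometric mean fold error
(GMFE) of AUC — the statistics used to qualify PBPK models.
"""

import numpy as np

from bupnet.engine import SimSettings
from bupnet.network import assemble_network, standard_protocol
from bupnet.pk import ConcentrationProfile, auc_last, gmfe, mrd, within_twofold
from bupnet.synthetic import SyntheticStudySpec, generate_observed_study

fast = SimSettings(rtol=1e-6, atol=1e-8)
times = np.array([0.5, 1, 2, 4, 8, 12, 24, 36, 48.0])
system = assemble_network()
protocol = standard_protocol(dose_mg=150, formulation="SR", duration_h=48.0,
                             observation_times_h=times)
spec = SyntheticStudySpec(protocol=protocol, n_subjects=12, residual_cv=0.2,
                          iiv_cv={"enzyme_concentration": 0.0, "organ_volume": 0.0,
                                  "blood_flow": 0.0},
                          seed=7, sampling_times_h=times)
study = generate_observed_study(system, spec, "demo_study", settings=fast)

prediction = system.simulate(study.protocol, settings=fast)
print("compound            MRD    GMFE_AUC   within 2-fold")
for arm in study.arms:
    predicted = np.interp(arm.times_h * 60.0, prediction.times,
                          prediction.plasma_concentrations[arm.compound])
    observed = ConcentrationProfile(arm.times_h, arm.mean_ng_ml)
    modelled = ConcentrationProfile(arm.times_h, predicted)
    g = gmfe([(auc_last(modelled), auc_last(observed))])
    print(f"{arm.compound:18s} {mrd(observed, modelled):6.3f}  {g:8.3f}   "
          f"{within_twofold(g)}")
# With noise-free data both statistics collapse to exactly 1; the values here
# reflect only the injected residual error, so they stay well inside the
# 2-fold acceptance band.
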