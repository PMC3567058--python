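import numpy as np
import pytest

from hemorisk import CohortSpec, generate_cohort, sample_nested_case_control

ZERO_LOADINGS = {k: (0.0, 0.0, 0.0) for k in
                 ("age", "male", "smoking", "diabetes", "bmi", "sbp",
                  "tchol", "log_tg")}
ZERO_COV_ORS = {k: 0.0 for k in
                ("age", "male", "smoking", "diabetes", "bmi", "sbp",
                 "tchol", "log_tg")}


def univariate_spec(n=20000, seed=0, or_true=1.3, rdr=0.5, n_repeat=500):
    """Single active marker (t-PA slot), no covariate confounding: the
    setting in which attenuation and dilution correction are analytic."""
    return CohortSpec(
        n_participants=n, seed=seed,
        true_log_or_per_sd=(float(np.log(or_true)), 0.0, 0.0),
        target_rdrs=(rdr, rdr, rdr),
        covariate_marker_loadings=dict(ZERO_LOADINGS),
        covariate_log_ors=dict(ZERO_COV_ORS),
        repeat_subsample_n=n_repeat)


@pytest.fixture(scope="session")
def default_cohort():
    """Moderate-size cohort under the default study-like conditions."""
    return generate_cohort(CohortSpec(n_participants=12000, seed=11))


@pytest.fixture(scope="session")
def ncc_sample(default_cohort):
    cc = sample_nested_case_control(default_cohort, ratio=1.88, seed=12)
    return cc.subset(default_cohort)
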