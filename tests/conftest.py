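import numpy as np
import pytest

from resconfound import CorrelationTriad, calibrate_to_observed

# Published correlation block and CI bounds for the three-trait survey triad
# (SEB = log mean parental income, CA = first-factor ability score,
# Degree = highest academic degree), used as calibration targets and
# containment checks throughout the suite.
PRINTED_TRIAD = CorrelationTriad(r_sc=0.395, r_sd=0.353, r_cd=0.508, n=4654)

#: (outcome, predictor) -> printed 95% CI of the standardized adjusted effect
PRINTED_EFFECT_CIS = {
    ("ca", "seb"): (0.232, 0.285),
    ("edu", "seb"): (0.159, 0.214),
    ("seb", "ca"): (0.249, 0.306),
    ("edu", "ca"): (0.403, 0.455),
    ("seb", "edu"): (0.170, 0.229),
    ("ca", "edu"): (0.402, 0.454),
}

PRINTED_DIFF_CI = (-0.081, -0.021)


@pytest.fixture(scope="session")
def printed_triad():
    return PRINTED_TRIAD


@pytest.fixture(scope="session")
def calibrated_spec():
    """Latent chain spec whose observed correlations match the printed triad."""

    def _make(n=4654, seed=0):
        return calibrate_to_observed(PRINTED_TRIAD, n=n, seed=seed)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
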