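import numpy as np
import pytest

from ubam import ModelParams

# Canonical parameter sets used throughout the suite.  "endemic" has
# R_m ~ 3.5; "media" pairs it with a slower media field; "threshold" is the
# set used for the media-threshold closed forms.
ENDEMIC = dict(mu=0.05, alpha=2, beta=0.01, rho=0.3, gamma=0.08,
               phi=0.5, phi0=0.1, c=5, m0=4)
MEDIA_SLOW = dict(mu=0.05, alpha=2, beta=0.2, rho=0.3, gamma=0.08,
                  phi=0.05, phi0=0.01, c=5, m0=4)
THRESHOLD = dict(mu=0.05, alpha=2, beta=0.2, rho=0.3, gamma=0.08,
                 phi=0.5, phi0=0.1, c=5, m0=4)
PULSE = dict(mu=0.05, alpha=2, beta=0.001, rho=0.4, gamma=0.4,
             phi=0.7, phi0=0.1, c=5, m0=5)

# independently computed reference values: quadratic formula for the
# endemic bootlegger fraction, then steady-state back-substitution, done by
# hand before implementation
ENDEMIC_B_STAR = 0.06126127274824206
ENDEMIC_A_STAR = 0.5070630508868689
ENDEMIC_M_STAR = 4.306306363741210
ENDEMIC_U_STAR = 1.0 - ENDEMIC_B_STAR - ENDEMIC_A_STAR


@pytest.fixture
def endemic_params() -> ModelParams:
    return ModelParams(**ENDEMIC)


@pytest.fixture
def media_slow_params() -> ModelParams:
    return ModelParams(**MEDIA_SLOW)


@pytest.fixture
def threshold_params() -> ModelParams:
    return ModelParams(**THRESHOLD)


@pytest.fixture
def pulse_params() -> ModelParams:
    return ModelParams(**PULSE)


def random_params(rng: np.random.Generator) -> ModelParams:
    """Log-uniform draw over a broad physically plausible box."""
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return ModelParams(
        mu=lu(0.01, 0.2), alpha=lu(0.1, 5.0), beta=lu(0.005, 0.5),
        rho=lu(0.05, 1.0), gamma=lu(0.01, 0.5), phi=lu(0.01, 1.0),
        phi0=lu(0.005, 0.5), c=lu(0.5, 10.0), m0=lu(0.5, 10.0),
    )
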