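import numpy as np
import pytest

from msceapc import BiologicalParams, TrendParams, get_preset


@pytest.fixture(scope="session")
def black_males():
    """Published posterior-median parameters, black males."""
    return get_preset("black_males")


@pytest.fixture(scope="session")
def white_males():
    return get_preset("white_males")


@pytest.fixture
def flat_params():
    """Constant-rate model: no period/cohort trends, no attenuation."""
    bp = BiologicalParams(nu0=2e-4, mu1=10.0, mu2=5e-8, g0=0.15)
    tp = TrendParams(w1=0.0, w2=0.0, y0=1960.0, s0=0.5, b1=0.0, b2=0.0,
                     use_log_attenuation=False)
    return bp, tp


@pytest.fixture
def inflated_params():
    """Desk-scale rates for stochastic-oracle runs: events are common and
    clones stay small (low alpha, high mu2)."""
    bp = BiologicalParams(nu0=0.05, mu1=0.4, mu2=0.02, g0=0.4, alpha=2.0,
                          lag=0.0)
    tp = TrendParams(w1=0.0, w2=0.0, y0=1960.0, s0=1.0, b1=0.0, b2=0.0,
                     use_log_attenuation=False)
    return bp, tp


def random_valid_rates(rng, n):
    """Random biologically plausible (alpha, beta, mu2) triples."""
    alpha = rng.uniform(0.5, 30.0, n)
    g = rng.uniform(0.0, 0.5, n)
    mu2 = 10.0 ** rng.uniform(-9.0, -1.0, n)
    beta = alpha - g - mu2
    ok = beta > 0
    return alpha[ok], beta[ok], mu2[ok]
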