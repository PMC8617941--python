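import cmath
import math

import numpy as np
import pytest

import thermodiel as td

EPS0 = 8.8541878128e-12


def oracle_eps(eps_inf, sigma_s, poles, f):
    """Hand-coded scalar Cole–Cole evaluation (independent of the package
    internals): eps_inf + sum d/(1+(j w tau)^(1-a)) + sigma/(j w eps0)."""
    w = 2.0 * math.pi * f
    val = complex(eps_inf, 0.0)
    for d, tau, a in poles:
        val += d / (1.0 + (1j * w * tau) ** (1.0 - a))
    if sigma_s:
        val += sigma_s / (1j * w * EPS0)
    return val


@pytest.fixture(scope="session")
def published1():
    return td.published_temperature_model(1)


@pytest.fixture(scope="session")
def published2():
    return td.published_temperature_model(2)


@pytest.fixture(scope="session")
def literature():
    return td.literature_models()


@pytest.fixture(scope="session")
def band_grid():
    """The measurement grid: 0.5–40 GHz in 25 MHz steps (1581 points)."""
    return td.CampaignDesign().frequency_grid


@pytest.fixture(scope="session")
def log_grid():
    return np.geomspace(0.5e9, 40e9, 100)
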