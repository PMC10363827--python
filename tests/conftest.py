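from datetime import date

import numpy as np
import pytest
from scipy.special import expit

from owlprov import synthetic
from owlprov.aux_models import LaborObservation
from owlprov.io_data import MassRecord
from owlprov.mcmc import ChainConfig


def make_beta_labor_data(rng, b0, b1, n=300, phi=10.0):
    """Interval-level female shares drawn from the beta GLM itself."""
    x = rng.uniform(1, 23, n)
    mu = expit(b0 + b1 * x)
    p = np.clip(rng.beta(mu * phi, (1 - mu) * phi), 1e-4, 1 - 1e-4)
    return [LaborObservation("A", float(xi), float(pi), 3)
            for xi, pi in zip(x, p)]


def make_mass_records(rng, n_ind, slope, intercept=80.0, sd_int=2.0,
                      sigma=1.5, cohort="adult_female"):
    """Adult weighings with per-individual intercepts and 1-3 captures."""
    recs = []
    for j in range(n_ind):
        u = rng.normal(0, sd_int)
        for day in rng.choice(np.arange(152, 201), rng.integers(1, 4),
                              replace=False):
            mass = intercept + u + slope * day + rng.normal(0, sigma)
            recs.append(MassRecord(f"B{j:03d}", cohort, date(2010, 6, 1),
                                   int(day), None, float(mass)))
    return recs


@pytest.fixture(scope="session")
def truth():
    return synthetic.default_truth()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quick_chains():
    """Short chains for functional checks where precision is secondary."""
    return ChainConfig(n_iterations=1500, n_burnin=600, seed=11)


@pytest.fixture
def standard_chains():
    """Moderate chains: long enough to converge on the test problems."""
    return ChainConfig(n_iterations=4000, n_burnin=1500, seed=11)
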