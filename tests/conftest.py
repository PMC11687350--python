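"""Shared fixtures: bundled truth, a mid-sized synthetic census, and fitted
model sets. Session-scoped because simulation and fitting dominate runtime."""

import copy

import pytest

from polydem import (default_truth, fit_genotype_modelset, make_mesh,
                     simulate_census, simulate_environment)
from polydem.synthetic import GenotypeTruth


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def env_series():
    return simulate_environment(n_blocks=30, years=3,
                                moisture_herbivory_corr=-0.4, seed=101)


@pytest.fixture(scope="session")
def census(truth, env_series):
    # 2100 transitions per genotype: enough for stable fits, cheap to make
    return simulate_census(truth, env_series, n_plants=700, n_years=3,
                           seed=102)


@pytest.fixture(scope="session")
def truth_modelset_bb(truth):
    return truth["BB"].modelset("BB")


@pytest.fixture(scope="session")
def fitted_bb(census, truth):
    """BB vital rates refitted at the generating model forms."""
    return fit_genotype_modelset(census, "BB", truth["BB"].recruitment,
                                 term_sets=truth["BB"].term_sets())


@pytest.fixture(scope="session")
def mesh():
    return make_mesh(0.3, 4.0, m=100, pad=1.1)


@pytest.fixture(scope="session")
def mesh_small():
    return make_mesh(0.3, 4.0, m=40, pad=1.1)


def strip_drivers(gt: GenotypeTruth) -> GenotypeTruth:
    """Truth variant whose vital rates ignore moisture and herbivory."""
    coefs = {k: {t: v for t, v in c.items() if t in ("intercept", "z")}
             for k, c in copy.deepcopy(gt.coefs).items()}
    return GenotypeTruth(coefs=coefs, recruitment=gt.recruitment,
                         seed_sd=gt.seed_sd)


@pytest.fixture(scope="session")
def env_free_modelset_bb(truth):
    return strip_drivers(truth["BB"]).modelset("BB")
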