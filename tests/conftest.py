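import numpy as np
import pandas as pd
import pytest

from megamir.io import CountMatrix
from megamir import synthetic as sy


def build_count_matrix(y, groups, sexes=None, organ="x") -> CountMatrix:
    """Wrap a numpy count array as a CountMatrix with minimal metadata."""
    y = np.asarray(y)
    ids = [f"s{i}" for i in range(y.shape[1])]
    counts = pd.DataFrame(y, index=[f"f{i}" for i in range(y.shape[0])], columns=ids)
    meta = pd.DataFrame(
        {
            "group": list(groups),
            "sex": list(sexes) if sexes is not None else ["NA"] * y.shape[1],
            "organ": organ,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return CountMatrix(counts=counts, sample_meta=meta)


def nb_draws(rng, mean, phi, size):
    """NB(mu, var = mu + phi mu^2) sampler used as the tests' own generator."""
    if phi <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean), size=size)


@pytest.fixture(scope="session")
def default_config() -> sy.SimulationConfig:
    return sy.SimulationConfig()  # seed 0: the canonical synthetic bundle


@pytest.fixture(scope="session")
def annotation(default_config):
    return sy.simulate_annotation(default_config)


@pytest.fixture(scope="session")
def mirna_bundle(default_config, annotation):
    counts, truth = sy.simulate_mirna_counts(annotation, default_config)
    return counts, truth.set_index("feature_id")
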