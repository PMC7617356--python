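import numpy as np
import pandas as pd
import pytest

from mosr.cohort import default_config, sample_cohort
from mosr.trees import random_tree, DEFAULT_OPERATORS


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort shared across tests (1190 patients)."""
    cfg = default_config(n_patients=1190, seed=7)
    return cfg, sample_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix():
    """Tiny labelled feature frame for engine-level tests."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["x1", "x2", "x3"])
    y = (X["x1"].to_numpy() + 0.3 * rng.normal(size=60) > 0).astype(int)
    return X, y


def make_random_trees(seed, n, features=("x1", "x2", "x3"), max_depth=4):
    rng = np.random.default_rng(seed)
    return [random_tree(rng, list(features), list(DEFAULT_OPERATORS),
                        (-2.0, 2.0), max_depth,
                        method="grow" if i % 2 else "full")
            for i in range(n)]
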