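import numpy as np
import pytest

import apcpred as ap

#: single-candidate grid for fast protocol tests where tuning is not the point
TINY_SVM = ap.SVMConfig(c_grid=(1.0,), gamma_grid=(2.0,), inner_folds=2)


@pytest.fixture(scope="session")
def planted_dataset():
    """Default study conditions: 200+200 20-mers, 10 planted pairs, 90% enrichment."""
    return ap.generate(ap.PlantSpec(seed=7))


@pytest.fixture(scope="session")
def planted_report(planted_dataset):
    """Nested fivefold CV on the planted dataset with the default grids."""
    return ap.nested_cross_validate(planted_dataset, seed=11)


@pytest.fixture(scope="session")
def small_planted_dataset():
    """A reduced planted dataset for fast protocol-shape tests."""
    return ap.generate(ap.PlantSpec(n_pos=30, n_neg=30, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
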