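import numpy as np
import pytest
from hypothesis import settings

import lssfind as lf

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fig_forest():
    """The exact two-tree population ensemble for E[Y|X] = 1(X1<=.5) 1(X2<=.5)."""
    return lf.build_illustrative_ensemble()


@pytest.fixture(scope="session")
def fig_transactions(fig_forest):
    return lf.extract_transactions(fig_forest, 0.01)


@pytest.fixture(scope="session")
def pair_model():
    """The J=1, L=2, p=20 benchmark model at 50% coverage."""
    return lf.build_simulation_model(1, 2, 20)


@pytest.fixture(scope="session")
def pair_data(pair_model):
    return lf.sample_dataset(pair_model, 1000, snr=5.0, seed=11)


@pytest.fixture(scope="session")
def small_fitted_forest(pair_data):
    """A modest fitted ensemble shared by structural tests."""
    return lf.fit_forest(pair_data, n_trees=10, mtry=10, seed=3)


def sf(k, b):
    return lf.SignedFeature(k, b)


@pytest.fixture
def S():
    return sf


def enumerate_supports(transactions, smax):
    """Independent miner oracle: weighted support of every signed set of size
    <= smax over the items observed in the transactions, by direct summation."""
    from itertools import combinations
    from math import fsum

    items = sorted({it for t in transactions for it in t.items})
    out = {}
    for r in range(1, smax + 1):
        for combo in combinations(items, r):
            s = frozenset(combo)
            if len({f.index for f in s}) < len(s):
                continue  # both signs of one feature never co-occur
            out[s] = fsum(t.weight for t in transactions if s <= t.items)
    return out
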