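import copy

import numpy as np
import pandas as pd
import pytest

import cariesim as cs
from cariesim.simulate import PSAResults


@pytest.fixture(scope="session")
def fixture_obj():
    return cs.make_fixture(seed=0, n_draws=50)


@pytest.fixture()
def template(fixture_obj):
    return copy.deepcopy(fixture_obj.template)


def make_psa(costs, effects, sampled=None, strategies=("A", "B")):
    """Hand-built PSAResults from per-draw (cost, effect) matrices."""
    costs = np.asarray(costs, dtype=float)
    effects = np.asarray(effects, dtype=float)
    n = costs.shape[0]
    if sampled is None:
        sampled = pd.DataFrame({"draw": np.arange(n)})
    else:
        sampled = pd.DataFrame(sampled)
        sampled.insert(0, "draw", np.arange(n))
    return PSAResults(list(strategies), costs, effects, sampled)
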