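import logging

import numpy as np
import pandas as pd
import pytest

from fedgamlss.model import ModelSpec, ParamSpec, SmoothTerm
from fedgamlss.pooled import fit_pooled

logging.getLogger("fedgamlss").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def gaussian_linear_fixture():
    """Small Gaussian dataset with a linear mean effect, plus its tight fit."""
    rng = np.random.default_rng(11)
    n = 300
    x = rng.uniform(0.0, 10.0, n)
    y = 2.0 + 0.5 * x + rng.normal(0.0, 1.3, n)
    df = pd.DataFrame({"x": x})
    spec = ModelSpec(
        family="NO",
        params=(ParamSpec(fixed=("x",)), ParamSpec()),
        c=1e-8,
        max_outer=300,
    )
    state, model = fit_pooled(y, df, spec)
    return {"y": y, "df": df, "spec": spec, "state": state, "model": model}


@pytest.fixture(scope="session")
def gaussian_smooth_fixture():
    """Gaussian data with a sine mean, fitted with a fixed-effect smooth."""
    rng = np.random.default_rng(5)
    n = 500
    x = rng.uniform(0.0, 10.0, n)
    y = np.sin(x) + 0.2 * x + rng.normal(0.0, 0.4, n)
    df = pd.DataFrame({"x": x})
    spec = ModelSpec(
        family="NO",
        params=(ParamSpec(smooth=SmoothTerm("x", 8)), ParamSpec()),
        c=1e-8,
        max_outer=300,
    )
    state, model = fit_pooled(y, df, spec)
    return {"y": y, "df": df, "spec": spec, "state": state, "model": model}


def random_partition(rng, n, m):
    """Random assignment of n subjects into m nonempty groups."""
    while True:
        labels = rng.integers(0, m, n)
        if len(np.unique(labels)) == m:
            return labels
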