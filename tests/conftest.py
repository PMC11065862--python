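import numpy as np
import pandas as pd
import pytest

from bioage.survey import SurveyDesign


@pytest.fixture
def iid_design():
    """Factory: degenerate design (equal weights, one stratum, each record
    its own PSU) under which every estimator must reduce to its textbook
    unweighted form."""

    def make(n, weight=1.0):
        return SurveyDesign(
            strata=np.zeros(n, dtype=int),
            psu=np.arange(n),
            weights=np.full(n, float(weight)),
        )

    return make


@pytest.fixture
def toy_logistic_data():
    """Small two-covariate logistic data set with a known generating model."""
    rng = np.random.default_rng(42)
    n = 500
    x1 = rng.normal(0, 1, n)
    x2 = rng.binomial(1, 0.4, n).astype(float)
    lp = -0.5 + 0.8 * x1 - 0.6 * x2
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2})
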