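import warnings

import numpy as np
import pandas as pd
import pytest

from digibench.simulate import (CohortParams, LearningCurveParams,
                                generate_cross_sectional,
                                generate_longitudinal)


@pytest.fixture(autouse=True)
def _quiet_mixedlm():
    # statsmodels MixedLM emits convergence chatter on tiny panels
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="statsmodels")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def cross_sectional_default():
    return generate_cross_sectional(CohortParams(seed=11))


@pytest.fixture(scope="session")
def longitudinal_default():
    return generate_longitudinal(LearningCurveParams(seed=7))


@pytest.fixture
def paired_sitting_scores(longitudinal_default):
    from digibench.scoring import sitting_scores
    t1 = sitting_scores(longitudinal_default, "trial1")
    t2 = sitting_scores(longitudinal_default, "trial2")
    pair = t1.merge(t2, on=["subject_id", "cohort", "sitting"],
                    suffixes=("_1", "_2"))
    return pair.rename(columns={"score_90s_1": "trial1_score",
                                "score_90s_2": "trial2_score"})
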