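import numpy as np
import pytest

from trecscreen.cohort import CohortConfig, Condition
from trecscreen.published import REFERENCE_STRATA


@pytest.fixture
def rng():
    return np.random.default_rng(20210825)


@pytest.fixture
def term_stratum():
    """The most mature gestational-age stratum (weeks 40-43)."""
    return next(s for s in REFERENCE_STRATA if s.label == "40-43")


@pytest.fixture
def healthy_term_config(term_stratum):
    """Healthy term newborns only: no cases, no technical failures."""
    return CohortConfig(
        n_newborns=5_000,
        n_non_newborns=0,
        ga_mixture=[(term_stratum, 1.0)],
        case_rates={},
        tech_failure_rate=0.0,
        unknown_ga_rate=0.0,
        seed=7,
    )


@pytest.fixture
def mixed_config():
    """Small cohort with strongly elevated case rates for end-to-end tests."""
    cfg = CohortConfig(n_newborns=4_000, n_non_newborns=50, seed=11)
    cfg.case_rates = {
        Condition.SCID: 0.002,
        Condition.LYMPHOPENIA_NON_SCID: 0.004,
        Condition.FP_LOW_TREC: 0.004,
    }
    cfg.tech_failure_rate = 0.002
    return cfg
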