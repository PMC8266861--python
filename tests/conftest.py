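import numpy as np
import pytest

from dcepcr.features import FilterBankExtractor
from dcepcr.synthetic import (SyntheticCohortConfig, SyntheticPhantomConfig,
                              gen_dce_patient, gen_feature_cohort)


@pytest.fixture(scope="session")
def extractor():
    return FilterBankExtractor(seed=0)


@pytest.fixture(scope="session")
def phantom_case():
    """Default phantom patient (pCR): series, planted mask, LD."""
    cfg = SyntheticPhantomConfig(seed=3)
    series, mask, ld = gen_dce_patient(cfg, label=1)
    return cfg, series, mask, ld


@pytest.fixture(scope="session")
def planted_small():
    """Small, strongly separated cohort for evaluation tests."""
    cfg = SyntheticCohortConfig(n_pcr=12, n_nonpcr=20, n_features=30,
                                informative_idx=frozenset(range(5)),
                                effect_size=3.0, seed=11)
    X, y, info = gen_feature_cohort(cfg)
    return X, y, info


def rng(seed=0):
    return np.random.default_rng(seed)
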