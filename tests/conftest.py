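import numpy as np
import pandas as pd
import pytest

from subtyperisk.cohort import generate_cohort
from subtyperisk.config import single_gene_config

NO_MISSING = {"er": 0.0, "pr": 0.0, "erbb2": 0.0, "grade": 0.0}
THREE_COUNTRIES = {"UK": 0.4, "Germany": 0.35, "Sweden": 0.25}


@pytest.fixture(scope="session")
def small_cohort():
    """A modest single-gene cohort with default (study-rate) missingness."""
    cfg = single_gene_config("BRCA2", carrier_freq=0.05, age_trend=1.0,
                             n_cases=2000, n_controls=2000, seed=42,
                             countries=dict(THREE_COUNTRIES))
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def complete_cohort():
    """Same design but with fully observed markers."""
    cfg = single_gene_config("BRCA2", carrier_freq=0.05, age_trend=1.0,
                             n_cases=2000, n_controls=2000, seed=42,
                             countries=dict(THREE_COUNTRIES),
                             missingness=dict(NO_MISSING))
    return generate_cohort(cfg)


def table_to_rows(counts):
    """Expand {(exposure, outcome): n} into a flat (X, y) dataset.

    X has an intercept and the exposure indicator; y is the integer
    outcome code.  Used to feed exact contingency tables to the fitters.
    """
    xs, ys = [], []
    for (exposure, outcome), n in counts.items():
        xs.extend([[1.0, float(exposure)]] * n)
        ys.extend([outcome] * n)
    return np.asarray(xs), np.asarray(ys)
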