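import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cinsig.cohort import CohortSpec, generate_cohort
from cinsig.matrix import (ENDOGENOUS, HOUSEKEEPING, NEGATIVE, POSITIVE,
                           ExpressionMatrix)
from cinsig.nanostring import normalize_counts


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-trial cohort with the default planted signature."""
    return generate_cohort(CohortSpec(n_trial1=160, n_trial2=160, seed=11))


@pytest.fixture(scope="session")
def normalized(small_cohort):
    expr, info = normalize_counts(small_cohort.expression)
    return expr


def toy_matrix(values, classes, samples=None, scale="raw"):
    """Build a small ExpressionMatrix from a dict probe -> row."""
    df = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    if samples is not None:
        df.columns = samples
    pc = pd.Series(classes)
    return ExpressionMatrix(values=df, probe_class=pc, scale=scale)


@pytest.fixture
def control_toy():
    """2 samples where B's positive controls are exactly 2x A's."""
    return toy_matrix(
        {
            "POS1": [4.0, 8.0],
            "POS2": [16.0, 32.0],
            "NEG1": [0.0, 0.0],
            "NEG2": [0.0, 0.0],
            "HK1": [10.0, 10.0],
            "G1": [100.0, 100.0],
            "G2": [50.0, 60.0],
        },
        {"POS1": POSITIVE, "POS2": POSITIVE, "NEG1": NEGATIVE,
         "NEG2": NEGATIVE, "HK1": HOUSEKEEPING, "G1": ENDOGENOUS,
         "G2": ENDOGENOUS},
        samples=["A", "B"],
    )
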