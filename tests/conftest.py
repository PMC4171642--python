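"""Shared fixtures: small synthetic cohorts and the published classifier."""

import numpy as np
import pandas as pd
import pytest

from cafsig import (Cohort, SyntheticParams, generate_cohort,
                    PUBLISHED_CLASSIFIER)


@pytest.fixture(scope="session")
def default_params() -> SyntheticParams:
    return SyntheticParams()


@pytest.fixture(scope="session")
def small_params() -> SyntheticParams:
    return SyntheticParams(n_samples=120, n_genes=30)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    cohort, truth = generate_cohort(small_params, seed=7)
    return cohort, truth


@pytest.fixture(scope="session")
def classifier():
    return PUBLISHED_CLASSIFIER


def make_cohort_from_arrays(expr: np.ndarray, clinical: dict,
                            genes=None, dataset_id="fixture") -> Cohort:
    """Tiny hand-built cohort for oracle tests."""
    n = expr.shape[0]
    ids = [f"P{i:03d}" for i in range(1, n + 1)]
    genes = genes or [f"g{j}" for j in range(expr.shape[1])]
    cohort = Cohort(
        pd.DataFrame(expr, index=ids, columns=genes),
        pd.DataFrame(clinical, index=ids),
        dataset_id,
    )
    cohort.validate()
    return cohort
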