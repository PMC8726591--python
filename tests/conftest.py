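import numpy as np
import pandas as pd
import pytest

import quantiptw as q


@pytest.fixture(scope="session")
def vocab_cohort():
    """Complete-data vocabulary-style cohort, n=64."""
    truth = q.truth_vocab(seed=7).replace(miss_rates={})
    table, params = q.generate_cohort(truth)
    return table, params


@pytest.fixture(scope="session")
def vocab_cohort_missing():
    """Vocabulary cohort with the default MAR missingness pattern."""
    table, params = q.generate_cohort(q.truth_vocab(seed=7))
    return table, params


@pytest.fixture(scope="session")
def big_confounded_cohort():
    """Large strongly confounded cohort for balance/weighting properties."""
    truth = q.truth_strong_confounding(n=2000, seed=3)
    table, params = q.generate_cohort(truth)
    return table, params


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def newton_logistic(X, y, tol=1e-12, max_iter=200):
    """Independent logistic-regression MLE (Newton-Raphson) used as an
    oracle against the ordinal pathway at K=2.  X excludes the intercept."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X1.shape[1])
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(X1 @ beta)))
        grad = X1.T @ (y - p)
        W = p * (1 - p)
        H = X1.T @ (X1 * W[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(grad)) < tol:
            break
    return beta
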