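"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest
from scipy.special import logsumexp

import gaitclass as gc

# ---------------------------------------------------------------------------
# independent oracle: exhaustive path enumeration for tiny HMM sequences
# ---------------------------------------------------------------------------


def brute_force_log_likelihood(startprob, transmat, weights, means, covars, X):
    """Total observation log-probability by summing over all 2^T state paths.

    Deliberately naive: per-path probabilities are accumulated in log space
    with no recursion, so this shares no code path with the forward
    algorithm under test.
    """
    X = np.asarray(X, dtype=float)
    T, d = X.shape
    n_states, n_mix = weights.shape
    # per-sample per-state log emission densities
    log_b = np.empty((T, n_states))
    for t in range(T):
        for s in range(n_states):
            comp = []
            for m in range(n_mix):
                lp = -0.5 * np.sum(
                    (X[t] - means[s, m]) ** 2 / covars[s, m]
                    + np.log(2 * np.pi * covars[s, m])
                )
                comp.append(np.log(weights[s, m]) + lp)
            log_b[t, s] = logsumexp(comp)
    path_logps = []
    with np.errstate(divide="ignore"):
        log_pi = np.log(startprob)
        log_A = np.log(transmat)
    for path in product(range(n_states), repeat=T):
        lp = log_pi[path[0]] + log_b[0, path[0]]
        for t in range(1, T):
            lp += log_A[path[t - 1], path[t]] + log_b[t, path[t]]
        path_logps.append(lp)
    return float(logsumexp(path_logps))


def random_hmm(rng: np.random.Generator, n_channels: int = 7, n_mix: int = 3):
    """A random valid 2-state Gaussian-mixture HMM."""
    pi = rng.dirichlet([2.0, 2.0])
    A = np.vstack([rng.dirichlet([4.0, 4.0]) for _ in range(2)])
    w = np.vstack([rng.dirichlet([2.0] * n_mix) for _ in range(2)])
    mu = rng.normal(scale=2.0, size=(2, n_mix, n_channels))
    cv = rng.uniform(0.2, 2.0, size=(2, n_mix, n_channels))
    return gc.GaitPhaseHMM.from_params(pi, A, w, mu, cv)


# ---------------------------------------------------------------------------
# cohort fixtures (session-scoped: generation and HMM training are reused)
# ---------------------------------------------------------------------------

#: Small SVM grid used throughout the tests to keep LOSO runs quick; the grid
#: spans the region relevant for z-scored 90-dimensional features.
SMALL_SVM = gc.SVMConfig(
    C_grid=(1.0, 8.0, 128.0),
    gamma_grid=(2.0**-9, 2.0**-6, 2.0**-3),
    inner_folds=3,
)


@pytest.fixture(scope="session")
def tiny_cohort() -> gc.Dataset:
    """2 subjects per class, 2-3 short passages each."""
    config = gc.three_class_config(
        n_subjects={"EL": 2, "PS": 2, "HD": 2},
        passages_per_subject=(2, 3),
        strides_per_passage=(3, 5),
        seed=7,
    )
    return gc.generate_cohort(config)


@pytest.fixture(scope="session")
def class_models(tiny_cohort) -> dict[str, gc.GaitPhaseHMM]:
    return gc.train_class_models(tiny_cohort.trials)


@pytest.fixture(scope="session")
def loso_cohort() -> gc.Dataset:
    """4 subjects per class: the smallest comfortable LOSO cohort."""
    config = gc.three_class_config(
        n_subjects={"EL": 4, "PS": 4, "HD": 4},
        passages_per_subject=(2, 4),
        strides_per_passage=(3, 5),
        seed=11,
    )
    return gc.generate_cohort(config)


@pytest.fixture(scope="session")
def loso_result(loso_cohort) -> gc.EvaluationResult:
    return gc.run_full_evaluation(loso_cohort, svm_config=SMALL_SVM)
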