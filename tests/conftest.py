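import numpy as np
import pytest

from maxcause import synth
from maxcause.em import ETConfig


@pytest.fixture(scope="session")
def bars_gt():
    return synth.make_ground_truth_fields("bars", (5, 5), 10, seed=0, pi=0.2, sigma=0.05)


@pytest.fixture(scope="session")
def bars_data(bars_gt):
    Y, S = synth.sample_mca_dataset(bars_gt, 500, seed=1)
    return Y, S


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_model():
    """A small random MCA parameter set for posterior/oracle tests."""
    from maxcause.mca import ModelParams

    r = np.random.default_rng(3)
    W = np.abs(r.normal(size=(9, 6)))
    return ModelParams(W=W, pi=0.25, sigma=0.3)


@pytest.fixture()
def exhaustive_cfg():
    return ETConfig(H_prime=6, gamma=6, n_iterations=3, seed=0, anneal_T_start=1.0, anneal_T_end=1.0)


def brute_force_posterior(y, params, mean_fn, T=1.0):
    """Exhaustive 2^H posterior oracle, independent of the package machinery."""
    import itertools

    D, H = params.W.shape
    states = np.array(list(itertools.product([0, 1], repeat=H)), dtype=float)
    lj = np.empty(len(states))
    for i, s in enumerate(states):
        mean = mean_fn(params.W, s)
        k = s.sum()
        lp = k * np.log(params.pi) + (H - k) * np.log(1 - params.pi)
        lj[i] = lp - 0.5 * np.sum((y - mean) ** 2) / (T * params.sigma**2) - 0.5 * D * np.log(
            2 * np.pi * T * params.sigma**2
        )
    w = np.exp(lj - lj.max())
    w /= w.sum()
    return states, w


def mean_max(W, s):
    act = s.astype(bool)
    return W[:, act].max(axis=1) if act.any() else np.zeros(W.shape[0])


def mean_sum(W, s):
    act = s.astype(bool)
    return W[:, act].sum(axis=1) if act.any() else np.zeros(W.shape[0])


def best_permutation_cosine(W_true, W_learned):
    """Mean cosine similarity under the best column matching (Hungarian)."""
    from scipy.optimize import linear_sum_assignment

    A = W_true / np.linalg.norm(W_true, axis=0, keepdims=True)
    B = W_learned / np.maximum(np.linalg.norm(W_learned, axis=0, keepdims=True), 1e-300)
    C = A.T @ B
    r, c = linear_sum_assignment(-C)
    return float(C[r, c].mean())
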