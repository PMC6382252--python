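"""Binary Sparse Coding: the linear-superposition control model.

Identical to the MCA model except that active fields combine by summation,

    y ~ Normal(sum_h s_h W_h, sigma^2 I),

so the fields are unconstrained in sign.  An optional clamped variant
projects W onto the non-negative orthant after every M-step, used to check
that inhibitory STRF subfields emerge from explaining away even when the
linear model's fields are forced non-negative.
"""

from __future__ import annotations

import logging

import numpy as np

from .em import ETConfig, fit_et
from .mca import ModelParams, _check_binary

logger = logging.getLogger(__name__)

__all__ = ["linear_superposition", "log_joint_bsc", "m_step_bsc", "fit_bsc"]


def linear_superposition(W: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Sum of active columns of W; the zero vector when no unit is active."""
    s = _check_binary(s)
    W = np.asarray(W, dtype=float)
    if W.shape[1] != len(s):
        raise ValueError("state length must match the number of fields")
    return W[:, s].sum(axis=1) if s.any() else np.zeros(W.shape[0])


def log_joint_bsc(y: np.ndarray, s: np.ndarray, params: ModelParams, T: float = 1.0) -> float:
    """log p(y, s | Theta) under the linear superposition model."""
    s = _check_binary(s)
    D, H = params.W.shape
    k = int(s.sum())
    lp = k * np.log(params.pi) + (H - k) * np.log1p(-params.pi)
    var = T * params.sigma**2
    resid = float(np.sum((np.asarray(y, dtype=float) - linear_superposition(params.W, s)) ** 2))
    return lp - 0.5 * resid / var - 0.5 * D * np.log(2.0 * np.pi * var)


def m_step_bsc(
    dataset: np.ndarray,
    posteriors,
    params: ModelParams,
    clamp_nonneg: bool = False,
) -> ModelParams:
    """Reference BSC M-step from explicit truncated posteriors.

    W solves the expected least-squares normal equations
    ``W (sum_n <s s^T>) = sum_n y <s>^T`` (pseudo-inverse if singular); sigma
    is the RMS expected residual under the linear mean and pi the mean
    expected activity.  With ``clamp_nonneg`` the solved W is floored at zero.
    """
    Y = np.asarray(dataset, dtype=float)
    N, D = Y.shape
    H = params.W.shape[1]
    M1 = np.zeros((D, H))
    M2 = np.zeros((H, H))
    abs_s_sum = 0.0
    for n in range(N):
        post = posteriors[n]
        Es = post.expectation()
        M1 += np.outer(Y[n], Es)
        for s, q in zip(post.states, post.weights):
            sv = np.asarray(s, dtype=float)
            M2 += q * np.outer(sv, sv)
            abs_s_sum += q * float(sv.sum())
    try:
        W_new = np.linalg.solve(M2, M1.T).T
    except np.linalg.LinAlgError:
        logger.warning("singular second-moment matrix in BSC M-step; using pseudo-inverse")
        W_new = (np.linalg.pinv(M2) @ M1.T).T
    if clamp_nonneg:
        W_new = np.maximum(W_new, 0.0)
    # sigma from the expected residual under the fields used in the E-step,
    # mirroring the one-pass update of the batch engine
    resid_sum = 0.0
    for n in range(N):
        post = posteriors[n]
        for s, q in zip(post.states, post.weights):
            mean = linear_superposition(params.W, s)
            resid_sum += q * float(np.sum((Y[n] - mean) ** 2))
    sigma_new = max(float(np.sqrt(resid_sum / (N * D))), 1e-8)
    pi_new = float(np.clip(abs_s_sum / (H * N), 1.0 / (10.0 * N * H), 1.0 - 1e-6))
    return params.replace(W=W_new, pi=pi_new, sigma=sigma_new, nonneg=clamp_nonneg)


def fit_bsc(
    Y: np.ndarray,
    H: int,
    cfg: ETConfig,
    clamp_nonneg: bool = False,
    init_params=None,
    n_restarts: int = 1,
):
    """Fit the linear BSC model with the same ET-EM machinery as MCA."""
    return fit_et(
        Y, H, cfg, model="bsc", clamp_nonneg=clamp_nonneg, init_params=init_params, n_restarts=n_restarts
    )
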