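"""Maximal Causes Analysis: a non-negative, masking-based sparse coding model.

Generative story for a D-dimensional cochleagram vector y:

    s_h ~ Bernoulli(pi),  h = 1..H
    y   ~ Normal(max_h { s_h W_h }, sigma^2 I)

with the max applied element-wise over the active non-negative fields W_h
(the max over an empty active set is the zero vector).  The point-wise max
mirrors the log-max rule by which cochleagrams of concurrent sources combine,
and the non-negativity matches the energy representation of the front-end.

The M-step for W uses a differentiable rho-softened max,
``Wbar_d = (sum_h (s_h W_dh)^rho)^(1/rho)``, whose derivative A^rho plays the
role of a per-dimension responsibility; sigma is updated with the exact max.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .em import ETConfig, fit_et

__all__ = [
    "ModelParams",
    "logmax_superposition",
    "log_joint",
    "softmax_field_and_derivative",
    "m_step",
    "fit_mca",
]

_W_TINY = 1e-12


@dataclass
class ModelParams:
    """Model parameters Theta = (W, pi, sigma)."""

    W: np.ndarray  # D x H, non-negative for MCA
    pi: float
    sigma: float
    nonneg: bool = True

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.nonneg and np.any(self.W < 0):
            raise ValueError("MCA fields must be non-negative")
        if not (0 < self.pi < 1):
            raise ValueError("pi must lie in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def replace(self, **kw) -> "ModelParams":
        return _dc_replace(self, **kw)

    @property
    def shape(self) -> tuple[int, int]:
        return self.W.shape


def _check_binary(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s)
    if not np.all((s == 0) | (s == 1)):
        raise ValueError("latent state must be binary")
    return s.astype(bool)


def logmax_superposition(W: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Element-wise max over active fields; the zero vector when none is active."""
    s = _check_binary(s)
    W = np.asarray(W, dtype=float)
    if W.shape[1] != len(s):
        raise ValueError("state length must match the number of fields")
    if not s.any():
        return np.zeros(W.shape[0])
    return W[:, s].max(axis=1)


def log_joint(y: np.ndarray, s: np.ndarray, params: ModelParams, T: float = 1.0) -> float:
    """log p(y, s | Theta) with the noise variance annealed to T * sigma^2."""
    if params.sigma <= 0:
        raise ValueError("sigma must be positive")
    s = _check_binary(s)
    H = params.W.shape[1]
    D = params.W.shape[0]
    k = int(s.sum())
    lp = k * np.log(params.pi) + (H - k) * np.log1p(-params.pi)
    mean = logmax_superposition(params.W, s)
    var = T * params.sigma**2
    resid = float(np.sum((np.asarray(y, dtype=float) - mean) ** 2))
    return lp - 0.5 * resid / var - 0.5 * D * np.log(2.0 * np.pi * var)


def softmax_field_and_derivative(W: np.ndarray, s: np.ndarray, rho: float):
    """The rho-softened max Wbar^rho and its derivative A^rho.

    Returns ``(Wbar, A)`` where ``Wbar`` is a D-vector and ``A`` is D x H with
    ``A_dh = s_h (s_h W_dh)^(rho-1) (sum_h' (s_h' W_dh')^rho)^(1/rho - 1)``.
    Computed in max-scaled form for overflow safety; entries where s_h = 0 or
    where all active entries vanish are exactly zero.
    """
    if rho < 1:
        raise ValueError("rho must be >= 1")
    s = _check_binary(s)
    W = np.asarray(W, dtype=float)
    D, H = W.shape
    Wbar = np.zeros(D)
    A = np.zeros((D, H))
    idx = np.flatnonzero(s)
    if len(idx) == 0:
        return Wbar, A
    if len(idx) == 1:
        # Wbar_d = W_dh exactly, so the derivative is 1 for every d,
        # including cells where the field is currently zero
        Wbar[:] = W[:, idx[0]]
        A[:, idx[0]] = 1.0
        return Wbar, A
    X = W[:, idx]  # D x k
    m = X.max(axis=1)
    pos = m > _W_TINY
    Z = np.zeros_like(X)
    Z[pos] = X[pos] / m[pos, None]
    S = (Z**rho).sum(axis=1)
    Wbar[pos] = m[pos] * S[pos] ** (1.0 / rho)
    Ak = np.zeros_like(X)
    Ak[pos] = Z[pos] ** (rho - 1.0) * S[pos, None] ** (1.0 / rho - 1.0)
    Ak[X <= _W_TINY] = 0.0
    A[:, idx] = Ak
    return Wbar, A


def m_step(dataset: np.ndarray, posteriors, params: ModelParams, rho: float = 20.0) -> ModelParams:
    """Reference MCA M-step from explicit per-datapoint truncated posteriors.

    ``posteriors`` is a sequence of :class:`maxcause.em.TruncatedPosterior`,
    one per row of ``dataset``.  W is updated from the expected A^rho
    statistics, sigma from the exact-max residuals, pi from the expected
    number of active units.  Units whose accumulated denominator falls below
    floor keep their previous column.  Intended for small problems and as the
    oracle companion of the vectorized engine in :mod:`maxcause.em`.
    """
    Y = np.asarray(dataset, dtype=float)
    N, D = Y.shape
    H = params.W.shape[1]
    num = np.zeros((D, H))
    den = np.zeros((D, H))
    resid_sum = 0.0
    abs_s_sum = 0.0
    for n in range(N):
        post = posteriors[n]
        for s, q in zip(post.states, post.weights):
            if q == 0.0:
                continue
            _, A = softmax_field_and_derivative(params.W, s, rho)
            num += q * A * Y[n][:, None]
            den += q * A
            mean = logmax_superposition(params.W, s)
            resid_sum += q * float(np.sum((Y[n] - mean) ** 2))
            abs_s_sum += q * float(np.sum(s))
    with np.errstate(invalid="ignore", divide="ignore"):
        W_new = np.where(den > _W_TINY, num / np.where(den > _W_TINY, den, 1.0), params.W)
    dead = den.max(axis=0) < 1e-10 * N
    if dead.any():
        W_new[:, dead] = params.W[:, dead]
    W_new = np.maximum(W_new, 0.0)
    sigma_new = max(float(np.sqrt(resid_sum / (N * D))), 1e-8)
    pi_new = float(np.clip(abs_s_sum / (H * N), 1.0 / (10.0 * N * H), 1.0 - 1e-6))
    return params.replace(W=W_new, pi=pi_new, sigma=sigma_new)


def fit_mca(
    Y: np.ndarray,
    H: int,
    cfg: ETConfig,
    init_params: ModelParams | None = None,
    true_states: np.ndarray | None = None,
    n_restarts: int = 1,
):
    """Fit the MCA model with truncated EM and deterministic annealing.

    Returns ``(params, monitor)`` where the monitor records the per-iteration
    truncated free energy, pi, sigma, annealing temperature and dead-unit
    count.  ``n_restarts > 1`` repeats the fit from different seeded
    initializations and keeps the run with the best final free energy.
    """
    return fit_et(
        Y,
        H,
        cfg,
        model="mca",
        clamp_nonneg=True,
        init_params=init_params,
        true_states=true_states,
        n_restarts=n_restarts,
    )
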