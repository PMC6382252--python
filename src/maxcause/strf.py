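"""Model STRF estimation by ridge regression on posterior expectations.

The learned generative fields are non-negative, but the best *linear*
read-out of the latent responses from the stimulus -- the analogue of an
experimentally measured spectro-temporal receptive field -- is signed.  Each
row of the STRF matrix is the ridge-regression map from a cochleagram vector
y to the truncated posterior expectation <s_h>:

    What = (sum_n <s^(n)> y^(n)T) (lambda N I + sum_n y^(n) y^(n)T)^{-1}

Negative STRF entries emerge although fields, data and latents are all
non-negative: whenever two fields overlap in support, the posterior
anticorrelates them (explaining away), and the optimal linear read-out
acquires inhibitory subfields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .em import ETConfig, expected_responses_batch

logger = logging.getLogger(__name__)

__all__ = [
    "STRFMatrix",
    "UsageRanking",
    "expected_responses",
    "choose_lambda",
    "estimate_strfs",
    "rank_fields_by_usage",
    "negative_energy_fraction",
]


@dataclass
class STRFMatrix:
    """H x D signed linear read-out filters, one row per model unit."""

    values: np.ndarray
    lam: float
    source_model: str = "mca"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("STRF entries must be finite")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    def reshape(self, n_channels: int, n_frames: int) -> np.ndarray:
        """Rows unflattened to (H, F, T), frequency-major as in the dataset."""
        H = self.values.shape[0]
        return self.values.reshape(H, n_channels, n_frames)


@dataclass
class UsageRanking:
    """Units ordered by mean posterior activation across the stimulus set."""

    order: np.ndarray
    usage: np.ndarray  # usage[i] belongs to unit order[i]; non-increasing
    cumulative_mass: np.ndarray


def expected_responses(Y: np.ndarray, params, cfg: ETConfig, model: str = "mca") -> np.ndarray:
    """N x H matrix of truncated posterior means <s> at T = 1; entries in [0, 1]."""
    R = expected_responses_batch(Y, params, cfg, model=model)
    return np.clip(R, 0.0, 1.0)


def choose_lambda(eigenvalues: np.ndarray) -> float:
    """Mid-range of the Gram-matrix spectrum: (min + max) / 2.

    Eigenvalues of ``sum_n y y^T`` are expected to be (numerically)
    non-negative; small negative round-off down to -1e-10 is clipped to zero.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    if eig.size == 0:
        raise ValueError("empty eigenvalue spectrum")
    if np.any(eig < -1e-10):
        raise ValueError("Gram-matrix eigenvalues must be non-negative")
    eig = np.clip(eig, 0.0, None)
    return float((eig.min() + eig.max()) / 2.0)


def estimate_strfs(
    responses: np.ndarray,
    dataset: np.ndarray,
    lam: float | None = None,
    source_model: str = "mca",
) -> STRFMatrix:
    """Closed-form ridge solution mapping stimuli to posterior expectations.

    With ``lam=None`` the regularizer is the mid-range of the eigenvalues of
    the sample covariance (1/N) sum_n y y^T, so that the ridge term lam*N*I
    sits in the mid-range of the Gram spectrum rather than dominating it by a
    factor N.  ``lam=0`` requires a non-singular Gram matrix.  The returned
    solution is verified against the ridge normal equations and against the
    zero matrix on the regression objective.
    """
    R = np.asarray(responses, dtype=float)
    Y = np.asarray(dataset, dtype=float)
    N, D = Y.shape
    G = Y.T @ Y
    if lam is None:
        lam = choose_lambda(np.linalg.eigvalsh(G) / N)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    A = lam * N * np.eye(D) + G
    B = Y.T @ R  # D x H
    if lam == 0.0:
        cond = np.linalg.cond(G)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "data Gram matrix is singular; a positive lambda is required"
            )
    What = np.linalg.solve(A, B).T  # H x D (A symmetric)
    # self-consistency: ridge normal equations
    lhs = What @ A
    rhs = B.T
    err = np.linalg.norm(lhs - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if err > 1e-8:
        raise FloatingPointError(f"ridge normal equations violated (rel err {err:.2e})")
    # the estimate must not be worse than the zero matrix on the objective
    f_hat = np.sum((Y @ What.T - R) ** 2) / N + lam * np.sum(What**2)
    f_zero = np.sum(R**2) / N
    if f_hat > f_zero * (1.0 + 1e-10) + 1e-12:
        raise FloatingPointError("ridge solution does not improve on the zero matrix")
    return STRFMatrix(values=What, lam=float(lam), source_model=source_model)


def rank_fields_by_usage(responses: np.ndarray) -> UsageRanking:
    """Order units by mean posterior activation (ties break to lower index)."""
    R = np.asarray(responses, dtype=float)
    usage = R.mean(axis=0)
    order = np.argsort(-usage, kind="stable")
    sorted_usage = usage[order]
    total = sorted_usage.sum()
    cum = np.cumsum(sorted_usage) / total if total > 0 else np.zeros_like(sorted_usage)
    return UsageRanking(order=order, usage=sorted_usage, cumulative_mass=cum)


def negative_energy_fraction(field: np.ndarray) -> float:
    """Share of a filter's squared energy carried by its negative entries."""
    x = np.asarray(field, dtype=float)
    total = float(np.sum(x**2))
    if total == 0.0:
        return 0.0
    return float(np.sum(np.minimum(x, 0.0) ** 2) / total)
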