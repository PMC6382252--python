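"""Expectation Truncation machinery shared by the MCA and BSC models.

Both generative models have binary latents s in {0,1}^H with an i.i.d.
Bernoulli(pi) prior and an isotropic Gaussian observation density around a
superposition of active fields (element-wise max for MCA, sum for BSC).  The
exact posterior over 2^H states is intractable for large H; Expectation
Truncation (ET) restricts it to a per-datapoint set K_n of candidate states:

* the H' units whose fields are most similar (cosine) to the datapoint are
  selected as candidates;
* all binary states supported on the candidates with at most gamma active
  units are enumerated, plus the all-zero state, plus every singleton state
  over all H units (so no unit can starve);
* posterior weights over K_n are normalized with log-sum-exp.

Deterministic annealing multiplies the noise variance by a temperature T that
decreases linearly from T_start to T_end over the first fraction of EM
iterations, flattening early posteriors to avoid local optima.

The module exposes both reference, per-datapoint operations (used as oracles
and for small problems) and a vectorized batch engine ``fit_et`` used by
:func:`maxcause.mca.fit_mca` and :func:`maxcause.bsc.fit_bsc`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "ETConfig",
    "TruncatedPosterior",
    "anneal_temperature",
    "select_candidates",
    "enumerate_states",
    "posterior_weights",
    "initialize",
    "fit_et",
]

_W_TINY = 1e-12  # field entries below this are treated as exact zeros in A^rho
_DEAD_FLOOR = 1e-10  # per-datapoint floor for the M-step denominator of a unit


@dataclass
class ETConfig:
    """Truncation, annealing and iteration settings for ET-EM."""

    H_prime: int = 10
    gamma: int = 6
    n_iterations: int = 70
    rho: float = 20.0
    anneal_T_start: float = 10.0
    anneal_T_end: float = 1.0
    anneal_fraction: float = 0.5
    anneal_param_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.gamma <= self.H_prime):
            raise ValueError("need 1 <= gamma <= H_prime")
        if self.rho < 1:
            raise ValueError("rho must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.anneal_T_end < 1 or self.anneal_T_start < self.anneal_T_end:
            raise ValueError("need anneal_T_start >= anneal_T_end >= 1")
        if not (0 <= self.anneal_fraction <= 1):
            raise ValueError("anneal_fraction must lie in [0, 1]")


@dataclass
class TruncatedPosterior:
    """Candidate set, enumerated states and normalized weights for one datapoint."""

    candidates: np.ndarray  # sorted unit indices, size <= H'
    states: np.ndarray  # (n_states, H) binary
    weights: np.ndarray  # (n_states,), sums to 1

    def __post_init__(self) -> None:
        s = float(np.sum(self.weights))
        if not np.isclose(s, 1.0, atol=1e-12):
            raise ValueError(f"posterior weights must sum to 1 (got {s})")

    def expectation(self) -> np.ndarray:
        """Posterior mean <s> of the binary latent vector."""
        return self.weights @ self.states


def anneal_temperature(iteration: int, cfg: ETConfig) -> float:
    """Linear annealing temperature for the given EM iteration (0-based).

    T decreases linearly from T_start at iteration 0 to T_end at the last
    iteration of the annealing phase (``floor(fraction * n_iterations) - 1``)
    and stays at T_end afterwards.
    """
    if not (0 <= iteration < cfg.n_iterations):
        raise ValueError("iteration out of range")
    n_anneal = int(np.floor(cfg.anneal_fraction * cfg.n_iterations))
    if iteration >= n_anneal or n_anneal <= 1:
        return float(cfg.anneal_T_end)
    frac = iteration / (n_anneal - 1)
    return float(cfg.anneal_T_start + frac * (cfg.anneal_T_end - cfg.anneal_T_start))


def _candidate_scores(Y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Cosine similarity between each datapoint (rows of Y) and each field."""
    wn = np.linalg.norm(W, axis=0)
    yn = np.linalg.norm(Y, axis=1)
    denom = np.outer(yn, wn)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = (Y @ W) / denom
    S[~np.isfinite(S)] = 0.0
    return S


def select_candidates(y: np.ndarray, W: np.ndarray, H_prime: int) -> np.ndarray:
    """Indices of the H' units most similar to y (cosine score, ties to lower index)."""
    H = W.shape[1]
    if H_prime > H:
        raise ValueError("H_prime cannot exceed H")
    if np.linalg.norm(y) == 0:
        logger.warning("zero-norm datapoint: candidate scores all zero")
    scores = _candidate_scores(y[None, :], W)[0]
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:H_prime])


def _select_candidates_batch(Y: np.ndarray, W: np.ndarray, H_prime: int) -> np.ndarray:
    S = _candidate_scores(Y, W)
    order = np.argsort(-S, axis=1, kind="stable")[:, :H_prime]
    return np.sort(order, axis=1)


def _patterns(H_prime: int, gamma: int):
    """All activation patterns over H' candidate slots with <= gamma active.

    Returns a boolean (n_pat, H') matrix ordered by pattern size then
    lexicographically, starting with the empty pattern, and the vector of
    pattern sizes.
    """
    pats = []
    for k in range(gamma + 1):
        for idx in combinations(range(H_prime), k):
            row = np.zeros(H_prime, dtype=bool)
            row[list(idx)] = True
            pats.append(row)
    P = np.array(pats)
    return P, P.sum(axis=1).astype(float)


def enumerate_states(candidates: np.ndarray, gamma: int, H: int) -> np.ndarray:
    """All states of K_n as binary H-vectors.

    The set comprises every binary vector supported on ``candidates`` with at
    most ``gamma`` active units (including the all-zero state) plus the
    mandatory singleton state of every unit 1..H (duplicates removed).
    """
    candidates = np.asarray(candidates, dtype=int)
    if gamma > len(candidates):
        raise ValueError("gamma cannot exceed the number of candidates")
    P, _ = _patterns(len(candidates), gamma)
    states = np.zeros((len(P), H), dtype=int)
    states[:, candidates] = P.astype(int)
    cand_set = set(candidates.tolist())
    extra = [h for h in range(H) if h not in cand_set]
    singles = np.zeros((len(extra), H), dtype=int)
    for i, h in enumerate(extra):
        singles[i, h] = 1
    return np.vstack([states, singles])


def posterior_weights(
    y: np.ndarray,
    states: np.ndarray,
    params,
    T: float = 1.0,
    log_joint_fn=None,
) -> TruncatedPosterior:
    """Normalized truncated posterior over an explicit state list.

    ``log_joint_fn(y, s, params, T)`` evaluates the log joint with the noise
    variance annealed to T*sigma^2; the MCA log joint is the default.
    Weights are normalized with log-sum-exp; if every state underflows to
    -inf, a uniform distribution is returned with a warning.
    """
    if T < 1:
        raise ValueError("annealing temperature must be >= 1")
    if log_joint_fn is None:
        from .mca import log_joint as log_joint_fn  # default model
    lj = np.array([log_joint_fn(y, s, params, T=T) for s in states])
    if np.all(np.isneginf(lj)):
        logger.warning("all posterior weights underflowed; using uniform weights")
        w = np.full(len(states), 1.0 / len(states))
    else:
        w = np.exp(lj - logsumexp(lj))
        w /= w.sum()
    active = np.asarray(states).sum(axis=1) > 0
    cand = np.unique(np.nonzero(np.asarray(states)[active])[1]) if active.any() else np.array([], int)
    return TruncatedPosterior(candidates=cand, states=np.asarray(states), weights=w)


def initialize(Y: np.ndarray, H: int, cfg: ETConfig, clamp_nonneg: bool = True):
    """Data-driven initialization of (W, pi, sigma).

    Each field is the data mean perturbed by Gaussian noise with variance a
    quarter of the data variance; sigma starts at the data standard deviation
    and pi at 30/H (clipped to at most 0.5 for small dictionaries).  With
    ``clamp_nonneg`` the perturbed fields are floored at zero (MCA and the
    clamped BSC variant).
    """
    from .mca import ModelParams

    if H <= 0:
        raise ValueError("H must be positive")
    Y = np.asarray(Y, dtype=float)
    if Y.size == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    mean = Y.mean(axis=0)
    var = float(Y.var())
    W = mean[:, None] + rng.normal(0.0, np.sqrt(var / 4.0) if var > 0 else 0.0, size=(Y.shape[1], H))
    if clamp_nonneg:
        W = np.maximum(W, 0.0)
    sigma = max(np.sqrt(var), 1e-6)
    pi = min(30.0 / H, 0.5)
    return ModelParams(W=W, pi=pi, sigma=sigma, nonneg=clamp_nonneg)


import math

from numba import njit


@njit(cache=True, inline="always")
def _powi(z: float, k: int) -> float:
    """z**k for integer k >= 0 by binary exponentiation."""
    r = 1.0
    b = z
    while k:
        if k & 1:
            r *= b
        k >>= 1
        b *= b
    return r


@njit(cache=True)
def _et_pass(
    Y,
    W,
    cand,
    slots,
    offs,
    sizes,
    YW,
    colsq,
    ysq,
    prior_k,
    prior_1,
    inv2Tvar,
    inv2var,
    rho,
    rho_is_int,
    is_mca,
    need_mstep,
    need_m2,
    Es,
    num,
    den,
    M2,
    acc,
    L1,
    Sig,
):
    """Single pass over the dataset: truncated E-step plus M-step accumulators.

    Fills Es (N x H posterior means), num/den (H x D A-weighted statistics for
    the MCA W update), M2 (H x H expected second moment for BSC),
    L1 (per-datapoint logsumexp of the log joint over K_n at T=1),
    Sig (per-datapoint expected squared residual) and
    acc = [sum q|s|, unused, unused, underflow count].
    """
    N, D = Y.shape
    H = W.shape[1]
    Hp = cand.shape[1]
    n_pat = offs.shape[0] - 1
    n_states = n_pat + H
    Mbuf = np.empty((n_pat, D))
    r2 = np.empty(n_states)
    lw = np.empty(n_states)
    lw1 = np.empty(n_states)
    irho = int(rho)
    # A = z^(rho-1) * S^(1/rho-1) <= z^(rho-1) since S >= 1; entries with
    # z below this bound fall under the 1e-12 floor and are treated as 0
    zmin = 1e-12 ** (1.0 / (rho - 1.0)) if rho > 1.0 else 0.0
    zp = np.empty(Hp)
    for n in range(N):
        for p in range(n_pat):
            a = offs[p]
            b = offs[p + 1]
            if b == a:
                r2[p] = ysq[n]
                for d in range(D):
                    Mbuf[p, d] = 0.0
            else:
                racc = 0.0
                for d in range(D):
                    if is_mca:
                        m = -1.7e308
                        for t in range(a, b):
                            v = W[d, cand[n, slots[t]]]
                            if v > m:
                                m = v
                    else:
                        m = 0.0
                        for t in range(a, b):
                            m += W[d, cand[n, slots[t]]]
                    Mbuf[p, d] = m
                    diff = Y[n, d] - m
                    racc += diff * diff
                r2[p] = racc
        for h in range(H):
            r2[n_pat + h] = ysq[n] - 2.0 * YW[n, h] + colsq[h]
        for p in range(n_pat):
            r = r2[p]
            pk = prior_k[sizes[p]]
            lw[p] = -r * inv2Tvar + pk
            lw1[p] = -r * inv2var + pk
        for h in range(H):
            r = r2[n_pat + h]
            lw[n_pat + h] = -r * inv2Tvar + prior_1
            lw1[n_pat + h] = -r * inv2var + prior_1
        for j in range(Hp):
            lw[n_pat + cand[n, j]] = -math.inf
            lw1[n_pat + cand[n, j]] = -math.inf
        mmax = -math.inf
        m1 = -math.inf
        for i in range(n_states):
            if lw[i] > mmax:
                mmax = lw[i]
            if lw1[i] > m1:
                m1 = lw1[i]
        if mmax == -math.inf:
            acc[3] += 1.0
            for i in range(n_states):
                lw[i] = 0.0
            for j in range(Hp):
                lw[n_pat + cand[n, j]] = -math.inf
            mmax = 0.0
        ssum = 0.0
        for i in range(n_states):
            lw[i] = math.exp(lw[i] - mmax)
            ssum += lw[i]
        if m1 > -math.inf:
            s1 = 0.0
            for i in range(n_states):
                if lw1[i] > -math.inf:
                    s1 += math.exp(lw1[i] - m1)
            L1[n] = m1 + math.log(s1)
        else:
            L1[n] = -math.inf
        inv = 1.0 / ssum
        pi_n = 0.0
        sig_n = 0.0
        for p in range(n_pat):
            qv = lw[p] * inv
            lw[p] = qv
            pi_n += qv * sizes[p]
            sig_n += qv * r2[p]
            for t in range(offs[p], offs[p + 1]):
                Es[n, cand[n, slots[t]]] += qv
        for h in range(H):
            qv = lw[n_pat + h] * inv
            lw[n_pat + h] = qv
            pi_n += qv
            sig_n += qv * r2[n_pat + h]
            Es[n, h] += qv
        acc[0] += pi_n
        Sig[n] = sig_n
        if need_mstep and is_mca:
            for p in range(1, n_pat):
                qv = lw[p]
                if qv <= 1e-12:
                    continue
                a = offs[p]
                b = offs[p + 1]
                if b - a == 1:
                    # singleton state: Wbar_d = W_dh, so A = 1 everywhere --
                    # this lets a field regain support on cells clamped to 0
                    h = cand[n, slots[a]]
                    for d in range(D):
                        den[h, d] += qv
                        num[h, d] += qv * Y[n, d]
                else:
                    for d in range(D):
                        m = Mbuf[p, d]
                        if m <= 1e-12:
                            continue
                        invm = 1.0 / m
                        S = 0.0
                        for t in range(a, b):
                            z = W[d, cand[n, slots[t]]] * invm
                            if z > zmin:
                                if rho_is_int:
                                    zr1 = _powi(z, irho - 1)
                                else:
                                    zr1 = z ** (rho - 1.0)
                                zp[t - a] = zr1
                                S += zr1 * z
                            else:
                                zp[t - a] = 0.0
                        c = S ** (1.0 / rho - 1.0)
                        for t in range(a, b):
                            zr1 = zp[t - a]
                            if zr1 > 0.0:
                                h = cand[n, slots[t]]
                                if W[d, h] > 1e-12:
                                    A = zr1 * c
                                    den[h, d] += qv * A
                                    num[h, d] += qv * A * Y[n, d]
            for h in range(H):
                qv = lw[n_pat + h]
                if qv <= 1e-12:
                    continue
                for d in range(D):
                    den[h, d] += qv
                    num[h, d] += qv * Y[n, d]
        if need_m2:
            for p in range(1, n_pat):
                qv = lw[p]
                if qv <= 0.0:
                    continue
                a = offs[p]
                b = offs[p + 1]
                for t1 in range(a, b):
                    h1 = cand[n, slots[t1]]
                    M2[h1, h1] += qv
                    for t2 in range(t1 + 1, b):
                        h2 = cand[n, slots[t2]]
                        M2[h1, h2] += qv
                        M2[h2, h1] += qv
            for h in range(H):
                qv = lw[n_pat + h]
                if qv > 0.0:
                    M2[h, h] += qv


def _pattern_csr(Hp: int, gamma: int):
    """CSR layout of the candidate patterns: (slots, offsets, sizes)."""
    P, sizes = _patterns(Hp, gamma)
    slots = []
    offs = [0]
    for row in P:
        slots.extend(np.flatnonzero(row).tolist())
        offs.append(len(slots))
    return (
        np.asarray(slots, dtype=np.int64),
        np.asarray(offs, dtype=np.int64),
        sizes.astype(np.int64),
    )


def _run_pass(Y, params, cfg: ETConfig, T: float, model: str, need_mstep: bool):
    """Prepare inputs, run the compiled pass, return raw accumulators."""
    Y = np.ascontiguousarray(Y, dtype=float)
    N, D = Y.shape
    W = np.ascontiguousarray(params.W, dtype=float)
    H = W.shape[1]
    Hp = min(cfg.H_prime, H)
    gamma = min(cfg.gamma, Hp)
    cand = np.ascontiguousarray(_select_candidates_batch(Y, W, Hp))
    slots, offs, sizes = _pattern_csr(Hp, gamma)
    YW = Y @ W
    colsq = np.einsum("dh,dh->h", W, W)
    ysq = np.einsum("nd,nd->n", Y, Y)
    pi, sigma = params.pi, params.sigma
    ks = np.arange(gamma + 1, dtype=float)
    prior_k = ks * np.log(pi) + (H - ks) * np.log1p(-pi)
    prior_1 = float(np.log(pi) + (H - 1) * np.log1p(-pi))
    Es = np.zeros((N, H))
    is_mca = model == "mca"
    num = np.zeros((H, D)) if (need_mstep and is_mca) else np.zeros((1, 1))
    den = np.zeros((H, D)) if (need_mstep and is_mca) else np.zeros((1, 1))
    M2 = np.zeros((H, H)) if (need_mstep and not is_mca) else np.zeros((1, 1))
    acc = np.zeros(4)
    L1 = np.zeros(N)
    Sig = np.zeros(N)
    _et_pass(
        Y,
        W,
        cand,
        slots,
        offs,
        sizes,
        YW,
        colsq,
        ysq,
        prior_k,
        prior_1,
        1.0 / (2.0 * T * sigma**2),
        1.0 / (2.0 * sigma**2),
        float(cfg.rho),
        float(cfg.rho).is_integer(),
        is_mca,
        need_mstep,
        need_mstep and not is_mca,
        Es,
        num,
        den,
        M2,
        acc,
        L1,
        Sig,
    )
    if acc[3] > 0:
        logger.warning("%d datapoint(s) with fully underflowed weights; used uniform", int(acc[3]))
    return Es, num, den, M2, acc, L1, Sig


def _em_iteration(Y, params, cfg: ETConfig, T: float, model: str, clamp_nonneg: bool):
    """One full ET-EM iteration; returns (new_params, stats dict)."""
    from scipy.stats import binom

    N, D = Y.shape
    W = params.W
    H = W.shape[1]
    Es, num, den, M2, acc, L1, Sig = _run_pass(Y, params, cfg, T, model, need_mstep=True)
    F = float(np.sum(L1) - N * (D / 2.0) * np.log(2.0 * np.pi * params.sigma**2))
    pi_new = float(np.clip(acc[0] / (H * N), 1.0 / (10.0 * N * H), 1.0 - 1e-6))
    # Truncation cuts off states with more than gamma active units, so the
    # worst-explained datapoints (those likely generated outside the truncated
    # volume) would bias the noise estimate upward.  Following the standard
    # Expectation Truncation procedure, sigma is estimated from the N_cut
    # datapoints best covered by their truncated state sets, with
    # N_cut = N * P(|s| <= gamma); without truncation N_cut = N exactly.
    gamma_eff = min(cfg.gamma, min(cfg.H_prime, H))
    p_covered = float(binom.cdf(gamma_eff, H, params.pi))
    n_cut = min(N, max(1, int(np.ceil(N * p_covered))))
    if n_cut < N:
        keep = np.argpartition(-L1, n_cut - 1)[:n_cut]
        sigma_new = max(float(np.sqrt(Sig[keep].sum() / (n_cut * D))), 1e-8)
    else:
        sigma_new = max(float(np.sqrt(Sig.sum() / (N * D))), 1e-8)
    n_dead = 0
    if model == "mca":
        with np.errstate(invalid="ignore", divide="ignore"):
            WT_new = np.where(den > _W_TINY, num / np.where(den > _W_TINY, den, 1.0), W.T)
        dead = den.max(axis=1) < _DEAD_FLOOR * N
        n_dead = int(dead.sum())
        if n_dead:
            logger.info("%d dead unit(s): M-step denominator below floor; columns kept", n_dead)
            WT_new[dead] = W.T[dead]
        W_new = np.maximum(WT_new.T, 0.0)
    else:
        M1 = Y.T @ Es  # D x H
        try:
            W_new = np.linalg.solve(M2, M1.T).T
        except np.linalg.LinAlgError:
            logger.warning("singular second-moment matrix; using pseudo-inverse")
            W_new = (np.linalg.pinv(M2) @ M1.T).T
        if clamp_nonneg:
            W_new = np.maximum(W_new, 0.0)
    new_params = params.replace(W=W_new, pi=pi_new, sigma=sigma_new)
    stats = {
        "free_energy": F,
        "pi": pi_new,
        "sigma": sigma_new,
        "n_dead": n_dead,
        "temperature": T,
        "expected_s": Es,
    }
    return new_params, stats


def fit_et(
    Y: np.ndarray,
    H: int,
    cfg: ETConfig,
    model: str = "mca",
    clamp_nonneg: bool | None = None,
    init_params=None,
    true_states: np.ndarray | None = None,
    n_restarts: int = 1,
):
    """Run ET-EM for a fixed number of iterations; returns (params, monitor).

    With ``n_restarts > 1`` the fit is repeated from differently seeded
    initializations and the run with the highest final truncated free energy
    is returned -- the standard maximum-likelihood defence against EM local
    optima, decided by the training objective alone.

    The monitor dict records, per iteration: the truncated free energy of the
    incoming parameters (at T=1), pi, sigma, the annealing temperature and the
    number of dead units.  When ``true_states`` (N x H binary, available for
    synthetic data) is given, the mean per-datapoint overlap between the
    candidate set and the truly active units is recorded as
    ``candidate_truth_overlap``.  Stopping is by iteration count only.
    """
    if model not in ("mca", "bsc"):
        raise ValueError("model must be 'mca' or 'bsc'")
    Y = np.asarray(Y, dtype=float)
    if clamp_nonneg is None:
        clamp_nonneg = model == "mca"
    if n_restarts > 1:
        if init_params is not None:
            raise ValueError("n_restarts > 1 requires seeded initialization, not init_params")
        best = None
        for r in range(n_restarts):
            sub_seed = cfg.seed if r == 0 else int(
                np.random.SeedSequence([cfg.seed, r]).generate_state(1)[0] % (2**31)
            )
            sub_cfg = ETConfig(**{**cfg.__dict__, "seed": sub_seed})
            params_r, monitor_r = fit_et(
                Y, H, sub_cfg, model=model, clamp_nonneg=clamp_nonneg, true_states=true_states
            )
            F_r = monitor_r["free_energy"][-1]
            if best is None or F_r > best[0]:
                best = (F_r, params_r, monitor_r)
        logger.info("selected restart with final free energy %.2f", best[0])
        return best[1], best[2]
    params = init_params if init_params is not None else initialize(Y, H, cfg, clamp_nonneg=clamp_nonneg)
    monitor = {k: [] for k in ("free_energy", "pi", "sigma", "temperature", "n_dead")}
    if true_states is not None:
        true_states = np.asarray(true_states) > 0
        monitor["candidate_truth_overlap"] = []
    noise_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    for it in range(cfg.n_iterations):
        T = anneal_temperature(it, cfg)
        if true_states is not None:
            cand = _select_candidates_batch(Y, params.W, min(cfg.H_prime, H))
            hits = np.take_along_axis(true_states, cand, axis=1).sum(axis=1)
            monitor["candidate_truth_overlap"].append(float(hits.mean()))
        params, stats = _em_iteration(Y, params, cfg, T, model, clamp_nonneg)
        # during the annealed phase, add small seeded parameter noise to the
        # fields (amplitude shrinking linearly to zero at T = T_end) so that
        # fields merged by the flattened posterior can still separate; at
        # T = T_end the update is the plain deterministic M-step
        if cfg.anneal_param_noise > 0 and T > cfg.anneal_T_end:
            frac = (T - cfg.anneal_T_end) / max(cfg.anneal_T_start - cfg.anneal_T_end, 1e-12)
            scale = cfg.anneal_param_noise * params.sigma * frac
            W_noisy = params.W + noise_rng.normal(0.0, scale, size=params.W.shape)
            if clamp_nonneg:
                W_noisy = np.maximum(W_noisy, 0.0)
            params = params.replace(W=W_noisy)
        if not (np.all(np.isfinite(params.W)) and np.isfinite(params.pi) and np.isfinite(params.sigma)):
            raise FloatingPointError(f"non-finite parameters at EM iteration {it}")
        for k in ("free_energy", "pi", "sigma", "temperature", "n_dead"):
            monitor[k].append(stats[k])
    return params, monitor


def expected_responses_batch(Y: np.ndarray, params, cfg: ETConfig, model: str = "mca") -> np.ndarray:
    """Truncated posterior means <s> for every datapoint at T = 1 (N x H)."""
    Es = _run_pass(np.asarray(Y, dtype=float), params, cfg, T=1.0, model=model, need_mstep=False)[0]
    return Es
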