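"""Probability mixture model for binary genotype data and its EM fit.

Each tumor subclone k is a mixture component with a binary genotype vector
``C_k`` over the M loci and weight ``pi_k``.  An observed entry ``D_ij`` is
the true state of the cell's subclone corrupted by a false-positive rate
``alpha`` (0 observed as 1) and a false-negative rate ``beta`` (1 observed
as 0, chiefly allele dropout).  Missing entries are treated as
non-informative: they contribute a factor of one to the cell likelihood and
are excluded from the error-rate update sums, which keeps every M-step
closed-form.

The observed-data log-likelihood is

    l(C, pi, alpha, beta) = sum_i log sum_k pi_k prod_j p(D_ij | C_kj)

and is maximised by EM: the E-step computes responsibilities gamma_ik, the
M-step updates C (per-entry argmax), then beta, then alpha, then pi, each a
closed-form maximiser of the expected complete-data log-likelihood given the
others, so the likelihood is non-decreasing across iterations.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .gtm import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Error rates are clamped to this interval to avoid log(0).
RATE_FLOOR = 1e-6


@dataclass
class MixtureParams:
    """Parameters of the K-component binary mixture.

    ``C`` is the K x M matrix of cluster genotypes, ``pi`` the mixture
    weights, ``alpha``/``beta`` the false-positive/false-negative rates.
    """

    C: np.ndarray
    pi: np.ndarray
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.int8)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.C.ndim != 2 or self.pi.shape != (self.C.shape[0],):
            raise ValueError("C must be K x M and pi length K")
        if not np.isin(self.C, (0, 1)).all():
            raise ValueError("cluster genotypes must be binary")
        if abs(self.pi.sum() - 1.0) > 1e-10 or (self.pi < 0).any():
            raise ValueError("pi must be a probability vector")
        self.alpha = float(np.clip(self.alpha, RATE_FLOOR, 1 - RATE_FLOOR))
        self.beta = float(np.clip(self.beta, RATE_FLOOR, 1 - RATE_FLOOR))

    @property
    def K(self) -> int:
        return self.C.shape[0]


@dataclass
class FitResult:
    """A converged EM fit.

    ``gamma`` holds posterior cluster responsibilities (rows sum to one),
    ``assignments`` the argmax-posterior hard labels, and ``Z`` the predicted
    binary genotype matrix in which row i is the genotype of cell i's
    cluster.  ``ll_trace`` is the per-iteration log-likelihood of the winning
    EM run; ``reseed_iters`` lists iterations at which a near-empty cluster
    was re-seeded (monotonicity is not guaranteed across those).
    """

    params: MixtureParams
    gamma: np.ndarray
    assignments: np.ndarray
    Z: np.ndarray
    log_likelihood: float
    n_iter: int
    cell_ids: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)
    score: float | None = None
    ll_trace: np.ndarray | None = None
    reseed_iters: list[int] = field(default_factory=list)
    score_trace: list[tuple[int, float, float]] | None = None


@dataclass
class EMConfig:
    """Knobs of the EM search.

    ``beta_grid`` is the set of initial false-negative rates tried; for each
    grid point ``n_restarts`` random genotype initialisations are run and the
    best final likelihood wins.  ``fixed_alpha``/``fixed_beta`` pin the error
    rates (their updates are skipped).

    The false-positive rate is usually known for an scDNA-seq experiment, so
    by default alpha stays at ``alpha0`` and only beta is estimated; set
    ``estimate_alpha=True`` to update alpha from the data as well (as in the
    error-rate estimation analyses).
    """

    alpha0: float = 0.01
    beta_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    estimate_alpha: bool = False
    fixed_alpha: float | None = None
    fixed_beta: float | None = None
    n_restarts: int = 10
    max_iter: int = 300
    tol: float = 1e-6

    @property
    def alpha_is_free(self) -> bool:
        return self.estimate_alpha and self.fixed_alpha is None


# ---------------------------------------------------------------------------
# per-entry / per-cell likelihoods (reference forms used by tests and by the
# vectorised internals below)

def entry_log_prob(d: int, c: int, alpha: float, beta: float) -> float:
    """log p(observed d | true state c) for one matrix entry.

    p(1|0)=alpha, p(0|0)=1-alpha, p(0|1)=beta, p(1|1)=1-beta; a missing
    observation contributes 0 (a factor of one in the product).
    """
    if d == MISSING:
        return 0.0
    if c == 1:
        return math.log(1 - beta) if d == 1 else math.log(beta)
    return math.log(alpha) if d == 1 else math.log(1 - alpha)


def cell_log_likelihood(d_row, c_row, alpha: float, beta: float) -> float:
    """log p(observed cell row | cluster genotype row), missing skipped."""
    d_row = np.asarray(d_row)
    c_row = np.asarray(c_row)
    if d_row.shape != c_row.shape:
        raise ValueError("observed and genotype rows differ in length")
    return float(
        sum(entry_log_prob(int(d), int(c), alpha, beta)
            for d, c in zip(d_row, c_row))
    )


def _obs_masks(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Float indicator matrices for observed-0 and observed-1 entries."""
    return (values == 0).astype(float), (values == 1).astype(float)


def _loglik_matrix(D0, D1, C, alpha: float, beta: float) -> np.ndarray:
    """N x K matrix of log p(D_i | C_k); two matmuls, missing excluded."""
    la, l1a = math.log(alpha), math.log1p(-alpha)
    lb, l1b = math.log(beta), math.log1p(-beta)
    Cf = C.astype(float)
    A1 = D1 @ Cf.T          # observed 1 at loci where C_k = 1
    A0 = D0 @ Cf.T          # observed 0 at loci where C_k = 1
    B1 = D1.sum(axis=1)[:, None] - A1
    B0 = D0.sum(axis=1)[:, None] - A0
    return A1 * l1b + A0 * lb + B1 * la + B0 * l1a


def total_log_likelihood(gtm: GenotypeMatrix, params: MixtureParams) -> float:
    """Observed-data log-likelihood, log-sum-exp stabilised."""
    D0, D1 = _obs_masks(gtm.values)
    L = _loglik_matrix(D0, D1, params.C, params.alpha, params.beta)
    return float(logsumexp(L + np.log(params.pi), axis=1).sum())


def e_step(gtm: GenotypeMatrix, params: MixtureParams) -> np.ndarray:
    """Posterior responsibilities gamma_ik; each row sums to one."""
    D0, D1 = _obs_masks(gtm.values)
    logw = _loglik_matrix(D0, D1, params.C, params.alpha, params.beta)
    logw = logw + np.log(params.pi)
    gamma = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    return gamma


# ---------------------------------------------------------------------------
# M-step updates

def _genotype_objectives(G0, G1, alpha, beta):
    """Expected log-likelihood contribution of each (k, j) for s=0 and s=1."""
    obj1 = G1 * math.log1p(-beta) + G0 * math.log(beta)
    obj0 = G1 * math.log(alpha) + G0 * math.log1p(-alpha)
    return obj0, obj1


def update_genotypes(gtm: GenotypeMatrix, gamma, alpha: float,
                     beta: float) -> np.ndarray:
    """Per-entry argmax update of the cluster genotype matrix C.

    For each cluster k and locus j the two candidate states s in {0, 1} are
    scored by the responsibility-weighted log-likelihood of the observed
    column entries; exact ties resolve to 0 (no mutation).
    """
    gamma = np.asarray(gamma, dtype=float)
    D0, D1 = _obs_masks(gtm.values)
    G0 = gamma.T @ D0
    G1 = gamma.T @ D1
    obj0, obj1 = _genotype_objectives(G0, G1, alpha, beta)
    return (obj1 > obj0).astype(np.int8)


def update_pi(gamma) -> np.ndarray:
    """Mixture weights: mean responsibility per cluster."""
    gamma = np.asarray(gamma, dtype=float)
    return gamma.sum(axis=0) / gamma.shape[0]


def update_beta(gtm: GenotypeMatrix, gamma, C,
                prev_beta: float = 0.2) -> float:
    """False-negative rate: responsibility-weighted fraction of observed
    zeros among entries whose cluster genotype is 1."""
    gamma = np.asarray(gamma, dtype=float)
    D0, D1 = _obs_masks(gtm.values)
    Cf = np.asarray(C, dtype=float)
    num = float((Cf * (gamma.T @ D0)).sum())
    den = num + float((Cf * (gamma.T @ D1)).sum())
    if den == 0.0:
        warnings.warn("beta update skipped: no observed entries under "
                      "mutated cluster genotypes", RuntimeWarning)
        return prev_beta
    return float(np.clip(num / den, RATE_FLOOR, 1 - RATE_FLOOR))


def update_alpha(gtm: GenotypeMatrix, gamma, C,
                 prev_alpha: float = 0.01) -> float:
    """False-positive rate: responsibility-weighted fraction of observed
    ones among entries whose cluster genotype is 0."""
    gamma = np.asarray(gamma, dtype=float)
    D0, D1 = _obs_masks(gtm.values)
    Cf = 1.0 - np.asarray(C, dtype=float)
    num = float((Cf * (gamma.T @ D1)).sum())
    den = num + float((Cf * (gamma.T @ D0)).sum())
    if den == 0.0:
        warnings.warn("alpha update skipped: no observed entries under "
                      "unmutated cluster genotypes", RuntimeWarning)
        return prev_alpha
    return float(np.clip(num / den, RATE_FLOOR, 1 - RATE_FLOOR))


# ---------------------------------------------------------------------------
# initialisation and the EM driver

def _sample_c0(values: np.ndarray, K: int, rng: np.random.Generator):
    """K distinct observed cell rows, missing entries zeroed."""
    rows = rng.choice(values.shape[0], size=K, replace=False)
    C0 = values[rows].astype(np.int8).copy()
    C0[C0 == MISSING] = 0
    return C0


def init_params(gtm: GenotypeMatrix, K: int, beta0: float,
                alpha0: float = 0.01,
                rng: np.random.Generator | None = None) -> MixtureParams:
    """Initial parameters: uniform pi, given error rates, C sampled from D."""
    if not 1 <= K <= gtm.n_cells:
        raise ValueError(f"K must be in [1, {gtm.n_cells}], got {K}")
    rng = np.random.default_rng(rng)
    return MixtureParams(
        C=_sample_c0(gtm.values, K, rng),
        pi=np.full(K, 1.0 / K),
        alpha=alpha0,
        beta=beta0,
    )


#: A cluster is dead when no cell's posterior argmax points at it (starved
#: components and exact duplicates can never re-separate on their own); at
#: most this many re-seed events are attempted per run before dead clusters
#: are left as-is.
_MAX_RESEEDS = 12


def _run_em(gtm: GenotypeMatrix, D0, D1, params: MixtureParams,
            cfg: EMConfig, rng: np.random.Generator):
    """One EM run from given initial parameters.

    Returns (params, gamma, ll, trace, reseed_iters, n_iter).

    Dead mixture components (no posterior mass) can never re-separate on
    their own, so they are re-seeded with the genotype of the cell the
    current model explains worst; the likelihood may transiently drop at
    those iterations (they are recorded in the trace of re-seed events).
    """
    C = params.C.astype(np.int8)
    pi = params.pi.copy()
    alpha, beta = params.alpha, params.beta
    n, K = gtm.n_cells, params.K
    la_obs1 = D1.sum(axis=1)[:, None]  # constant row sums reused per iter
    la_obs0 = D0.sum(axis=1)[:, None]
    trace: list[float] = []
    reseeds: list[int] = []
    n_reseeds = 0
    prev_ll = -np.inf
    gamma = None
    just_reseeded = False
    for it in range(cfg.max_iter):
        # E-step (inlined _loglik_matrix to reuse row sums)
        la, l1a = math.log(alpha), math.log1p(-alpha)
        lb, l1b = math.log(beta), math.log1p(-beta)
        Cf = C.astype(float)
        A1 = D1 @ Cf.T
        A0 = D0 @ Cf.T
        L = (A1 * l1b + A0 * lb
             + (la_obs1 - A1) * la + (la_obs0 - A0) * l1a)
        logw = L + np.log(np.maximum(pi, 1e-300))
        lse = logsumexp(logw, axis=1, keepdims=True)
        ll = float(lse.sum())
        gamma = np.exp(logw - lse)
        trace.append(ll)
        if abs(ll - prev_ll) < cfg.tol and not just_reseeded:
            break
        prev_ll = ll
        just_reseeded = False
        # M-step: C, then beta, then alpha, then pi
        G0 = gamma.T @ D0
        G1 = gamma.T @ D1
        obj0, obj1 = _genotype_objectives(G0, G1, alpha, beta)
        C = (obj1 > obj0).astype(np.int8)
        Cf = C.astype(float)
        if cfg.fixed_beta is None:
            num = float((Cf * G0).sum())
            den = num + float((Cf * G1).sum())
            if den > 0:
                beta = float(np.clip(num / den, RATE_FLOOR, 1 - RATE_FLOOR))
        if cfg.alpha_is_free:
            num = float(((1 - Cf) * G1).sum())
            den = num + float(((1 - Cf) * G0).sum())
            if den > 0:
                alpha = float(np.clip(num / den, RATE_FLOOR, 1 - RATE_FLOOR))
        pi = gamma.sum(axis=0) / n
        # dead-cluster rescue: components that lost all posterior mass are
        # re-seeded at the cells the mixture currently explains worst
        if n_reseeds < _MAX_RESEEDS:
            counts = np.bincount(np.argmax(gamma, axis=1), minlength=K)
            dead = np.flatnonzero(counts == 0)
            if dead.size:
                worst = np.argsort(lse[:, 0])  # least-explained cells first
                for rank, k in enumerate(dead):
                    row = gtm.values[worst[rank]].astype(np.int8).copy()
                    row[row == MISSING] = 0
                    C[k] = row
                    pi[k] = 1.0 / K
                pi = pi / pi.sum()
                n_reseeds += dead.size
                reseeds.append(it)
                just_reseeded = True
                logger.debug("iteration %d: re-seeded clusters %s", it,
                             dead.tolist())
    final = MixtureParams(C=C, pi=pi / pi.sum(), alpha=alpha, beta=beta)
    return final, gamma, trace[-1], np.asarray(trace), reseeds, len(trace)


def _polish_genotypes(D0, D1, C, pi, alpha: float, beta: float,
                      max_flips: int = 200):
    """Greedy single-entry ascent of the observed log-likelihood over C.

    EM's genotype update maximises the expected complete-data objective
    given the previous responsibilities, so a converged C need not be
    optimal for the observed likelihood entry-by-entry; this pass flips the
    single best (k, j) entry while any flip still helps.  Each flip's exact
    likelihood change is computed in closed form from the responsibilities,
    so the observed likelihood increases monotonically.

    Returns (C, number of flips applied).
    """
    C = np.asarray(C, dtype=np.int8).copy()
    K = C.shape[0]
    la, l1a = math.log(alpha), math.log1p(-alpha)
    lb, l1b = math.log(beta), math.log1p(-beta)
    # exp(change in entry log-prob) - 1, by (observed state, flip direction)
    e10 = math.exp(l1b - la) - 1    # d=1, c 0->1
    e00 = math.exp(lb - l1a) - 1    # d=0, c 0->1
    e11 = math.exp(la - l1b) - 1    # d=1, c 1->0
    e01 = math.exp(l1a - lb) - 1    # d=0, c 1->0
    log_pi = np.log(np.maximum(pi, 1e-300))
    n_flips = 0
    for _ in range(max_flips):
        L = _loglik_matrix(D0, D1, C, alpha, beta)
        logw = L + log_pi
        lse = logsumexp(logw, axis=1, keepdims=True)
        gamma = np.exp(logw - lse)
        best_gain, best_kj = 1e-10, None
        for k in range(K):
            up = C[k] == 0
            e = np.where(up[None, :], D1 * e10 + D0 * e00,
                         D1 * e11 + D0 * e01)
            gain = np.log1p(gamma[:, k][:, None] * e).sum(axis=0)
            j = int(np.argmax(gain))
            if gain[j] > best_gain:
                best_gain, best_kj = float(gain[j]), (k, j)
        if best_kj is None:
            break
        C[best_kj] ^= 1
        n_flips += 1
    return C, n_flips


def fit_em(gtm: GenotypeMatrix, K: int, config: EMConfig | None = None,
           rng: np.random.Generator | int | None = None) -> FitResult:
    """Fit the K-component mixture by EM with restarts and a beta0 grid.

    For every initial false-negative rate in ``config.beta_grid`` and each of
    ``config.n_restarts`` random genotype initialisations an EM run is
    performed; the run with the highest final log-likelihood wins (ties keep
    the earliest run).  User-fixed alpha/beta are honoured by skipping the
    corresponding updates.
    """
    cfg = config or EMConfig()
    rng = np.random.default_rng(rng)
    if not 1 <= K <= gtm.n_cells:
        raise ValueError(f"K must be in [1, {gtm.n_cells}], got {K}")
    D0, D1 = _obs_masks(gtm.values)
    alpha0 = cfg.fixed_alpha if cfg.fixed_alpha is not None else cfg.alpha0
    grid = ((cfg.fixed_beta,) if cfg.fixed_beta is not None
            else tuple(cfg.beta_grid))
    best = None
    for beta0 in grid:
        for _ in range(cfg.n_restarts):
            init = MixtureParams(
                C=_sample_c0(gtm.values, K, rng),
                pi=np.full(K, 1.0 / K),
                alpha=alpha0,
                beta=beta0,
            )
            run = _run_em(gtm, D0, D1, init, cfg, rng)
            if best is None or run[2] > best[2]:
                best = run
    params, gamma, ll, trace, reseeds, n_iter = best
    # refine the winning run: alternate greedy genotype flips (observed-
    # likelihood ascent) with further EM sweeps until neither moves
    for _ in range(10):
        C_ref, flips = _polish_genotypes(D0, D1, params.C, params.pi,
                                         params.alpha, params.beta)
        if flips == 0:
            break
        logger.debug("polish: %d genotype flips accepted", flips)
        cont = _run_em(gtm, D0, D1,
                       MixtureParams(C=C_ref, pi=params.pi,
                                     alpha=params.alpha, beta=params.beta),
                       cfg, rng)
        params, gamma, ll = cont[0], cont[1], cont[2]
        reseeds = reseeds + [n_iter + r for r in cont[4]]
        trace = np.concatenate([trace, cont[3]])
        n_iter += cont[5]
    # final polish at the returned rates, so the reported C is entry-wise
    # optimal for the reported (pi, alpha, beta)
    C_ref, flips = _polish_genotypes(D0, D1, params.C, params.pi,
                                     params.alpha, params.beta)
    if flips:
        params = MixtureParams(C=C_ref, pi=params.pi, alpha=params.alpha,
                               beta=params.beta)
        logw = (_loglik_matrix(D0, D1, params.C, params.alpha, params.beta)
                + np.log(params.pi))
        lse = logsumexp(logw, axis=1, keepdims=True)
        gamma = np.exp(logw - lse)
        ll = float(lse.sum())
        trace = np.append(trace, ll)
        n_iter += 1
    assignments = np.argmax(gamma, axis=1)
    Z = params.C[assignments].astype(np.int8)
    return FitResult(
        params=params,
        gamma=gamma,
        assignments=assignments,
        Z=Z,
        log_likelihood=ll,
        n_iter=n_iter,
        cell_ids=list(gtm.cell_ids),
        locus_ids=list(gtm.locus_ids),
        ll_trace=trace,
        reseed_iters=reseeds,
    )
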