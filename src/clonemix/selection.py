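"""Choosing the number of subclones via an inter-cluster variance score.

For a fitted model with K clusters, every unordered cluster pair (i, k) is
scored by comparing two distances: the distance *expected* between cells of
the two clusters given the inferred genotypes and error/missing rates, and
the *observed* mean pairwise distance between the clusters' cells.  The pair
score is ``exp(-(d - d_hat)^2)``, close to one when the fitted model explains
the observed separation, and the model score s_K is the mean over pairs.
K is grown from 1 until the best score stops improving for ``kappa``
consecutive values (patience rule).

The per-locus mismatch probabilities given true cluster states (s, t) are

    p00 = 2 a(1-a)(1-eta)^2 + 2 eta(1-eta)
    p01 = p10 = [(1-a)(1-b) + a b](1-eta)^2 + 2 eta(1-eta)
    p11 = 2 b(1-b)(1-eta)^2 + 2 eta(1-eta)

where a, b are the fitted error rates and eta the missing fraction of the
input.  The ``2 eta(1-eta)`` term counts exactly-one-missing as a mismatch;
accordingly the observed distance treats two missing entries as equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .em import EMConfig, FitResult, fit_em
from .gtm import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_IMPROVE_TOL = 1e-12


@dataclass
class PairScoreTable:
    """Pairwise score bookkeeping for one fitted K.

    All matrices are symmetric K x K with unused diagonals; ``s_K`` is the
    mean of ``s`` over unordered pairs.
    """

    d_expected: np.ndarray
    d_observed: np.ndarray
    s: np.ndarray
    s_K: float


def mismatch_probs(alpha_star: float, beta_star: float,
                   eta: float) -> tuple[float, float, float, float]:
    """Per-locus mismatch probabilities (p00, p01, p10, p11)."""
    a, b, h = alpha_star, beta_star, eta
    obs2 = (1 - h) ** 2
    one_missing = 2 * h * (1 - h)
    p00 = 2 * a * (1 - a) * obs2 + one_missing
    p01 = ((1 - a) * (1 - b) + a * b) * obs2 + one_missing
    p11 = 2 * b * (1 - b) * obs2 + one_missing
    return p00, p01, p01, p11


def expected_distance(c_i, c_k, probs) -> float:
    """Expected count of mismatching loci between cells of two clusters."""
    c_i = np.asarray(c_i)
    c_k = np.asarray(c_k)
    if c_i.shape != c_k.shape:
        raise ValueError("genotype vectors differ in length")
    p00, p01, p10, p11 = probs
    n00 = np.sum((c_i == 0) & (c_k == 0))
    n01 = np.sum((c_i == 0) & (c_k == 1))
    n10 = np.sum((c_i == 1) & (c_k == 0))
    n11 = np.sum((c_i == 1) & (c_k == 1))
    return float(p00 * n00 + p01 * n01 + p10 * n10 + p11 * n11)


def observed_mean_distance(gtm: GenotypeMatrix, cells_i, cells_k) -> float:
    """Mean ternary mismatch count over all cross pairs of two cell sets.

    States compare as 0 != 1, missing != 0, missing != 1, and
    missing == missing (the expected-distance formulas count only
    exactly-one-missing events).
    """
    idx_i = np.asarray(list(cells_i), dtype=int)
    idx_k = np.asarray(list(cells_k), dtype=int)
    if idx_i.size == 0 or idx_k.size == 0:
        raise ValueError("cell sets must be non-empty")
    if np.intersect1d(idx_i, idx_k).size:
        raise ValueError("cell sets must be disjoint")
    mism = _pairwise_mismatch(gtm.values[idx_i], gtm.values[idx_k])
    return float(mism.mean())


def _pairwise_mismatch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|A| x |B| counts of loci at which the ternary states differ."""
    m = A.shape[1]
    matches = np.zeros((A.shape[0], B.shape[0]))
    for state in (0, 1, MISSING):
        matches += (A == state).astype(float) @ (B == state).astype(float).T
    return m - matches


def pair_score(d: float, d_hat: float) -> float:
    """exp(-(d - d_hat)^2); 1 when expectation matches observation."""
    return float(np.exp(-((d - d_hat) ** 2)))


def pair_score_table(gtm: GenotypeMatrix, fit: FitResult) -> PairScoreTable:
    """Full pairwise score table for a fit; empty clusters are dropped."""
    labels = fit.assignments
    occupied = [k for k in range(fit.params.K)
                if np.any(labels == k)]
    if len(occupied) < fit.params.K:
        logger.debug("dropping %d empty cluster(s) before scoring",
                     fit.params.K - len(occupied))
    k_eff = len(occupied)
    probs = mismatch_probs(fit.params.alpha, fit.params.beta, gtm.eta)
    d_exp = np.zeros((k_eff, k_eff))
    d_obs = np.zeros((k_eff, k_eff))
    s = np.zeros((k_eff, k_eff))
    members = [np.flatnonzero(labels == k) for k in occupied]
    for a in range(k_eff):
        for b in range(a + 1, k_eff):
            d = expected_distance(fit.params.C[occupied[a]],
                                  fit.params.C[occupied[b]], probs)
            mism = _pairwise_mismatch(gtm.values[members[a]],
                                      gtm.values[members[b]])
            d_hat = float(mism.mean())
            d_exp[a, b] = d_exp[b, a] = d
            d_obs[a, b] = d_obs[b, a] = d_hat
            s[a, b] = s[b, a] = pair_score(d, d_hat)
    if k_eff <= 1:
        s_k = 0.0
    else:
        iu = np.triu_indices(k_eff, 1)
        s_k = float(s[iu].mean())
    return PairScoreTable(d_expected=d_exp, d_observed=d_obs, s=s, s_K=s_k)


def model_score(gtm: GenotypeMatrix, fit: FitResult) -> float:
    """Model score s_K: mean pair score; 0 for a single (effective) cluster.

    A single-cluster model offers no between-cluster evidence, so s_1 is
    fixed at 0 and any genuinely separable structure scores above it.
    """
    return pair_score_table(gtm, fit).s_K


def select_k(gtm: GenotypeMatrix, config: EMConfig | None = None,
             kappa: int = 10, k_max: int | None = None,
             seed: int = 0) -> FitResult:
    """Grow K from 1 and return the fit with the best model score.

    Fits K = 1, 2, ... with the full restart/grid protocol of
    :func:`clonemix.em.fit_em`, each K seeded deterministically from
    ``(seed, K)``.  The loop stops once the best score has not strictly
    improved for ``kappa`` consecutive K values, or K reaches ``k_max``
    (default ``min(N, 50)``).  Ties favour the smallest K.  The returned fit
    carries ``score`` and a ``score_trace`` of (K, s_K, log-likelihood).
    """
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    if k_max is None:
        k_max = min(gtm.n_cells, 50)
    k_max = min(k_max, gtm.n_cells)
    best_fit: FitResult | None = None
    best_s = -np.inf
    stall = 0
    trace: list[tuple[int, float, float]] = []
    for K in range(1, k_max + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(K,)))
        fit = fit_em(gtm, K, config, rng)
        s_k = model_score(gtm, fit)
        fit.score = s_k
        trace.append((K, s_k, fit.log_likelihood))
        logger.info("K=%d  s_K=%.6f  loglik=%.2f", K, s_k,
                    fit.log_likelihood)
        if s_k > best_s + _IMPROVE_TOL:
            best_s, best_fit, stall = s_k, fit, 0
        else:
            stall += 1
            if stall >= kappa:
                break
    assert best_fit is not None
    best_fit.score_trace = trace
    return best_fit
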