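"""Evaluation metrics: clustering V-measure and genotype recovery rates.

Doublet cells (two cells captured as one) have no single true label or
genotype, so every metric here excludes them when their indices are known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class EvalReport:
    """Bundle of evaluation metrics for one fitted dataset."""

    v_measure: float
    accuracy: float
    sensitivity: float
    specificity: float
    n_cells_evaluated: int


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def v_measure(true_labels, pred_labels) -> float:
    """V-measure: harmonic mean of homogeneity and completeness.

    Homogeneity h = 1 - H(true|pred)/H(true) measures whether each predicted
    cluster contains a single true class; completeness c = 1 - H(pred|true)/
    H(pred) whether each class lands in a single cluster.  Both default to 1
    when the corresponding marginal entropy is zero; the score is invariant
    to relabelling.
    """
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if t.size == 0:
        raise ValueError("label vectors must be non-empty")
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    n_t, n_p = ti.max() + 1, pi.max() + 1
    cont = np.zeros((n_t, n_p))
    np.add.at(cont, (ti, pi), 1.0)
    h_t = _entropy(cont.sum(axis=1))
    h_p = _entropy(cont.sum(axis=0))
    n = t.size
    # conditional entropies from the contingency table
    h_t_given_p = 0.0
    h_p_given_t = 0.0
    nz = np.argwhere(cont > 0)
    col_sums = cont.sum(axis=0)
    row_sums = cont.sum(axis=1)
    for a, b in nz:
        c = cont[a, b]
        h_t_given_p -= (c / n) * math.log(c / col_sums[b])
        h_p_given_t -= (c / n) * math.log(c / row_sums[a])
    hom = 1.0 if h_t == 0 else 1.0 - h_t_given_p / h_t
    com = 1.0 if h_p == 0 else 1.0 - h_p_given_t / h_p
    if hom + com == 0:
        return 0.0
    return float(2 * hom * com / (hom + com))


def genotype_metrics(Z, Z_star, doublet_indices=()) -> tuple[float, float,
                                                             float]:
    """(accuracy, sensitivity, specificity) of a predicted genotype matrix.

    Accuracy is the fraction of entries of Z matching Z_star; sensitivity
    the fraction of true 1-entries called 1; specificity the fraction of
    true 0-entries called 0.  Doublet rows are dropped from both matrices
    first.  A metric with an empty reference class is returned as NaN.
    """
    Z = np.asarray(Z)
    Zs = np.asarray(Z_star)
    if Z.shape != Zs.shape:
        raise ValueError("predicted and true matrices differ in shape")
    if len(doublet_indices):
        keep = np.setdiff1d(np.arange(Z.shape[0]),
                            np.asarray(list(doublet_indices), dtype=int))
        Z, Zs = Z[keep], Zs[keep]
    total = Zs.size
    correct = int((Z == Zs).sum())
    ones = Zs == 1
    zeros = Zs == 0
    accuracy = correct / total
    sensitivity = (float((Z[ones] == 1).mean()) if ones.any()
                   else float("nan"))
    specificity = (float((Z[zeros] == 0).mean()) if zeros.any()
                   else float("nan"))
    return float(accuracy), sensitivity, specificity


def evaluate(true_labels, pred_labels, Z, Z_star,
             doublet_indices=()) -> EvalReport:
    """Full report with doublets excluded from every metric."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if len(doublet_indices):
        keep = np.setdiff1d(np.arange(t.size),
                            np.asarray(list(doublet_indices), dtype=int))
        t, p = t[keep], p[keep]
    acc, sens, spec = genotype_metrics(Z, Z_star, doublet_indices)
    return EvalReport(
        v_measure=v_measure(t, p),
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        n_cells_evaluated=int(t.size),
    )
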