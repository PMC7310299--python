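"""Connectivity-matrix sparsification and recovery metrics.

Implements the thresholding rules compared in the validation study —
absolute (fixed cutoff, default 1e-6 as a numerically safe stand-in for
zero), proportional (top fraction per subject), and the model-based
pseudo-false-discovery-rate rule — plus the confusion-matrix metrics used
to score each sparsified network against a known binary ground truth.

Method-name strings used in reports: ``abs_corr``, ``abs_pp``,
``mixture_pfdr``, ``prop5_corr``, ``prop5_pp``, ``prop10_corr``,
``prop10_pp``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import matrix_to_pairs

__all__ = [
    "SparsifiedNetwork",
    "ClassificationMetrics",
    "binarize_truth",
    "absolute_threshold",
    "proportional_threshold",
    "pseudo_fdr_threshold",
    "evaluate_classification",
]


@dataclasses.dataclass
class SparsifiedNetwork:
    """Binary (n x m) adjacency vectors plus how they were obtained."""

    edges: np.ndarray
    method: str
    threshold: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges)
        if not np.isin(self.edges, (0, 1)).all():
            raise ValueError("edges must be binary")
        self.edges = self.edges.astype(np.int8)

    @property
    def edge_counts(self) -> np.ndarray:
        return self.edges.sum(axis=1)


@dataclasses.dataclass
class ClassificationMetrics:
    """Per-subject and averaged recovery metrics against ground truth.

    ``mean_performance`` is the per-subject classification accuracy
    (TP + TN) / m averaged over subjects.  PPV is undefined when a subject
    has no predicted positives; such subjects are excluded from the PPV
    average and counted in ``n_undefined_ppv``.
    """

    per_subject: pd.DataFrame
    tpr: float
    fpr: float
    ppv: float
    mean_performance: float
    n_undefined_ppv: int


def binarize_truth(a_matrix: np.ndarray) -> np.ndarray:
    """Binary truth vector from a square (possibly directed) weight matrix.

    Off-diagonal non-zero entries mark connected pairs; the diagonal
    (self-association) is discarded.  A directed matrix is symmetrized by
    OR: a pair is connected if either direction carries a non-zero weight,
    since the mixture model is defined on unordered pairs.
    """
    a = np.asarray(a_matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("truth matrix must be square")
    sym = (a != 0) | (a.T != 0)
    vec, _ = matrix_to_pairs(sym.astype(float))
    return (vec != 0).astype(np.int8)


def absolute_threshold(
    values: np.ndarray, cutoff: float = 1e-6, method: str = "abs"
) -> SparsifiedNetwork:
    """Declare connected every value strictly above ``cutoff``.

    The 1e-6 default approximates thresholding at zero while being immune
    to floating-point noise.  Works identically for Fisher-z values and
    posterior probabilities; edge counts generally differ across subjects.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return SparsifiedNetwork((values > cutoff).astype(np.int8), method, cutoff)


def proportional_threshold(
    values: np.ndarray, fraction: float, method: str = "prop"
) -> SparsifiedNetwork:
    """Keep the top ``floor(fraction * m)`` values of each subject.

    Ties at the boundary are broken by pair-index order (stable sort), so
    the result is deterministic.  Every subject gets the same edge count —
    the defining property (and the defining assumption) of proportional
    thresholding.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, m = values.shape
    k = int(np.floor(fraction * m))
    edges = np.zeros((n, m), dtype=np.int8)
    if k < 1:
        warnings.warn("fraction * m < 1: empty network", stacklevel=2)
        return SparsifiedNetwork(edges, method, fraction)
    # stable sort on (-value, pair index): ties resolved by earlier pair
    order = np.argsort(-values, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), k)
    edges[rows, order[:, :k].ravel()] = 1
    return SparsifiedNetwork(edges, method, fraction)


def pseudo_fdr_threshold(
    z: np.ndarray,
    pi_hat: np.ndarray,
    mu0: np.ndarray,
    sigma0_sq: np.ndarray,
    mu1: np.ndarray,
    sigma1_sq: np.ndarray,
    q: float = 0.05,
    method: str = "mixture_pfdr",
) -> SparsifiedNetwork:
    """Per-subject cutoff controlling the model-implied false discovery rate.

    With F0, F1 the fitted non-connected (normal) and connected (lognormal)
    distribution functions of subject i, the pseudo-FDR of a cutoff t is
    the model-implied fraction of non-connected pairs among declarations::

        pFDR_i(t) = (1 - pi_i)(1 - F0(t))
                    / [ (1 - pi_i)(1 - F0(t)) + pi_i (1 - F1(t)) ]

    The cutoff t_i* is the smallest t on the grid of the subject's own
    sorted positive z values (plus 0) with pFDR_i(t) <= q; pairs with
    z > t_i* are connected.  A subject with pi_hat = 0 gets no connections
    (maximally conservative).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n, m = z.shape
    edges = np.zeros((n, m), dtype=np.int8)
    cutoffs = np.full(n, np.inf)
    for i in range(n):
        if pi_hat[i] <= 0:
            continue
        grid = np.concatenate([[0.0], np.sort(z[i][z[i] > 0])])
        tail0 = stats.norm.sf(grid, mu0[i], np.sqrt(sigma0_sq[i]))
        tail1 = stats.lognorm.sf(grid, np.sqrt(sigma1_sq[i]), scale=np.exp(mu1[i]))
        num = (1 - pi_hat[i]) * tail0
        denom = num + pi_hat[i] * tail1
        with np.errstate(invalid="ignore", divide="ignore"):
            pfdr = np.where(denom > 0, num / denom, 0.0)
        ok = np.nonzero(pfdr <= q)[0]
        if ok.size:
            cutoffs[i] = grid[ok[0]]
            edges[i] = z[i] > cutoffs[i]
    return SparsifiedNetwork(edges, method, cutoffs)


def evaluate_classification(
    estimate: SparsifiedNetwork | np.ndarray, truth: np.ndarray
) -> ClassificationMetrics:
    """Confusion-matrix metrics of an estimated network vs. the truth.

    TPR, FPR, PPV and accuracy are computed per subject and averaged
    unweighted across subjects ("mean performance" is the accuracy
    average).
    """
    est = estimate.edges if isinstance(estimate, SparsifiedNetwork) else np.asarray(estimate)
    est = np.atleast_2d(est).astype(bool)
    truth = np.atleast_2d(np.asarray(truth)).astype(bool)
    if est.shape != truth.shape:
        raise ValueError(f"shape mismatch: estimate {est.shape}, truth {truth.shape}")
    n, m = truth.shape
    tp = (est & truth).sum(axis=1).astype(float)
    fp = (est & ~truth).sum(axis=1).astype(float)
    fn = (~est & truth).sum(axis=1).astype(float)
    tn = (~est & ~truth).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        fpr = np.where(fp + tn > 0, fp / (fp + tn), np.nan)
        ppv = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
    acc = (tp + tn) / m
    per_subject = pd.DataFrame({
        "subject": np.arange(n), "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "tpr": tpr, "fpr": fpr, "ppv": ppv, "accuracy": acc,
    })
    return ClassificationMetrics(
        per_subject=per_subject,
        tpr=float(np.nanmean(tpr)),
        fpr=float(np.nanmean(fpr)),
        ppv=float(np.nanmean(ppv)) if not np.all(np.isnan(ppv)) else float("nan"),
        mean_performance=float(acc.mean()),
        n_undefined_ppv=int(np.isnan(ppv).sum()),
    )
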