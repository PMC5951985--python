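"""Scoring of estimated networks against ground truth or reference wiring."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .connectivity import ConnectivityEstimate, mirror

__all__ = [
    "EvaluationReport",
    "weight_correlation",
    "roc_auc",
    "interfrequency_similarity",
    "fpr_matched_threshold",
    "coincidence_summary",
    "evaluate_estimate",
]


@dataclass
class EvaluationReport:
    """Per-frequency (or per-band) recovery scores for one network."""

    correlation: float
    auc: float
    n_edges_true: int
    n_edges_est: int
    label: str = ""
    config_hash: str = ""


def _offdiag(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    return m[~np.eye(m.shape[0], dtype=bool)]


def weight_correlation(
    est: np.ndarray, truth: np.ndarray, mirrored: bool = False
) -> float:
    """Pearson correlation over all strictly off-diagonal weight pairs.

    Zero entries participate: this is a whole-matrix comparison, not one
    restricted to detected edges.  With ``mirrored`` the estimate is
    symmetrized first (for comparison against symmetric references).
    Returns NaN (with a warning) if either side has zero variance.
    """
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError("shapes must match")
    if mirrored:
        est = mirror(est)
    a, b = _offdiag(est), _offdiag(truth)
    if a.std() == 0 or b.std() == 0:
        warnings.warn(
            "correlation undefined: zero variance on one side", RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def roc_auc(scores: np.ndarray, truth_adjacency: np.ndarray) -> float:
    """Area under the ROC curve for edge detection, ranking by |score|.

    Equals the probability that a uniformly chosen true edge outranks a
    uniformly chosen non-edge (ties counted half).  Off-diagonal entries
    only; the truth must contain at least one edge and one non-edge.
    """
    scores = np.abs(_offdiag(np.asarray(scores)))
    truth = _offdiag(np.asarray(truth_adjacency)) != 0
    if truth.all() or not truth.any():
        raise ValueError("truth must contain at least one edge and one non-edge")
    return float(roc_auc_score(truth, scores))


def interfrequency_similarity(est: ConnectivityEstimate) -> np.ndarray:
    """F x F matrix of weight correlations between frequency slices.

    Symmetric with unit diagonal; degenerate (zero-variance) slices yield
    NaN rows/columns.  Block structure in this matrix is what motivates
    grouping bins into frequency bands.
    """
    F = len(est.frequencies)
    if F < 2:
        raise ValueError("need at least two frequencies")
    sim = np.eye(F)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(F):
            for j in range(i + 1, F):
                r = weight_correlation(
                    est.signed_weights[i], est.signed_weights[j]
                )
                sim[i, j] = sim[j, i] = r
    return sim


def fpr_matched_threshold(
    est: np.ndarray, reference: np.ndarray, target_fpr: float
) -> tuple[float, float]:
    """Smallest |weight| threshold achieving at most the target FPR.

    FPR = fraction of reference-negative off-diagonal entries whose
    estimated magnitude exceeds the threshold.  Returns (threshold,
    achieved_fpr).
    """
    if not 0.0 < target_fpr <= 1.0:
        raise ValueError("target_fpr must lie in (0, 1]")
    ref = _offdiag(np.asarray(reference)) != 0
    if ref.all():
        raise ValueError("reference has no negative entries")
    vals = np.abs(_offdiag(np.asarray(est)))[~ref]
    if float(np.mean(vals > 0.0)) <= target_fpr:
        return 0.0, float(np.mean(vals > 0.0))
    for t in np.sort(np.unique(vals)):
        fpr = float(np.mean(vals > t))
        if fpr <= target_fpr:
            return float(t), fpr
    return float(vals.max()), 0.0


def coincidence_summary(
    est: np.ndarray, reference: np.ndarray
) -> dict[str, float]:
    """Edge-set agreement between a thresholded estimate and a reference.

    Percentages are relative to the union of edges present in either
    network and sum to 100: present in both, present only in the estimate,
    present only in the reference.  Densities are the nonzero fraction of
    off-diagonal entries in each network.
    """
    e = _offdiag(np.asarray(est)) != 0
    r = _offdiag(np.asarray(reference)) != 0
    union = (e | r).sum()
    if union == 0:
        raise ValueError("both networks are empty")
    return {
        "pct_both": 100.0 * (e & r).sum() / union,
        "pct_est_only": 100.0 * (e & ~r).sum() / union,
        "pct_ref_only": 100.0 * (~e & r).sum() / union,
        "density_est": float(e.mean()),
        "density_ref": float(r.mean()),
    }


def evaluate_estimate(
    est: ConnectivityEstimate,
    truth: np.ndarray,
    *,
    mirrored: bool = False,
    bins: np.ndarray | None = None,
) -> list[EvaluationReport]:
    """Correlation and AUC against a ground-truth adjacency, per frequency."""
    truth = np.asarray(truth, dtype=float)
    if bins is None:
        bins = np.arange(len(est.frequencies))
    reports = []
    for fi in bins:
        w = est.signed_weights[fi]
        reports.append(
            EvaluationReport(
                correlation=weight_correlation(w, truth, mirrored=mirrored),
                auc=roc_auc(w, truth),
                n_edges_true=int((_offdiag(truth) != 0).sum()),
                n_edges_est=int((_offdiag(w) != 0).sum()),
                label=f"{est.frequencies[fi]:.4g} Hz",
                config_hash=est.provenance.get("config_hash", ""),
            )
        )
    return reports
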