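"""Link and guild inference from pairwise metric matrices.

A pairwise measure becomes an undirected link graph by thresholding;
guilds are the single-linkage clusters of that graph (transitive closure
of supra-threshold links), or — in the one-iteration variant — pairs are
grouped only when linked directly or through one shared neighbor.
Performance against the ground-truth resource overlap GG^T is scored by
Spearman rank correlation (metric vs overlap entries), and by ROC/AUC
for two binary tasks: link detection (is the overlap entry nonzero?) and
guild detection (do two species share a guild?).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .spectral import MetricMatrix

__all__ = [
    "Partition",
    "RocResult",
    "OVERLAP_TOL",
    "spearman_vs_overlap",
    "threshold_links",
    "single_linkage_partition",
    "pair_comembership",
    "link_roc",
    "pooled_link_roc",
    "guild_roc",
    "local_detectability",
    "DegenerateTruthError",
]

#: floating-point tolerance below which an overlap entry counts as zero
OVERLAP_TOL = 1e-12


class DegenerateTruthError(ValueError):
    """Ground truth has only one class; ROC undefined."""


@dataclass
class Partition:
    """Cluster labels from thresholded single-linkage clustering."""

    labels: np.ndarray
    threshold: float
    linkage_mode: str = "full"

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


@dataclass
class RocResult:
    """Threshold sweep for a binary pair-classification task."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    task: str


def _offdiag(values: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(values.shape[0], k=1)
    return values[iu, ju]


def _metric_values(metric: MetricMatrix | np.ndarray) -> np.ndarray:
    return metric.values if isinstance(metric, MetricMatrix) else np.asarray(metric, dtype=float)


def spearman_vs_overlap(
    metric: MetricMatrix | np.ndarray, overlap: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation between metric and overlap off-diagonals."""
    mv = _metric_values(metric)
    ov = np.asarray(overlap, dtype=float)
    if mv.shape != ov.shape:
        raise ValueError("metric and overlap must have the same shape")
    a, b = _offdiag(mv), _offdiag(ov)
    if a.size < 3:
        raise ValueError("need at least 3 species pairs")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def threshold_links(metric: MetricMatrix | np.ndarray, threshold: float) -> np.ndarray:
    """Boolean adjacency: link each pair whose metric is strictly above threshold."""
    mv = _metric_values(metric)
    links = mv > threshold
    np.fill_diagonal(links, False)
    return links | links.T


def single_linkage_partition(links: np.ndarray, threshold: float = np.nan) -> Partition:
    """Connected components of the link graph (full transitive closure)."""
    links = np.asarray(links, dtype=bool)
    _, labels = connected_components(csr_matrix(links), directed=False)
    return Partition(labels=labels, threshold=threshold, linkage_mode="full")


def pair_comembership(links: np.ndarray, mode: str = "full") -> np.ndarray:
    """Boolean matrix: does the clustering place pair (i, j) together?

    ``full``: same connected component.  ``one_iteration``: linked
    directly or sharing at least one direct neighbor — a single merge
    round; note this relation is not transitive, so it defines pair
    classifications rather than a partition.
    """
    links = np.asarray(links, dtype=bool)
    if mode == "full":
        labels = single_linkage_partition(links).labels
        same = labels[:, None] == labels[None, :]
    elif mode == "one_iteration":
        shared = (links.astype(int) @ links.astype(int)) > 0
        same = links | shared
    else:
        raise ValueError(f"unknown linkage mode {mode!r}")
    np.fill_diagonal(same, True)
    return same


def _check_truth(truth: np.ndarray, task: str) -> None:
    if truth.all() or not truth.any():
        raise DegenerateTruthError(f"{task} ground truth has a single class")


def link_roc(metric: MetricMatrix | np.ndarray, overlap: np.ndarray) -> RocResult:
    """ROC for detecting nonzero resource overlap from the pair scores.

    Sweeps every distinct score value (exact ROC), trapezoidal AUC.
    """
    scores = _offdiag(_metric_values(metric))
    truth = _offdiag(np.asarray(overlap, dtype=float)) > OVERLAP_TOL
    _check_truth(truth, "link")
    fpr, tpr, thresholds = _sk_roc_curve(truth, scores)
    return RocResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)), task="link"
    )


def pooled_link_roc(
    metrics: list[MetricMatrix | np.ndarray], overlaps: list[np.ndarray]
) -> RocResult:
    """Link ROC with pair scores pooled across realizations."""
    scores = np.concatenate([_offdiag(_metric_values(m)) for m in metrics])
    truth = np.concatenate(
        [_offdiag(np.asarray(o, dtype=float)) > OVERLAP_TOL for o in overlaps]
    )
    _check_truth(truth, "link")
    fpr, tpr, thresholds = _sk_roc_curve(truth, scores)
    return RocResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)), task="link"
    )


def guild_roc(
    metric: MetricMatrix | np.ndarray,
    true_labels: np.ndarray,
    mode: str = "full",
    n_thresholds: int = 200,
) -> RocResult:
    """ROC for same-guild classification after threshold-and-cluster.

    For each threshold the link graph is clustered (mode ``full`` or
    ``one_iteration``) and every species pair is classified same/different
    cluster against the ground-truth labels.  Thresholds sweep the
    off-diagonal metric range (plus +/- infinity endpoints).
    """
    mv = _metric_values(metric)
    labels = np.asarray(true_labels)
    if labels.shape[0] != mv.shape[0]:
        raise ValueError("label vector does not match the metric size")
    truth = _offdiag(labels[:, None] == labels[None, :])
    _check_truth(truth, "guild")

    off = _offdiag(mv)
    ths = np.concatenate(
        [[np.inf], np.linspace(off.max(), off.min(), n_thresholds), [-np.inf]]
    )
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    tpr = np.empty(ths.size)
    fpr = np.empty(ths.size)
    for idx, th in enumerate(ths):
        pred = _offdiag(pair_comembership(threshold_links(mv, th), mode=mode))
        tpr[idx] = (pred & truth).sum() / n_pos
        fpr[idx] = (pred & ~truth).sum() / n_neg
    order = np.argsort(fpr, kind="stable")
    roc_auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocResult(thresholds=ths, fpr=fpr, tpr=tpr, auc=roc_auc, task="guild")


def local_detectability(
    links: np.ndarray, true_labels: np.ndarray, guild_id: int
) -> tuple[float, float]:
    """Per-guild true/false positive link rates.

    TPR: detected within-guild links over N_k (N_k - 1) / 2 possible
    pairs.  FPR: probability that a guild member is linked to a species
    outside the guild.
    """
    links = np.asarray(links, dtype=bool)
    labels = np.asarray(true_labels)
    members = np.where(labels == guild_id)[0]
    n_k = members.size
    if n_k == 0:
        raise ValueError(f"guild {guild_id} does not exist")
    if n_k < 2:
        raise ValueError(f"guild {guild_id} is a singleton; detectability undefined")
    outsiders = np.where(labels != guild_id)[0]
    within = links[np.ix_(members, members)]
    tp = np.triu(within, k=1).sum()
    tpr = tp / (n_k * (n_k - 1) / 2)
    if outsiders.size == 0:
        return float(tpr), 0.0
    fp = links[np.ix_(members, outsiders)].sum()
    fpr = fp / (n_k * outsiders.size)
    return float(tpr), float(fpr)
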