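"""Empirical relative-abundance pipeline.

Applies the pairwise metrics to taxa x time relative-abundance tables
(replicates averaged per day, taxa filtered to those present every day)
and relates them to phylogenetic distance computed from pre-aligned
marker-gene sequences (Jukes-Cantor).  Without a ground-truth resource
overlap, association is assessed by binning the pairwise metric against
distance and comparing the first (closest-relatives) bin to an
index-shuffle null that permutes taxa jointly in the metric matrix,
preserving the multiset of metric values but destroying any relation to
phylogeny.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._rng import substream
from .inference import Partition, single_linkage_partition, threshold_links
from .spectral import MetricMatrix

__all__ = [
    "AbundanceTable",
    "DistanceMatrix",
    "BinnedAssociation",
    "load_and_average",
    "filter_always_present",
    "jukes_cantor",
    "bin_metric_by_distance",
    "index_shuffle_null",
    "cluster_to_k",
]

_REPLICATE_RE = re.compile(r"^(?P<day>\d+)(?:[._\-:](?P<rep>\w+))?$")


@dataclass
class AbundanceTable:
    """Taxa x time abundance matrix with equally spaced integer day labels."""

    taxa: list[str]
    times: np.ndarray
    values: np.ndarray
    is_relative: bool = False

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.taxa):
            raise ValueError("distance matrix must be square and match the taxa list")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        self.values = v


@dataclass
class BinnedAssociation:
    """Pairwise metric summarized in equal-width distance bins.

    ``null_means`` holds one row per shuffle when produced by the
    index-shuffle null; ``first_bin_p`` is the upper-tail proportion of
    shuffles whose first-bin mean exceeds the observed one.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    null_means: np.ndarray | None = None
    first_bin_p: float | None = None
    first_bin_index: int = 0


def load_and_average(
    table: pd.DataFrame | str | Path, sep: str = "\t", is_relative: bool | None = None
) -> AbundanceTable:
    """Read a taxa x (day, replicate) table and average replicates per day.

    Columns are named ``<day>`` or ``<day><sep><replicate>`` where the
    separator is one of ``. _ - :`` (e.g. ``12_1``, ``12_2``).  Every
    replicate set must cover the same days; day labels must be
    consecutive with equal spacing (the metrics assume regular sampling
    and no imputation is attempted).
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep=sep, index_col=0)
    day_of: dict[str, int] = {}
    rep_of: dict[str, str] = {}
    for col in table.columns:
        m = _REPLICATE_RE.match(str(col).strip())
        if not m:
            raise ValueError(f"cannot parse column label {col!r} as day[{{sep}}replicate]")
        day_of[col] = int(m.group("day"))
        rep_of[col] = m.group("rep") or "1"

    days = sorted(set(day_of.values()))
    reps = sorted(set(rep_of.values()))
    covered = {r: {day_of[c] for c in table.columns if rep_of[c] == r} for r in reps}
    missing = {r: sorted(set(days) - covered[r]) for r in reps if set(days) - covered[r]}
    if missing:
        detail = "; ".join(f"replicate {r}: days {m}" for r, m in missing.items())
        raise ValueError(f"days missing from some replicate sets: {detail}")
    if table.isna().any().any():
        bad = sorted({day_of[c] for c in table.columns if table[c].isna().any()})
        raise ValueError(f"missing values on days {bad}")

    spacing = np.diff(days)
    if len(days) > 1 and not np.all(spacing == spacing[0]):
        gaps = [int(days[i + 1]) for i, s in enumerate(spacing) if s != spacing[0]]
        raise ValueError(f"day labels are not equally spaced (irregular before days {gaps})")

    values = np.empty((table.shape[0], len(days)))
    for j, d in enumerate(days):
        cols = [c for c in table.columns if day_of[c] == d]
        values[:, j] = table[cols].to_numpy(dtype=float).mean(axis=1)
    if np.any(values < 0):
        raise ValueError("abundances must be non-negative")
    if is_relative is None:
        is_relative = bool(np.all(values.sum(axis=0) <= 1.0 + 1e-6))
    return AbundanceTable(
        taxa=[str(t) for t in table.index],
        times=np.asarray(days),
        values=values,
        is_relative=is_relative,
    )


def filter_always_present(table: AbundanceTable) -> AbundanceTable:
    """Keep only taxa with strictly positive abundance at every time point."""
    keep = np.all(table.values > 0, axis=1)
    if not keep.any():
        raise ValueError("no taxon is present at every time point")
    return AbundanceTable(
        taxa=[t for t, k in zip(table.taxa, keep) if k],
        times=table.times,
        values=table.values[keep],
        is_relative=table.is_relative,
    )


_VALID_BASES = frozenset("ACGT")


def jukes_cantor(records) -> DistanceMatrix:
    """Jukes-Cantor distances from pre-aligned sequences.

    ``records`` is a path to an aligned FASTA or an iterable of
    (id, sequence) pairs / SeqRecords.  Sites where either sequence has
    a gap or ambiguity code are excluded pairwise (U is read as T); with
    p the mismatch proportion over comparable sites,
    d = -(3/4) ln(1 - 4p/3), undefined for p >= 3/4.
    """
    if isinstance(records, (str, Path)):
        records = list(SeqIO.parse(str(records), "fasta"))
    ids: list[str] = []
    seqs: list[str] = []
    for rec in records:
        if hasattr(rec, "seq"):
            ids.append(str(rec.id))
            seqs.append(str(rec.seq))
        else:
            name, seq = rec
            ids.append(str(name))
            seqs.append(str(seq))
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences are not aligned (unequal lengths)")

    enc = np.array(
        [[c if c in _VALID_BASES else "-" for c in s.upper().replace("U", "T")] for s in seqs]
    )
    valid = enc != "-"
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = valid[i] & valid[j]
            n_sites = int(comparable.sum())
            if n_sites == 0:
                raise ValueError(f"no comparable sites between {ids[i]} and {ids[j]}")
            p = float((enc[i, comparable] != enc[j, comparable]).sum()) / n_sites
            if p >= 0.75:
                raise ValueError(
                    f"Jukes-Cantor distance undefined for {ids[i]} vs {ids[j]} (p = {p:.3f} >= 3/4)"
                )
            d[i, j] = d[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return DistanceMatrix(taxa=ids, values=d)


def _pair_arrays(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def _bin_assignments(dist: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = _pair_arrays(dist.shape[0])
    dvals = dist[iu, ju]
    edges = np.linspace(dvals.min(), dvals.max(), n_bins + 1)
    idx = np.clip(np.digitize(dvals, edges[1:-1]), 0, n_bins - 1)
    return edges, idx


def _binned_means(values: np.ndarray, bin_idx: np.ndarray, n_bins: int) -> tuple[np.ndarray, ...]:
    counts = np.bincount(bin_idx, minlength=n_bins)
    sums = np.bincount(bin_idx, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        sq = np.bincount(bin_idx, weights=values**2, minlength=n_bins)
        sds = np.where(counts > 0, np.sqrt(np.maximum(sq / np.maximum(counts, 1) - means**2, 0.0)), np.nan)
    return counts, means, sds


def bin_metric_by_distance(
    metric: MetricMatrix | np.ndarray, dist: DistanceMatrix, n_bins: int = 8
) -> BinnedAssociation:
    """Mean/sd of the pairwise metric in equal-width distance bins."""
    mv = metric.values if isinstance(metric, MetricMatrix) else np.asarray(metric, dtype=float)
    if mv.shape != dist.values.shape:
        raise ValueError("metric and distance matrices must match")
    iu, ju = _pair_arrays(mv.shape[0])
    edges, bin_idx = _bin_assignments(dist.values, n_bins)
    counts, means, sds = _binned_means(mv[iu, ju], bin_idx, n_bins)
    if np.any(counts == 0):
        warnings.warn(f"{int((counts == 0).sum())} empty distance bins (reported as NaN)")
    return BinnedAssociation(bin_edges=edges, counts=counts, means=means, sds=sds)


def index_shuffle_null(
    metric: MetricMatrix | np.ndarray,
    dist: DistanceMatrix,
    n_bins: int = 8,
    n_shuffles: int = 10_000,
    seed: int = 0,
) -> BinnedAssociation:
    """Index-shuffle null for the metric-vs-distance binned association.

    Each shuffle applies one random permutation jointly to rows and
    columns of the metric matrix (preserving its multiset of values) and
    recomputes the binned means against the fixed distances.  The
    first-bin p value is the proportion of shuffles whose mean in the
    first non-empty bin exceeds the observed mean.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    mv = metric.values if isinstance(metric, MetricMatrix) else np.asarray(metric, dtype=float)
    if mv.shape != dist.values.shape:
        raise ValueError("metric and distance matrices must match")
    n = mv.shape[0]
    iu, ju = _pair_arrays(n)
    edges, bin_idx = _bin_assignments(dist.values, n_bins)
    counts, means, sds = _binned_means(mv[iu, ju], bin_idx, n_bins)
    first = int(np.flatnonzero(counts > 0)[0])

    rng = substream(seed, "index-shuffle")
    counts_f = np.maximum(counts, 1).astype(float)
    null_means = np.empty((n_shuffles, n_bins))
    for s in range(n_shuffles):
        perm = rng.permutation(n)
        vals = mv[perm[iu], perm[ju]]
        null_means[s] = np.bincount(bin_idx, weights=vals, minlength=n_bins) / counts_f
    null_means[:, counts == 0] = np.nan
    p = float(np.mean(null_means[:, first] > means[first]))
    return BinnedAssociation(
        bin_edges=edges,
        counts=counts,
        means=means,
        sds=sds,
        null_means=null_means,
        first_bin_p=p,
        first_bin_index=first,
    )


def cluster_to_k(
    metric: MetricMatrix | np.ndarray, k_target: int, mode: str = "full"
) -> Partition:
    """Find a threshold whose single-linkage partition has ``k_target`` clusters.

    Binary-searches the sorted unique off-diagonal metric values (the
    cluster count is non-increasing as the threshold decreases).  When
    ties make the exact count unreachable, the nearest achievable count
    is returned with a warning.
    """
    if mode != "full":
        raise ValueError("cluster_to_k requires the full transitive-closure mode")
    mv = metric.values if isinstance(metric, MetricMatrix) else np.asarray(metric, dtype=float)
    n = mv.shape[0]
    if not 1 <= k_target <= n:
        raise ValueError(f"k_target must lie in [1, {n}]")
    iu, ju = _pair_arrays(n)
    uniq = np.unique(mv[iu, ju])

    def count_at(th: float) -> int:
        return single_linkage_partition(threshold_links(mv, th)).n_clusters

    # candidate thresholds: above the max (all singletons) plus each unique
    # value (strict > drops ties together); counts are non-increasing with
    # decreasing threshold index.
    candidates = np.concatenate([[uniq[-1] + 1.0], uniq[::-1]])
    lo, hi = 0, candidates.size - 1  # lo: high threshold (many clusters)
    best_idx = 0
    while lo <= hi:
        mid = (lo + hi) // 2
        c = count_at(candidates[mid])
        if c >= k_target:
            best_idx = mid
            lo = mid + 1
        else:
            hi = mid - 1
    th = float(candidates[best_idx])
    achieved = count_at(th)
    if achieved != k_target and best_idx + 1 < candidates.size:
        # a lower threshold may land nearer the target from below
        alt_th = float(candidates[best_idx + 1])
        alt = count_at(alt_th)
        if abs(alt - k_target) < abs(achieved - k_target):
            th, achieved = alt_th, alt
    if achieved != k_target:
        warnings.warn(
            f"exact cluster count {k_target} unreachable (ties); returning {achieved}"
        )
    links = threshold_links(mv, th)
    part = single_linkage_partition(links, threshold=th)
    return part
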