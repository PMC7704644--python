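"""Pairwise IBD summaries and downstream relatedness analyses.

Includes per-pair genome-fraction summaries (interval unions in genetic
distance), per-individual genome coverage, the threshold-based effective
population size estimator ``Ne = T / mean(f_T)``, the closed-form expected
total IBD sharing for k-th degree cousins, kNN birth-location prediction
from a sparse similarity, and average-linkage agglomerative clustering of
sparse similarity matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .panel_io import GeneticMap

logger = logging.getLogger(__name__)

__all__ = [
    "PairSummary",
    "pair_summaries",
    "genome_coverage",
    "estimate_ne",
    "expected_cousin_sharing",
    "knn_predict_location",
    "Dendrogram",
    "cluster_average_linkage",
]


def _union_length(intervals) -> float:
    """Total length of a union of (lo, hi) intervals."""
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    total = 0.0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    return total + (cur_hi - cur_lo)


@dataclass
class PairSummary:
    """Sparse symmetric per-pair IBD summaries, keyed by (min_id, max_id)."""

    n_segments: dict[tuple, int] = field(default_factory=dict)
    total_cm: dict[tuple, float] = field(default_factory=dict)
    fraction_genome: dict[tuple, float] = field(default_factory=dict)


def _iter_segments(segments):
    """Yield (ind_a, ind_b, start_cm, end_cm) from a DataFrame or segment list."""
    if hasattr(segments, "itertuples"):
        has_cm = "start_cm" in segments.columns
        for row in segments.itertuples():
            if has_cm:
                yield row.ind_a, row.ind_b, float(row.start_cm), float(row.end_cm)
            else:
                yield row.ind_a, row.ind_b, float(row.start_bp), float(row.end_bp)
    else:
        for s in segments:
            yield s.ind_a, s.ind_b, s.start_cm, s.end_cm


def _to_cm_intervals(segments, gmap: GeneticMap):
    """Normalize segments to (ind_a, ind_b, start_cm, end_cm)."""
    if hasattr(segments, "itertuples") and "start_cm" not in segments.columns:
        start = gmap.interp_cm(segments["start_bp"].to_numpy())
        end = gmap.interp_cm(segments["end_bp"].to_numpy())
        for a, b, lo, hi in zip(segments["ind_a"], segments["ind_b"], start, end):
            yield a, b, float(lo), float(hi)
    else:
        yield from _iter_segments(segments)


def pair_summaries(segments, gmap: GeneticMap) -> PairSummary:
    """Per-pair segment count, union total cM and genome fraction.

    Overlapping segments of a pair are unioned before coverage arithmetic.
    Segments outside the map raise ``ValueError``.
    """
    lo_map, hi_map = float(gmap.cm[0]), float(gmap.cm[-1])
    by_pair: dict[tuple, list] = {}
    counts: dict[tuple, int] = {}
    for a, b, lo, hi in _to_cm_intervals(segments, gmap):
        if lo < lo_map - 1e-9 or hi > hi_map + 1e-9:
            raise ValueError(f"segment [{lo}, {hi}] cM outside map [{lo_map}, {hi_map}]")
        key = (a, b) if a <= b else (b, a)
        by_pair.setdefault(key, []).append((lo, hi))
        counts[key] = counts.get(key, 0) + 1
    out = PairSummary()
    total = gmap.total_cM
    for key, ivs in by_pair.items():
        u = _union_length(ivs)
        out.n_segments[key] = counts[key]
        out.total_cm[key] = u
        out.fraction_genome[key] = u / total
    return out


def genome_coverage(segments, individual, gmap: GeneticMap) -> float:
    """Fraction of *individual*'s genome covered by >= 1 segment with anyone
    (union over all partners and both haplotypes)."""
    ivs = [
        (lo, hi)
        for a, b, lo, hi in _to_cm_intervals(segments, gmap)
        if a == individual or b == individual
    ]
    return _union_length(ivs) / gmap.total_cM


def estimate_ne(f_mean: float, T: float) -> float:
    """Aggregate effective population size: T over the mean IBD fraction."""
    if T <= 0:
        raise ValueError("T must be positive")
    if f_mean <= 0:
        raise ValueError("mean IBD fraction must be positive (estimate diverges)")
    return T / f_mean


def expected_cousin_sharing(k: int, G: float = 7247.14) -> float:
    """Expected total IBD (cM) for k-th degree cousins: 2 G (1/2)^(2(k+1)).

    ``G`` is the total diploid genome size in cM; cousins of degree k are
    separated by 2(k+1) generations.
    """
    if k < 1:
        raise ValueError("cousin degree must be >= 1")
    if G <= 0:
        raise ValueError("genome size must be positive")
    return 2.0 * G * 0.5 ** (2 * (k + 1))


# ---------------------------------------------------------------------------
# kNN birth-location prediction
# ---------------------------------------------------------------------------


def knn_predict_location(
    similarity: Mapping[tuple, float],
    coords: Mapping[object, tuple[float, float]],
    query_ids: Sequence,
    K: int = 5,
    exclude_pairs: Sequence[tuple] = (),
) -> dict:
    """Predict each query's coordinates as the unweighted mean of its K
    most-similar neighbors with known coordinates.

    ``similarity`` maps unordered id pairs to total shared cM; excluded
    pairs (e.g. close relatives) are skipped.  Ties are broken by neighbor
    id.  Queries with fewer than K usable neighbors get NaN predictions
    with a warning.  Returns predictions plus error summaries for queries
    whose true coordinates are known.
    """
    excl = {tuple(sorted(p)) for p in exclude_pairs}
    neigh: dict[object, list] = {}
    for (a, b), s in similarity.items():
        key = tuple(sorted((a, b)))
        if key in excl:
            continue
        neigh.setdefault(a, []).append((b, s))
        neigh.setdefault(b, []).append((a, s))

    predictions: dict[object, tuple[float, float]] = {}
    errors = []
    pred_xy, true_xy = [], []
    for q in query_ids:
        cands = [
            (nb, s) for nb, s in neigh.get(q, [])
            if nb != q and nb not in query_ids and nb in coords
        ]
        if len(cands) < K:
            warnings.warn(f"query {q!r} has {len(cands)} usable neighbors (< K={K})", stacklevel=2)
            predictions[q] = (float("nan"), float("nan"))
            continue
        cands.sort(key=lambda t: (-t[1], str(t[0])))
        top = cands[:K]
        xy = np.mean([coords[nb] for nb, _ in top], axis=0)
        predictions[q] = (float(xy[0]), float(xy[1]))
        if q in coords:
            tx, ty = coords[q]
            errors.append(float(np.hypot(xy[0] - tx, xy[1] - ty)))
            pred_xy.append(xy)
            true_xy.append((tx, ty))

    summary = {"n_predicted": len(errors)}
    if errors:
        summary["median_error"] = float(np.median(errors))
        summary["mean_error"] = float(np.mean(errors))
        p = np.array(pred_xy)
        t = np.array(true_xy)
        for ax, name in ((0, "r_x"), (1, "r_y")):
            if len(errors) > 2 and np.std(p[:, ax]) > 0 and np.std(t[:, ax]) > 0:
                summary[name] = float(np.corrcoef(p[:, ax], t[:, ax])[0, 1])
            else:
                summary[name] = float("nan")
    return {"predictions": predictions, "errors": errors, "summary": summary}


# ---------------------------------------------------------------------------
# Sparse average-linkage clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Sequence of agglomerative merges on similarity.

    ``merges[t] = (id_i, id_j, similarity, new_size)``; original leaves are
    0..n-1 and merge t creates cluster id n + t (scipy linkage convention).
    ``ids`` maps leaf indices back to the input identifiers.
    """

    ids: list
    merges: list[tuple[int, int, float, int]]

    def flat_clusters(self, cut: float, min_cluster_size: int = 1) -> dict:
        """Replay merges with similarity >= *cut*; clusters smaller than
        ``min_cluster_size`` are labeled -1 (unassigned)."""
        n = len(self.ids)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        for t, (i, j, sim, _) in enumerate(self.merges):
            if sim < cut:
                break
            members[n + t] = members.pop(i) + members.pop(j)
        labels = {}
        next_label = 0
        for clust in sorted(members.values(), key=lambda m: (-len(m), m[0])):
            if len(clust) >= min_cluster_size:
                lab = next_label
                next_label += 1
            else:
                lab = -1
            for leaf in clust:
                labels[self.ids[leaf]] = lab
        return labels


def _largest_component(ids, similarity):
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    index = {v: i for i, v in enumerate(ids)}
    rows, cols = [], []
    for (a, b), s in similarity.items():
        if s > 0 and a in index and b in index:
            rows.append(index[a])
            cols.append(index[b])
    m = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(ids), len(ids))
    )
    n_comp, labels = connected_components(m, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        keep = int(np.argmax(sizes))
        dropped = len(ids) - int(sizes[keep])
        logger.info("dropping %d node(s) outside the largest connected component", dropped)
        ids = [v for v, l in zip(ids, labels) if l == keep]
    return ids


def cluster_average_linkage(
    similarity: Mapping[tuple, float],
    ids: Sequence | None = None,
    min_cluster_size: int = 1,
    restrict_to_component: bool = True,
) -> Dendrogram:
    """Agglomerative average-linkage clustering on a sparse similarity.

    At each step the two clusters with the highest average cross-pair
    similarity (absent entries count as 0) are merged; ties are broken by
    cluster index.  Only the largest connected component is clustered when
    ``restrict_to_component`` is set (smaller components are dropped with a
    log message).
    """
    if ids is None:
        ids = sorted({v for pair in similarity for v in pair}, key=str)
    ids = list(ids)
    if restrict_to_component and len(ids) > 1:
        ids = _largest_component(ids, similarity)
    n = len(ids)
    if n == 0:
        raise ValueError("empty component: nothing to cluster")
    index = {v: i for i, v in enumerate(ids)}
    # sums[i, j] = summed cross-pair similarity between clusters i and j
    size = np.ones(n)
    sums = np.zeros((n, n))
    for (a, b), s in similarity.items():
        if a in index and b in index and a != b:
            i, j = index[a], index[b]
            sums[i, j] += s
            sums[j, i] += s
    active = list(range(n))
    merges = []
    next_id = n
    labels = list(range(n))  # dendrogram ids of active clusters
    while len(active) > 1:
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                avg = sums[i, j] / (size[i] * size[j])
                if best is None or avg > best[0] + 1e-15:
                    best = (avg, i, j)
        avg, i, j = best
        # merge j into i; Lance-Williams on sums is exact
        sums[i, :] += sums[j, :]
        sums[:, i] += sums[:, j]
        size[i] += size[j]
        merges.append((labels[i], labels[j], float(avg), int(size[i])))
        labels[i] = next_id
        next_id += 1
        active.remove(j)
    return Dendrogram(ids, merges)
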