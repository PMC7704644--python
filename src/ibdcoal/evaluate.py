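"""Site-level accuracy evaluation under the TMRCA-threshold IBD definition.

A (pair, site) unit is truly IBD iff the pair's true TMRCA at the site is
below the time threshold T; it is predicted IBD iff at least one reported
segment for that pair covers the site.  Precision-recall curves sweep a
per-segment score (quality score for verified segments, genetic length for
raw candidates) and report area under the curve over the achieved recall
range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SiteConfusion",
    "ScoredCall",
    "site_confusion",
    "precision_recall_curve",
    "mle_age",
    "age_error_summary",
]


@dataclass(frozen=True)
class SiteConfusion:
    """Confusion counts over (pair, site) units at threshold T."""

    TP: int
    FP: int
    TN: int
    FN: int
    threshold: float

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def precision(self) -> float:
        denom = self.TP + self.FP
        if denom == 0:
            warnings.warn("no predicted-IBD sites; precision undefined", stacklevel=2)
            return float("nan")
        return self.TP / denom

    @property
    def recall(self) -> float:
        denom = self.TP + self.FN
        return self.TP / denom if denom else float("nan")


@dataclass(frozen=True)
class ScoredCall:
    """A reported segment reduced to its pair, covered site range and score."""

    pair: tuple[int, int]
    start_site: int
    end_site: int  # half-open
    score: float


def _coverage_mask(calls, pair_index, n_sites):
    mask = np.zeros((len(pair_index), n_sites), dtype=bool)
    for c in calls:
        mask[pair_index[c.pair], c.start_site : c.end_site] = True
    return mask


def site_confusion(
    truth: Mapping[tuple[int, int], np.ndarray],
    calls: Sequence[ScoredCall],
    T: float,
    n_sites: int,
) -> SiteConfusion:
    """Tally TP/FP/TN/FN over all (pair, site) units.

    *truth* maps each evaluated haplotype pair to its per-site true TMRCA
    array (length ``n_sites``).  Every call's pair must appear in *truth*.
    """
    pairs = sorted(truth)
    pair_index = {p: i for i, p in enumerate(pairs)}
    for c in calls:
        if c.pair not in pair_index:
            raise ValueError(f"pair {c.pair} missing from truth")
    truth_mat = np.stack([np.asarray(truth[p], dtype=float) for p in pairs])
    if truth_mat.shape[1] != n_sites:
        raise ValueError("truth arrays do not match the evaluated site count")
    is_ibd = truth_mat < T
    pred = _coverage_mask(calls, pair_index, n_sites)
    tp = int(np.sum(pred & is_ibd))
    fp = int(np.sum(pred & ~is_ibd))
    fn = int(np.sum(~pred & is_ibd))
    tn = int(np.sum(~pred & ~is_ibd))
    return SiteConfusion(tp, fp, tn, fn, T)


def precision_recall_curve(
    calls: Sequence[ScoredCall],
    truth: Mapping[tuple[int, int], np.ndarray],
    T: float,
    n_sites: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sweep score thresholds (unique scores, descending) and integrate.

    Returns ``(precision, recall, auPRC)``.  The area is the trapezoid
    integral of precision over the achieved recall range, normalized by the
    width of that range (so a perfectly ranked call set scores 1 and a
    random ranking scores the positive-class prevalence).  Raises if the
    truth contains no positive site.
    """
    pairs = sorted(truth)
    pair_index = {p: i for i, p in enumerate(pairs)}
    for c in calls:
        if c.pair not in pair_index:
            raise ValueError(f"pair {c.pair} missing from truth")
    truth_mat = np.stack([np.asarray(truth[p], dtype=float) for p in pairs])
    is_ibd = truth_mat < T
    n_pos = int(is_ibd.sum())
    if n_pos == 0:
        raise ValueError("no positive truth sites at this threshold")

    order = np.argsort([-c.score for c in calls], kind="stable")
    coverage = np.zeros(truth_mat.shape, dtype=np.int32)
    tp = fp = 0
    precisions, recalls = [], []
    i = 0
    while i < len(order):
        score = calls[order[i]].score
        while i < len(order) and calls[order[i]].score == score:
            c = calls[order[i]]
            row = pair_index[c.pair]
            sl = slice(c.start_site, c.end_site)
            newly = coverage[row, sl] == 0
            tp += int(np.sum(newly & is_ibd[row, sl]))
            fp += int(np.sum(newly & ~is_ibd[row, sl]))
            coverage[row, sl] += 1
            i += 1
        precisions.append(tp / (tp + fp) if tp + fp else 1.0)
        recalls.append(tp / n_pos)
    precisions = np.array(precisions)
    recalls = np.array(recalls)
    if len(recalls) == 0:
        return precisions, recalls, float("nan")
    span = recalls[-1] - recalls[0]
    if span > 0:
        au = float(np.trapezoid(precisions, recalls)) / float(span)
    else:
        au = float(precisions[-1])
    return precisions, recalls, au


def mle_age(length_morgans: float) -> float:
    """Length-based maximum-likelihood age of an IBD segment: 1 / (2 l)."""
    if length_morgans <= 0:
        raise ValueError("segment length must be positive")
    return 1.0 / (2.0 * length_morgans)


def age_error_summary(
    lengths_cm: np.ndarray,
    age_map: np.ndarray,
    age_true: np.ndarray,
    min_length_grid: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0),
) -> dict[float, dict[str, float]]:
    """Median absolute age error of the length MLE and the MAP estimate.

    For each minimum-length cutoff, errors are computed over segments of at
    least that genetic length; the true age of a detected segment is the
    length-weighted mean truth TMRCA over its span (supplied by the
    caller).  Empty bins yield NaN with a warning.
    """
    lengths_cm = np.asarray(lengths_cm, dtype=float)
    age_map = np.asarray(age_map, dtype=float)
    age_true = np.asarray(age_true, dtype=float)
    mle = 1.0 / (2.0 * lengths_cm / 100.0)
    out = {}
    for cut in min_length_grid:
        sel = lengths_cm >= cut
        if not np.any(sel):
            warnings.warn(f"no segments >= {cut} cM", stacklevel=2)
            out[cut] = {"mle": float("nan"), "map": float("nan"), "n": 0}
            continue
        out[cut] = {
            "mle": float(np.median(np.abs(mle[sel] - age_true[sel]))),
            "map": float(np.median(np.abs(age_map[sel] - age_true[sel]))),
            "n": int(sel.sum()),
        }
    return out
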