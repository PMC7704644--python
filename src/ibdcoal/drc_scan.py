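"""Density-of-recent-coalescence (DRC) selection scan.

The per-site statistic is the mean, over all analyzed pairs, of the pair's
IBD quality score at the site (zero where no segment covers the site);
sites are averaged within tiling windows of genetic distance.  A Gamma
null is fitted by maximum likelihood to putative-neutral windows and
iteratively refined by excluding newly significant windows; one-sided
upper-tail p-values are Bonferroni-corrected over the tested windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DRCWindow",
    "ScanResult",
    "drc_statistic",
    "fit_gamma_null",
    "selection_scan",
    "bonferroni_threshold",
]


@dataclass
class DRCWindow:
    """One half-open genetic-distance window of the scan."""

    chrom: str
    start_cm: float
    end_cm: float
    start_bp: int
    end_bp: int
    drc: float
    n_sites: int
    p_value: float = float("nan")
    significant: bool = False


def drc_statistic(
    segments,
    n_pairs_analyzed: int,
    gen_pos: np.ndarray,
    phys_pos: np.ndarray,
    chrom: str = "1",
    window_cM: float = 0.05,
) -> list[DRCWindow]:
    """Window-averaged DRC statistic from scored IBD segments.

    *segments* is an iterable with ``start_site``, ``end_site`` (half-open)
    and ``score`` attributes (``IBDSegment`` works).  Windows tile genetic
    distance from the first site's position; windows without sites are
    flagged with ``n_sites == 0`` and excluded from testing downstream.
    """
    if n_pairs_analyzed <= 0:
        raise ValueError("n_pairs_analyzed must be positive")
    gen_pos = np.asarray(gen_pos, dtype=float)
    phys_pos = np.asarray(phys_pos, dtype=np.int64)
    n_sites = len(gen_pos)
    per_site = np.zeros(n_sites)
    for seg in segments:
        if seg.start_site < 0 or seg.end_site > n_sites:
            raise ValueError(
                f"segment site range [{seg.start_site}, {seg.end_site}) outside panel"
            )
        per_site[seg.start_site : seg.end_site] += seg.score
    per_site /= n_pairs_analyzed

    start = gen_pos[0]
    n_win = int(np.floor((gen_pos[-1] - start) / window_cM)) + 1
    win_idx = np.minimum(((gen_pos - start) / window_cM).astype(int), n_win - 1)
    out = []
    for w in range(n_win):
        lo_cm = start + w * window_cM
        hi_cm = lo_cm + window_cM
        in_w = win_idx == w
        cnt = int(in_w.sum())
        drc = float(per_site[in_w].mean()) if cnt else 0.0
        if cnt:
            lo_bp, hi_bp = int(phys_pos[in_w][0]), int(phys_pos[in_w][-1])
        else:
            lo_bp = hi_bp = 0
        out.append(DRCWindow(chrom, lo_cm, hi_cm, lo_bp, hi_bp, drc, cnt))
    return out


def _overlaps_excluded(win: DRCWindow, regions, pad: int) -> bool:
    for chrom, lo, hi in regions:
        if chrom == win.chrom and win.start_bp <= hi + pad and win.end_bp >= lo - pad:
            return True
    return False


def fit_gamma_null(
    windows: Sequence[DRCWindow],
    excluded_regions: Sequence[tuple[str, int, int]] = (),
    pad: int = 500_000,
    min_windows: int = 30,
) -> tuple[float, float]:
    """Maximum-likelihood Gamma fit (location fixed at 0) to neutral windows.

    Windows overlapping any excluded region (padded by *pad* bp) or holding
    no sites are left out; exact zeros are excluded from the fit (logged).
    Returns ``(shape, scale)``.
    """
    vals = [
        w.drc
        for w in windows
        if w.n_sites > 0 and not _overlaps_excluded(w, excluded_regions, pad)
    ]
    n_zero = sum(1 for v in vals if v <= 0)
    if n_zero:
        logger.info("excluding %d zero-DRC window(s) from the Gamma fit", n_zero)
    vals = np.array([v for v in vals if v > 0])
    if len(vals) < min_windows:
        raise ValueError(
            f"only {len(vals)} usable neutral windows (< {min_windows}); cannot fit null"
        )
    var = float(np.var(vals))
    mean = float(np.mean(vals))
    if var <= 0:
        raise ValueError("neutral DRC values are constant; Gamma null is degenerate")
    try:
        shape, _, scale = stats.gamma.fit(vals, floc=0)
    except (ValueError, RuntimeError):  # near-degenerate samples: fall back to moments
        logger.info("Gamma MLE failed; using method-of-moments fit")
        shape, scale = mean**2 / var, var / mean
    return float(shape), float(scale)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    return alpha / n_tests


@dataclass
class ScanResult:
    windows: list[DRCWindow]
    shape: float
    scale: float
    alpha: float
    per_test_threshold: float
    n_tested: int
    iterations: int
    iteration_log: list[str] = field(default_factory=list)


def selection_scan(
    windows: Sequence[DRCWindow],
    known_regions: Sequence[tuple[str, int, int]] = (),
    alpha: float = 0.05,
    pad: int = 500_000,
    max_iter: int = 20,
) -> ScanResult:
    """Iterative Gamma-null scan with Bonferroni calls.

    The null is fitted on windows outside *known_regions*; windows whose
    upper-tail p-value beats ``alpha / n_tested`` are called significant,
    removed from the neutral set, and the null is refitted until the
    significant set stabilizes.
    """
    windows = list(windows)
    tested = [w for w in windows if w.n_sites > 0]
    n_tested = len(tested)
    if n_tested == 0:
        raise ValueError("no testable windows")
    thr = bonferroni_threshold(alpha, n_tested)
    extra_excluded: list[tuple[str, int, int]] = []
    log: list[str] = []
    prev_sig: set[int] = set()
    for it in range(1, max_iter + 1):
        shape, scale = fit_gamma_null(
            windows, list(known_regions) + extra_excluded, pad
        )
        sig = set()
        for i, w in enumerate(tested):
            w.p_value = float(stats.gamma.sf(w.drc, shape, scale=scale))
            w.significant = w.p_value < thr
            if w.significant:
                sig.add(i)
        log.append(f"iteration {it}: shape={shape:.4g} scale={scale:.4g} significant={len(sig)}")
        if sig == prev_sig:
            return ScanResult(windows, shape, scale, alpha, thr, n_tested, it, log)
        extra_excluded = [
            (tested[i].chrom, tested[i].start_bp, tested[i].end_bp) for i in sig
        ]
        prev_sig = sig
    raise RuntimeError(
        "selection scan did not converge after "
        f"{max_iter} iterations; log: {'; '.join(log)}"
    )


def read_bed_regions(path) -> list[tuple[str, int, int]]:
    """Minimal BED reader: (chrom, start, end) per line, 0-based half-open."""
    out = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split()
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out
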