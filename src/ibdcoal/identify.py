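"""Hash-based identification of candidate IBD segments.

Haplotypes are hashed window by window into bins of identical allele
strings; over-full ("low complexity") bins are recursively diversified by
appending following windows until they are small enough or a recursion cap
is reached.  Pairs co-occurring in a bin are extended across contiguous
windows, tolerating a bounded number of consecutive non-matching windows
(phasing-error tolerance), and sufficiently long runs are emitted as
candidate segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .panel_io import HaplotypePanel

__all__ = [
    "IdentifyParams",
    "WindowHash",
    "CandidateSegment",
    "n_windows",
    "window_site_range",
    "hash_window",
    "diversify_bins",
    "matching_pairs",
    "find_candidates",
]


@dataclass(frozen=True)
class IdentifyParams:
    """Tuning knobs for the identification stage.

    ``word_size`` is the SNPs-per-window width (final partial window is
    hashed at its true width); ``max_bin_size`` is the low-complexity
    threshold triggering recursive diversification, capped at ``depth_cap``
    extra windows; ``max_gap_windows`` consecutive non-matching windows are
    tolerated inside a run; runs shorter than ``min_length_cM`` are dropped.
    """

    word_size: int = 32
    max_bin_size: int = 64
    max_gap_windows: int = 1
    min_length_cM: float = 1.0
    depth_cap: int = 4

    def __post_init__(self):
        if not 8 <= self.word_size <= 64:
            raise ValueError("word_size must be in [8, 64]")
        if self.min_length_cM <= 0:
            raise ValueError("min_length_cM must be positive")
        if self.max_bin_size < 1 or self.depth_cap < 0 or self.max_gap_windows < 0:
            raise ValueError("invalid identification parameters")


@dataclass
class WindowHash:
    """Hash bins for one window: binary word -> set of haplotype indices.

    After diversification a key may span several windows; ``depths[key]``
    records how many extra windows were appended and ``at_cap`` flags bins
    emitted over-full because the recursion depth cap was reached.
    """

    window_index: int
    bins: dict[bytes, frozenset[int]]
    depths: dict[bytes, int] = field(default_factory=dict)
    at_cap: set[bytes] = field(default_factory=set)

    @property
    def depth(self) -> int:
        return max(self.depths.values(), default=0)


@dataclass(frozen=True)
class CandidateSegment:
    """A putative IBD run for an (ordered) haplotype pair.

    Site range is half-open; window range is inclusive; ``length_cM`` spans
    the first to last site of the run.
    """

    hap_a: int
    hap_b: int
    start_window: int
    end_window: int
    start_site: int
    end_site: int
    n_mismatch_windows: int
    length_cM: float

    def sort_key(self):
        return (self.hap_a, self.hap_b, self.start_site)


def n_windows(n_sites: int, word_size: int) -> int:
    return math.ceil(n_sites / word_size)


def window_site_range(w: int, word_size: int, n_sites: int) -> tuple[int, int]:
    """Half-open site range of window *w* (final window may be partial)."""
    return w * word_size, min((w + 1) * word_size, n_sites)


def hash_window(panel: HaplotypePanel, window_index: int, word_size: int) -> WindowHash:
    """Hash every haplotype's allele string in one window into bins.

    Two haplotypes share a bin iff their alleles are identical across the
    window.
    """
    lo, hi = window_site_range(window_index, word_size, panel.n_sites)
    if lo >= panel.n_sites:
        raise ValueError(f"window {window_index} outside site range")
    bins: dict[bytes, set[int]] = {}
    words = panel.alleles[:, lo:hi]
    for h in range(panel.n_haplotypes):
        bins.setdefault(words[h].tobytes(), set()).add(h)
    return WindowHash(window_index, {k: frozenset(v) for k, v in bins.items()})


def _extend_key(panel, haps, w, word_size):
    lo, hi = window_site_range(w, word_size, panel.n_sites)
    return {h: panel.alleles[h, lo:hi].tobytes() for h in haps}


def diversify_bins(
    wh: WindowHash,
    max_bin_size: int,
    panel: HaplotypePanel,
    depth_cap: int,
    word_size: int,
) -> WindowHash:
    """Recursively split over-full bins on following windows.

    Every output bin is either at most ``max_bin_size`` haplotypes, or
    flagged in ``at_cap`` because no further windows were available or the
    recursion depth cap was hit.  Haplotypes in one output bin are identical
    over window ``w`` through ``w + depth``.
    """
    total_windows = n_windows(panel.n_sites, word_size)
    out_bins: dict[bytes, frozenset[int]] = {}
    depths: dict[bytes, int] = {}
    at_cap: set[bytes] = set()

    def emit(key, haps, depth, capped):
        out_bins[key] = frozenset(haps)
        depths[key] = depth
        if capped:
            at_cap.add(key)

    def split(key, haps, depth):
        if len(haps) <= max_bin_size:
            emit(key, haps, depth, False)
            return
        next_w = wh.window_index + depth + 1
        if depth >= depth_cap or next_w >= total_windows:
            emit(key, haps, depth, True)
            return
        ext = _extend_key(panel, haps, next_w, word_size)
        sub: dict[bytes, set[int]] = {}
        for h in haps:
            sub.setdefault(key + ext[h], set()).add(h)
        for k, v in sub.items():
            split(k, v, depth + 1)

    for key, haps in wh.bins.items():
        split(key, haps, wh.depths.get(key, 0))
    return WindowHash(wh.window_index, out_bins, depths, at_cap)


def matching_pairs(panel: HaplotypePanel, w: int, params: IdentifyParams) -> set[tuple[int, int]]:
    """Unordered haplotype pairs co-occurring in a (diversified) bin at *w*."""
    wh = diversify_bins(
        hash_window(panel, w, params.word_size),
        params.max_bin_size,
        panel,
        params.depth_cap,
        params.word_size,
    )
    pairs: set[tuple[int, int]] = set()
    for haps in wh.bins.values():
        hs = sorted(haps)
        for i in range(len(hs)):
            for j in range(i + 1, len(hs)):
                pairs.add((hs[i], hs[j]))
    return pairs


@dataclass
class _Run:
    start_window: int
    last_match: int
    n_mismatch: int = 0


def find_candidates(
    panel: HaplotypePanel, params: IdentifyParams | None = None
) -> list[CandidateSegment]:
    """Scan the panel window by window and emit candidate IBD runs.

    A candidate for pair (a, b) is a maximal run of windows in which the
    pair co-occurs in a hash bin, interrupted by at most
    ``max_gap_windows`` consecutive non-matching windows, of total genetic
    length at least ``min_length_cM``.  Output is sorted by
    (hap_a, hap_b, start_site) and deterministic.
    """
    params = params or IdentifyParams()
    total = n_windows(panel.n_sites, params.word_size)
    active: dict[tuple[int, int], _Run] = {}
    out: list[CandidateSegment] = []

    def close(pair, run):
        seg = _emit(panel, pair, run, params)
        if seg is not None:
            out.append(seg)

    for w in range(total):
        for pair in matching_pairs(panel, w, params):
            run = active.get(pair)
            if run is None:
                active[pair] = _Run(w, w)
            else:
                gap = w - run.last_match - 1
                if gap <= params.max_gap_windows:
                    run.n_mismatch += gap
                    run.last_match = w
                else:
                    close(pair, run)
                    active[pair] = _Run(w, w)
    for pair, run in active.items():
        close(pair, run)
    out.sort(key=CandidateSegment.sort_key)
    return out


def _emit(panel, pair, run, params) -> CandidateSegment | None:
    start_site, _ = window_site_range(run.start_window, params.word_size, panel.n_sites)
    _, end_site = window_site_range(run.last_match, params.word_size, panel.n_sites)
    length = float(panel.gen_pos[end_site - 1] - panel.gen_pos[start_site])
    if length < params.min_length_cM:
        return None
    a, b = pair
    return CandidateSegment(
        a, b, run.start_window, run.last_match, start_site, end_site, run.n_mismatch, length
    )
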