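"""Ground-truth simulation: SMC pair paths and a discrete-generation
backward Wright-Fisher coalescent with recombination, mutation dropping and
array-style site ascertainment.

The pair simulator draws an initial TMRCA from the pairwise coalescent
prior, then walks along the map: the distance to the next recombination is
exponential with rate ``2t`` per Morgan at the current TMRCA ``t``, and at
each breakpoint a new TMRCA is drawn from the same detach-and-re-coalesce
kernel used by the verification HMM.

The multi-sample simulator traces ancestral lineages backward one
generation at a time; crossovers are Poisson along each lineage's span
(rate 1 per Morgan per generation) and lineages landing on the same of
``Ne(g)`` haploid parents coalesce.  Mutations are dropped as Poisson
processes on the marginal trees, and per-pair TMRCA truth can be extracted
for any site or genomic interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .panel_io import DemographicModel, HaplotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "TruthPath",
    "SimulatedPanel",
    "simulate_pair_path",
    "simulate_panel",
    "ascertain_sites",
]


# ---------------------------------------------------------------------------
# Truth paths
# ---------------------------------------------------------------------------


@dataclass
class TruthPath:
    """Piecewise-constant TMRCA along the chromosome for one haplotype pair.

    ``breaks_cm`` has length m+1 (starting at 0, ending at the map length);
    ``tmrca`` holds the m per-interval TMRCA values in generations.
    """

    breaks_cm: np.ndarray
    tmrca: np.ndarray

    def __post_init__(self):
        self.breaks_cm = np.asarray(self.breaks_cm, dtype=float)
        self.tmrca = np.asarray(self.tmrca, dtype=float)
        if len(self.breaks_cm) != len(self.tmrca) + 1:
            raise ValueError("need one more breakpoint than TMRCA value")
        if np.any(np.diff(self.breaks_cm) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(self.tmrca <= 0):
            raise ValueError("TMRCA must be positive")

    @property
    def length_cm(self) -> float:
        return float(self.breaks_cm[-1] - self.breaks_cm[0])

    def tmrca_at(self, cm) -> np.ndarray:
        """TMRCA at genetic position(s) *cm* (right-open intervals)."""
        idx = np.searchsorted(self.breaks_cm, np.asarray(cm, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, len(self.tmrca) - 1)
        return self.tmrca[idx]

    def fraction_below(self, T: float) -> float:
        """Length fraction of the path with TMRCA <= T."""
        widths = np.diff(self.breaks_cm)
        return float(widths[self.tmrca <= T].sum() / widths.sum())

    def mean_tmrca(self, lo_cm: float, hi_cm: float) -> float:
        """Length-weighted mean TMRCA over [lo_cm, hi_cm]."""
        lo = np.clip(self.breaks_cm[:-1], lo_cm, hi_cm)
        hi = np.clip(self.breaks_cm[1:], lo_cm, hi_cm)
        w = hi - lo
        if w.sum() <= 0:
            return float(self.tmrca_at(0.5 * (lo_cm + hi_cm)))
        return float(np.sum(w * self.tmrca) / w.sum())


def _recoalesce(model: DemographicModel, t: float, rng: np.random.Generator) -> float:
    """Detach uniform on (0, t), re-coalesce at rate 1/Ne(s)."""
    u = rng.uniform(0.0, t)
    return float(model.inverse_hazard(model.cumulative_hazard(u) + rng.exponential()))


def simulate_pair_path(
    map_length_cM: float, model: DemographicModel, seed: int | np.random.Generator
) -> TruthPath:
    """Simulate one SMC TMRCA path along a map of ``map_length_cM``."""
    if map_length_cM <= 0:
        raise ValueError("map length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = map_length_cM / 100.0  # Morgans
    t = float(model.sample_tmrca(rng))
    x = 0.0
    breaks = [0.0]
    ts = [t]
    while True:
        x += rng.exponential(1.0 / (2.0 * t))
        if x >= L:
            break
        t_new = _recoalesce(model, t, rng)
        if t_new != t:
            breaks.append(x * 100.0)
            ts.append(t_new)
            t = t_new
    breaks.append(map_length_cM)
    return TruthPath(np.array(breaks), np.array(ts))


# ---------------------------------------------------------------------------
# Multi-sample backward Wright-Fisher simulation
# ---------------------------------------------------------------------------


class _Arg:
    """Per-interval coalescent forest produced by the DTWF simulation.

    Nodes are created lazily, one per overlapping piece at each merge; the
    marginal tree at a genomic point consists of the nodes whose creation
    interval contains it, linked by the recorded (binary) children.
    """

    def __init__(self, n_leaves: int, length_morgan: float):
        self.n = n_leaves
        self.L = length_morgan
        self.time: list[float] = [0.0] * n_leaves
        self.children: list[tuple[int, int] | None] = [None] * n_leaves
        # completed local roots: (left, right, node) in Morgans
        self.roots: list[tuple[float, float, int]] = []

    def new_node(self, t: float, c1: int, c2: int) -> int:
        self.time.append(t)
        self.children.append((c1, c2))
        return len(self.time) - 1

    # -- post-hoc queries ---------------------------------------------------

    def atomic_intervals(self) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints (Morgans) partitioning the genome into intervals with
        a constant marginal tree, plus the root node of each interval."""
        roots = sorted(self.roots)
        lefts = np.array([l for l, _, _ in roots])
        nodes = np.array([node for _, _, node in roots], dtype=np.int64)
        edges = np.unique(np.concatenate([[0.0, self.L], lefts, [r for _, r, _ in roots]]))
        mids = 0.5 * (edges[:-1] + edges[1:])
        idx = np.searchsorted(lefts, mids, side="right") - 1
        if np.any(idx < 0):  # pragma: no cover - simulation covers the genome
            raise RuntimeError("genome position not covered by a coalesced tree")
        return edges, nodes[idx]

    def _leaves_under(self, node: int) -> list[int]:
        stack, out = [node], []
        while stack:
            v = stack.pop()
            ch = self.children[v]
            if ch is None:
                out.append(v)
            else:
                stack.extend(ch)
        return out

    def pair_matrix(self, root: int, out: np.ndarray) -> None:
        """Fill ``out[a, b]`` with the TMRCA of every leaf pair under *root*."""

        def rec(v: int) -> list[int]:
            ch = self.children[v]
            if ch is None:
                return [v]
            left = rec(ch[0])
            right = rec(ch[1])
            t = self.time[v]
            out[np.ix_(left, right)] = t
            out[np.ix_(right, left)] = t
            left.extend(right)
            return left

        rec(root)

    def branch_table(self, root: int) -> list[tuple[float, list[int]]]:
        """(branch length, descendant leaves) for every non-root edge."""
        out: list[tuple[float, list[int]]] = []

        def rec(v: int) -> list[int]:
            ch = self.children[v]
            if ch is None:
                return [v]
            leaves = []
            for c in ch:
                sub = rec(c)
                out.append((self.time[v] - self.time[c], sub))
                leaves.extend(sub)
            return leaves

        rec(root)
        return out


def _split_segments(segments, points):
    """Split (l, r, node, count) segments at sorted crossover points and
    assign alternating chunks to two parental groups."""
    groups = ([], [])
    for l, r, node, cnt in segments:
        cur = l
        k = int(np.searchsorted(points, l, side="right"))
        while cur < r:
            nxt = points[k] if k < len(points) and points[k] < r else r
            groups[k % 2].append((cur, nxt, node, cnt))
            cur = nxt
            k += 1
    return [g for g in groups if g]


def _merge_lineages(a, b, g, arg: "_Arg"):
    """Coalesce two lineages' segment lists at generation *g*."""
    events = sorted(set([s[0] for s in a] + [s[1] for s in a] + [s[0] for s in b] + [s[1] for s in b]))
    def lookup(segs, lo, hi):
        for l, r, node, cnt in segs:
            if l <= lo and hi <= r:
                return node, cnt
        return None
    merged = []
    for lo, hi in zip(events[:-1], events[1:]):
        sa = lookup(a, lo, hi)
        sb = lookup(b, lo, hi)
        if sa and sb:
            node = arg.new_node(g, sa[0], sb[0])
            cnt = sa[1] + sb[1]
            if cnt == arg.n:
                arg.roots.append((lo, hi, node))
            else:
                merged.append((lo, hi, node, cnt))
        elif sa:
            merged.append((lo, hi, sa[0], sa[1]))
        elif sb:
            merged.append((lo, hi, sb[0], sb[1]))
    return _coalesce_adjacent(merged)


def _coalesce_adjacent(segs):
    """Re-join abutting pieces that carry the same node (keeps lists short)."""
    out = []
    for seg in segs:
        if out and out[-1][2] == seg[2] and out[-1][1] == seg[0]:
            out[-1] = (out[-1][0], seg[1], seg[2], seg[3])
        else:
            out.append(list(seg) if isinstance(seg, tuple) else seg)
            out[-1] = tuple(out[-1])
    return out


@dataclass
class SimulatedPanel:
    """A simulated haplotype panel with full pairwise TMRCA ground truth."""

    panel: HaplotypePanel
    arg: _Arg
    cm_per_mb: float
    params: dict = field(default_factory=dict)

    @property
    def region_cm(self) -> float:
        return self.arg.L * 100.0

    def site_truth_matrix(self, pairs: Sequence[tuple[int, int]] | None = None) -> np.ndarray:
        """True TMRCA at every panel site for the given haplotype pairs
        (default: all unordered pairs, in lexicographic order).

        Returns an (n_pairs, n_sites) float array.
        """
        n = self.arg.n
        if pairs is None:
            pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        ai = np.array([p[0] for p in pairs])
        bi = np.array([p[1] for p in pairs])
        edges, roots = self.arg.atomic_intervals()
        site_m = self.panel.gen_pos / 100.0  # Morgans (uniform rate)
        interval_of = np.clip(np.searchsorted(edges, site_m, side="right") - 1, 0, len(roots) - 1)
        out = np.empty((len(pairs), self.panel.n_sites), dtype=float)
        M = np.empty((n, n))
        for iv in np.unique(interval_of):
            self.arg.pair_matrix(roots[iv], M)
            cols = np.where(interval_of == iv)[0]
            out[:, cols] = M[ai, bi][:, None]
        return out

    def truth_paths(self, pairs: Sequence[tuple[int, int]]) -> dict[tuple[int, int], TruthPath]:
        """Exact piecewise TMRCA paths for the requested haplotype pairs."""
        n = self.arg.n
        edges, roots = self.arg.atomic_intervals()
        vals = np.empty((len(pairs), len(roots)))
        ai = np.array([p[0] for p in pairs])
        bi = np.array([p[1] for p in pairs])
        M = np.empty((n, n))
        for iv, root in enumerate(roots):
            self.arg.pair_matrix(root, M)
            vals[:, iv] = M[ai, bi]
        out = {}
        for i, pair in enumerate(pairs):
            # merge equal adjacent intervals for compactness
            keep = np.concatenate([[True], np.diff(vals[i]) != 0])
            breaks = np.concatenate([edges[:-1][keep], [edges[-1]]]) * 100.0
            out[pair] = TruthPath(breaks, vals[i][keep])
        return out

    def mean_fraction_below(self, T: float) -> float:
        """Mean over all pairs of the genome fraction with TMRCA <= T.

        Computed exactly from the truth trees: within each atomic interval
        the number of pairs coalescing by T is the sum of |left| x |right|
        over merge nodes no older than T.
        """
        n = self.arg.n
        n_pairs = n * (n - 1) // 2
        edges, roots = self.arg.atomic_intervals()
        widths = np.diff(edges)
        total = 0.0
        size_cache: dict[int, int] = {}

        def size(v: int) -> int:
            got = size_cache.get(v)
            if got is None:
                ch = self.arg.children[v]
                got = 1 if ch is None else size(ch[0]) + size(ch[1])
                size_cache[v] = got
            return got

        for iv, root in enumerate(roots):
            recent = 0
            stack = [root]
            while stack:
                v = stack.pop()
                ch = self.arg.children[v]
                if ch is None:
                    continue
                if self.arg.time[v] <= T:
                    recent += size(ch[0]) * size(ch[1])
                stack.extend(ch)
            total += widths[iv] * recent
        return total / (widths.sum() * n_pairs)

    def subset_sites(self, idx: np.ndarray) -> "SimulatedPanel":
        idx = np.sort(np.asarray(idx))
        p = self.panel
        sub = HaplotypePanel(
            p.individual_ids, p.chrom, p.phys_pos[idx], p.gen_pos[idx], p.alleles[:, idx]
        )
        return SimulatedPanel(sub, self.arg, self.cm_per_mb, dict(self.params))


def simulate_panel(
    n_haploids: int,
    region_cM: float,
    model: DemographicModel,
    mutation_rate: float = 1.25e-8,
    seed: int = 0,
    cm_per_mb: float = 1.0,
    budget: float = 4000.0,
) -> SimulatedPanel:
    """Backward DTWF simulation of *n_haploids* over *region_cM*.

    ``mutation_rate`` is per bp per generation; physical length follows the
    uniform ``cm_per_mb`` rate.  ``budget`` guards desk-scale use: the
    product ``n_haploids * region_cM`` may not exceed it.
    """
    if n_haploids < 2:
        raise ValueError("need at least two haploids")
    if n_haploids * region_cM > budget:
        raise ValueError(
            f"n_haploids * region_cM = {n_haploids * region_cM:g} exceeds the desk-scale "
            f"budget {budget:g}; use simulate_pair_path for large scenarios"
        )
    rng = np.random.default_rng(seed)
    L = region_cM / 100.0
    arg = _Arg(n_haploids, L)
    # lineage = list of (left, right, node, n_samples_subtended)
    lineages = [[(0.0, L, i, 1)] for i in range(n_haploids)]

    g = 0.0
    while lineages:
        g += 1.0
        ne = max(2, int(round(model.ne[model._epoch_index(g)])))
        # recombination: split each lineage at Poisson crossovers on its span
        offspring = []
        for segs in lineages:
            span_l, span_r = segs[0][0], segs[-1][1]
            n_x = rng.poisson(span_r - span_l)
            if n_x:
                points = np.sort(rng.uniform(span_l, span_r, size=n_x))
                offspring.extend(_split_segments(segs, points))
            else:
                offspring.append(segs)
        # parent assignment and coalescence
        parents = rng.integers(0, ne, size=len(offspring))
        by_parent: dict[int, list] = {}
        for segs, p in zip(offspring, parents):
            if p in by_parent:
                by_parent[p] = _merge_lineages(by_parent[p], segs, g, arg)
            else:
                by_parent[p] = segs
        lineages = [segs for segs in by_parent.values() if segs]

    # drop mutations on marginal trees
    bp_per_morgan = 1e8 / cm_per_mb
    edges, roots = arg.atomic_intervals()
    positions: list[int] = []
    carrier_sets: list[list[int]] = []
    for iv, root in enumerate(roots):
        lo_bp = edges[iv] * bp_per_morgan
        hi_bp = edges[iv + 1] * bp_per_morgan
        branches = arg.branch_table(root)
        lens = np.array([b[0] for b in branches])
        lam = mutation_rate * (hi_bp - lo_bp) * lens.sum()
        n_mut = rng.poisson(lam)
        if not n_mut:
            continue
        which = rng.choice(len(branches), size=n_mut, p=lens / lens.sum())
        pos = rng.integers(int(lo_bp) + 1, max(int(hi_bp), int(lo_bp) + 2), size=n_mut)
        for w, p in zip(which, pos):
            positions.append(int(p))
            carrier_sets.append(branches[w][1])

    order = np.argsort(positions, kind="stable")
    seen = set()
    phys, cols = [], []
    for k in order:
        p = positions[k]
        if p in seen:
            continue
        seen.add(p)
        col = np.zeros(n_haploids, dtype=np.uint8)
        col[carrier_sets[k]] = 1
        phys.append(p)
        cols.append(col)
    if not phys:
        logger.info("no polymorphic mutations generated; returning an empty panel")
    phys = np.array(phys, dtype=np.int64)
    alleles = (
        np.array(cols, dtype=np.uint8).T if cols else np.zeros((n_haploids, 0), np.uint8)
    )
    gen = (phys / 1e6) * cm_per_mb
    ids = [f"sim{i}" for i in range(math.ceil(n_haploids / 2))]
    if n_haploids % 2:  # keep diploid packaging: pad ids only, never alleles
        raise ValueError("n_haploids must be even to package as diploid individuals")
    panel = HaplotypePanel(ids, "1", phys, gen, alleles)
    params = dict(
        n_haploids=n_haploids,
        region_cM=region_cM,
        mutation_rate=mutation_rate,
        seed=seed,
        epochs=model.epochs,
    )
    return SimulatedPanel(panel, arg, cm_per_mb, params)


def ascertain_sites(
    sim: SimulatedPanel,
    target_density: float,
    target_spectrum: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
) -> SimulatedPanel:
    """Subsample sites to an array-like density and frequency spectrum.

    ``target_density`` is SNPs per cM.  ``target_spectrum`` is an optional
    (bin_edges, weights) histogram over derived allele frequency; each bin
    is filled proportionally to its weight as far as availability allows
    (shortfalls are logged).  Sampling is without replacement and seeded.
    """
    if target_density <= 0:
        raise ValueError("target_density must be positive")
    rng = np.random.default_rng(seed)
    n_target = int(round(target_density * sim.region_cm))
    freqs = sim.panel.derived_freq
    n_sites = sim.panel.n_sites
    if target_spectrum is None:
        if n_target >= n_sites:
            return sim.subset_sites(np.arange(n_sites))
        idx = rng.choice(n_sites, size=n_target, replace=False)
        return sim.subset_sites(idx)
    edges, weights = target_spectrum
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    chosen = []
    for b in range(len(weights)):
        in_bin = np.where((freqs >= edges[b]) & (freqs < edges[b + 1]))[0]
        want = int(round(n_target * weights[b]))
        if want > len(in_bin):
            logger.info(
                "ascertainment bin [%g, %g) has only %d of %d requested sites",
                edges[b], edges[b + 1], len(in_bin), want,
            )
            want = len(in_bin)
        if want:
            chosen.append(rng.choice(in_bin, size=want, replace=False))
    if not chosen:
        raise ValueError("no sites available in any requested frequency bin")
    return sim.subset_sites(np.concatenate(chosen))
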