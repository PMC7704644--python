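"""Domain types and I/O: haplotype panels, genetic maps, demographic models,
TMRCA discretizations, coalescent priors and parallel job partitioning.

Coordinate conventions
----------------------
Physical positions are 1-based inclusive (VCF convention); genetic positions
are in centimorgans; site indices are 0-based and ranges are half-open.
``Ne`` is defined such that a pair's instantaneous coalescence rate at time
``t`` is ``1/Ne(t)`` per generation, i.e. ``Ne`` is the mean pairwise
coalescence time under a constant model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SiteInfo",
    "HaplotypePanel",
    "GeneticMap",
    "DemographicModel",
    "TimeDiscretization",
    "read_haplotype_panel",
    "write_panel",
    "read_genetic_map",
    "read_demography",
    "write_demography",
    "read_discretization",
    "coalescent_prior",
    "make_quantile_discretization",
    "partition_jobs",
    "default_demography",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteInfo:
    """A single polymorphic site.

    Attributes
    ----------
    chrom : str
        Chromosome label.
    phys_pos : int
        1-based physical position in bp.
    gen_pos : float
        Genetic position in cM.
    derived_freq : float
        Derived/alternate allele frequency, strictly inside (0, 1).
    """

    chrom: str
    phys_pos: int
    gen_pos: float
    derived_freq: float


class HaplotypePanel:
    """Phased 0/1 haplotypes over an ordered set of biallelic sites.

    Parameters
    ----------
    individual_ids : sequence of str
        One id per diploid individual; haplotypes are ordered
        ``(ind0_hap0, ind0_hap1, ind1_hap0, ...)``.
    chrom : str
        Chromosome label (a panel spans a single chromosome).
    phys_pos, gen_pos : arrays
        Per-site physical (bp, strictly increasing) and genetic (cM,
        non-decreasing) coordinates.
    alleles : (n_haplotypes, n_sites) array of {0, 1}
        Phased allele matrix. Every column must be polymorphic.
    """

    def __init__(self, individual_ids, chrom, phys_pos, gen_pos, alleles):
        self.individual_ids = list(individual_ids)
        self.chrom = str(chrom)
        self.phys_pos = np.asarray(phys_pos, dtype=np.int64)
        self.gen_pos = np.asarray(gen_pos, dtype=float)
        self.alleles = np.ascontiguousarray(alleles, dtype=np.uint8)
        self._validate()

    def _validate(self):
        n_hap, n_sites = self.alleles.shape
        if n_hap != 2 * len(self.individual_ids):
            raise ValueError(
                f"allele matrix has {n_hap} rows but "
                f"{len(self.individual_ids)} individuals imply {2 * len(self.individual_ids)}"
            )
        if len(self.phys_pos) != n_sites or len(self.gen_pos) != n_sites:
            raise ValueError("coordinate arrays do not match site count")
        if n_sites:
            if np.any(np.diff(self.phys_pos) <= 0):
                raise ValueError("physical positions must be strictly increasing")
            if np.any(np.diff(self.gen_pos) < 0):
                raise ValueError("genetic positions must be non-decreasing")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        freq = self.alleles.mean(axis=0) if n_hap else np.array([])
        if n_sites and (np.any(freq <= 0.0) or np.any(freq >= 1.0)):
            bad = int(np.sum((freq <= 0) | (freq >= 1)))
            raise ValueError(f"{bad} monomorphic column(s) in allele matrix")

    # -- derived views ------------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def haplotype_ids(self) -> list[str]:
        return [f"{ind}_{h}" for ind in self.individual_ids for h in (0, 1)]

    @property
    def derived_freq(self) -> np.ndarray:
        return self.alleles.mean(axis=0)

    def site(self, i: int) -> SiteInfo:
        return SiteInfo(
            self.chrom,
            int(self.phys_pos[i]),
            float(self.gen_pos[i]),
            float(self.derived_freq[i]),
        )

    @property
    def sites(self) -> list[SiteInfo]:
        return [self.site(i) for i in range(self.n_sites)]

    def with_genetic_map(self, gmap: "GeneticMap") -> "HaplotypePanel":
        """Return a copy whose ``gen_pos`` is interpolated from *gmap*."""
        return HaplotypePanel(
            self.individual_ids,
            self.chrom,
            self.phys_pos,
            gmap.interp_cm(self.phys_pos),
            self.alleles,
        )

    def __eq__(self, other):
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.chrom == other.chrom
            and np.array_equal(self.phys_pos, other.phys_pos)
            and np.allclose(self.gen_pos, other.gen_pos)
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass(frozen=True)
class GeneticMap:
    """Piecewise-linear physical-to-genetic map.

    ``anchors`` are (phys_pos bp, gen_pos cM) pairs with non-decreasing
    gen_pos in phys_pos; interpolation between anchors is linear and values
    at anchors are reproduced exactly.
    """

    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self):
        bp = np.asarray(self.bp, dtype=float)
        cm = np.asarray(self.cm, dtype=float)
        if bp.ndim != 1 or bp.shape != cm.shape or len(bp) < 2:
            raise ValueError("map needs >= 2 (bp, cM) anchors")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("anchor bp must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("anchor cM must be non-decreasing")
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)

    @property
    def total_cM(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    def interp_cm(self, phys_pos) -> np.ndarray:
        return np.interp(np.asarray(phys_pos, dtype=float), self.bp, self.cm)

    def interp_bp(self, gen_pos) -> np.ndarray:
        return np.interp(np.asarray(gen_pos, dtype=float), self.cm, self.bp)

    @classmethod
    def uniform(cls, length_cm: float, cm_per_mb: float = 1.0) -> "GeneticMap":
        """Uniform-rate map of *length_cm*, starting at bp 1 / cM 0."""
        bp_len = length_cm / cm_per_mb * 1e6
        return cls(np.array([1.0, 1.0 + bp_len]), np.array([0.0, length_cm]))


class DemographicModel:
    """Piecewise-constant pairwise-coalescent effective size over time.

    ``epochs`` is a sequence of ``(start_generation, Ne)`` pairs with the
    first start at 0.  A pair coalesces at instantaneous rate ``1/Ne(t)``
    per generation, so the TMRCA survival function is
    ``S(t) = exp(-integral_0^t dt'/Ne(t'))``.
    """

    def __init__(self, epochs: Sequence[tuple[float, float]]):
        epochs = sorted((float(s), float(n)) for s, n in epochs)
        if not epochs or epochs[0][0] != 0.0:
            raise ValueError("first epoch must start at generation 0")
        starts = np.array([s for s, _ in epochs])
        ne = np.array([n for _, n in epochs])
        if np.any(np.diff(starts) <= 0):
            raise ValueError("epoch starts must be strictly increasing")
        if np.any(ne <= 0):
            raise ValueError("Ne must be positive in every epoch")
        self.starts = starts
        self.ne = ne
        # cumulative hazard at epoch starts
        rates = 1.0 / ne
        durations = np.diff(starts)
        self._H0 = np.concatenate([[0.0], np.cumsum(rates[:-1] * durations)])

    @property
    def epochs(self) -> list[tuple[float, float]]:
        return list(zip(self.starts.tolist(), self.ne.tolist()))

    def _epoch_index(self, t):
        return np.clip(np.searchsorted(self.starts, t, side="right") - 1, 0, len(self.starts) - 1)

    def rate(self, t) -> np.ndarray:
        """Instantaneous pairwise coalescence rate 1/Ne(t)."""
        return 1.0 / self.ne[self._epoch_index(t)]

    def cumulative_hazard(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        i = self._epoch_index(t)
        return self._H0[i] + (t - self.starts[i]) / self.ne[i]

    def survival(self, t) -> np.ndarray:
        """S(t) = P(TMRCA > t) for a pair sampled at present."""
        t = np.asarray(t, dtype=float)
        out = np.where(np.isinf(t), 0.0, np.exp(-self.cumulative_hazard(np.where(np.isinf(t), 0.0, t))))
        return out

    def density(self, t) -> np.ndarray:
        return self.rate(t) * self.survival(t)

    def inverse_hazard(self, h) -> np.ndarray:
        """Invert the cumulative hazard (used for quantiles and sampling)."""
        h = np.asarray(h, dtype=float)
        i = np.clip(np.searchsorted(self._H0, h, side="right") - 1, 0, len(self.starts) - 1)
        return self.starts[i] + (h - self._H0[i]) * self.ne[i]

    def quantile(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q >= 1)):
            raise ValueError("quantile levels must lie in [0, 1)")
        return self.inverse_hazard(-np.log1p(-q))

    def sample_tmrca(self, rng: np.random.Generator, size=None) -> np.ndarray:
        return self.inverse_hazard(rng.exponential(size=size))

    def exp_hazard_integral(self, t) -> np.ndarray:
        """W(t) = integral_0^t exp(H(u)) du, piecewise closed form."""
        t = np.asarray(t, dtype=float)
        # cumulative W at epoch starts
        if not hasattr(self, "_W0"):
            w0 = [0.0]
            for j in range(len(self.starts) - 1):
                lam = 1.0 / self.ne[j]
                dur = self.starts[j + 1] - self.starts[j]
                w0.append(w0[-1] + math.exp(self._H0[j]) * math.expm1(lam * dur) / lam)
            self._W0 = np.array(w0)
        i = self._epoch_index(t)
        lam = 1.0 / self.ne[i]
        return self._W0[i] + np.exp(self._H0[i]) * np.expm1(lam * (t - self.starts[i])) / lam

    def interval_mass_and_mean(self, lo: float, hi: float) -> tuple[float, float]:
        """Probability mass and conditional mean of TMRCA on [lo, hi).

        Both are computed in closed form within constant epochs; ``hi`` may
        be ``inf``.
        """
        if not (0 <= lo < hi):
            raise ValueError("need 0 <= lo < hi")
        mass = float(self.survival(lo) - self.survival(hi))
        if mass <= 0:
            return 0.0, 0.5 * (lo + hi) if np.isfinite(hi) else lo
        # sum int t f(t) dt over epoch pieces:
        # within an epoch with rate lam, int_u^v t lam S(t) dt
        #   = S(u)(u + 1/lam) - S(v)(v + 1/lam)
        cut = self.starts[(self.starts > lo) & (self.starts < hi)]
        edges = np.concatenate([[lo], cut, [hi]])
        total = 0.0
        for u, v in zip(edges[:-1], edges[1:]):
            lam = float(self.rate(u))
            su = float(self.survival(u))
            if np.isinf(v):
                total += su * (u + 1.0 / lam)
            else:
                sv = float(self.survival(v))
                total += su * (u + 1.0 / lam) - sv * (v + 1.0 / lam)
        return mass, total / mass

    def upper_time_bound(self, tail: float = 1e-14) -> float:
        """A finite time with survival below *tail* (for quadrature cutoffs)."""
        return float(self.inverse_hazard(-math.log(tail)))


@dataclass
class TimeDiscretization:
    """Increasing TMRCA interval boundaries ``t_0=0 < ... < t_K=inf`` plus
    per-interval prior probabilities and representative (conditional mean)
    times under a demographic model."""

    boundaries: np.ndarray
    probabilities: np.ndarray
    representatives: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b[0] != 0.0 or not np.isinf(b[-1]) or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must satisfy 0 = t_0 < ... < t_K = inf")
        p = np.asarray(self.probabilities, dtype=float)
        r = np.asarray(self.representatives, dtype=float)
        if len(p) != len(b) - 1 or len(r) != len(b) - 1:
            raise ValueError("need one probability and representative per interval")
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < -1e-15):
            raise ValueError("interval probabilities must be non-negative and sum to 1")
        if np.any(r < b[:-1]) or np.any(r[:-1] > b[1:-1]):
            raise ValueError("representatives must lie inside their intervals")
        self.boundaries, self.probabilities, self.representatives = b, p, r

    @property
    def n_intervals(self) -> int:
        return len(self.probabilities)

    def index_of_boundary(self, t: float, atol: float = 1e-9) -> int:
        """Index k such that boundaries[k] == t (within atol)."""
        k = int(np.argmin(np.abs(self.boundaries - t)))
        if abs(self.boundaries[k] - t) > atol:
            raise ValueError(f"{t} is not a discretization boundary")
        return k

    def mass_below(self, t: float) -> float:
        """Exact prior mass below boundary *t*."""
        return float(self.probabilities[: self.index_of_boundary(t)].sum())


# ---------------------------------------------------------------------------
# Coalescent prior and discretization
# ---------------------------------------------------------------------------


def coalescent_prior(
    model: DemographicModel, boundaries: Iterable[float]
) -> TimeDiscretization:
    """Interval prior probabilities and conditional-mean representatives.

    ``pi_k = S(t_k) - S(t_{k+1})`` and the representative of interval k is
    ``E[t | t in [t_k, t_{k+1})]`` under the pairwise coalescent of *model*,
    both in closed form within constant epochs.
    """
    b = np.asarray(list(boundaries), dtype=float)
    if b[0] != 0.0 or not np.isinf(b[-1]) or np.any(np.diff(b) <= 0):
        raise ValueError("boundaries must satisfy 0 = t_0 < ... < t_K = inf")
    probs, reps = [], []
    for lo, hi in zip(b[:-1], b[1:]):
        mass, mean = model.interval_mass_and_mean(float(lo), float(hi))
        probs.append(mass)
        reps.append(mean)
    probs = np.array(probs)
    probs /= probs.sum()
    return TimeDiscretization(b, probs, np.array(reps))


def make_quantile_discretization(
    model: DemographicModel, K: int, pinned: Iterable[float] | None = None
) -> TimeDiscretization:
    """K prior-quantile intervals, with *pinned* generation values (e.g. the
    IBD time threshold T) inserted verbatim as extra boundaries."""
    if K < 2:
        raise ValueError("need K >= 2 intervals")
    qs = np.arange(1, K) / K
    b = list(model.quantile(qs))
    for t in pinned or ():
        t = float(t)
        if t <= 0:
            raise ValueError("pinned boundaries must be positive")
        if not any(math.isclose(t, x, rel_tol=1e-12) for x in b):
            b.append(t)
    boundaries = np.concatenate([[0.0], np.sort(b), [np.inf]])
    return coalescent_prior(model, boundaries)


def partition_jobs(n_samples: int, K: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split all unordered sample pairs into K jobs of set-pairs.

    Samples are divided into S nearly equal disjoint sets where
    ``K = S(S+1)/2``; each job is a set-pair {i, j} with i <= j, covering
    within-set pairs when i == j and cross-set pairs otherwise.  Every
    unordered sample pair is covered by exactly one job.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    s = (-1 + math.isqrt(1 + 8 * K)) // 2
    if s * (s + 1) // 2 != K:
        lower = s * (s + 1) // 2
        upper = (s + 1) * (s + 2) // 2
        raise ValueError(
            f"K={K} is not of the form S(S+1)/2; nearest valid values are {lower} and {upper}"
        )
    sets = np.array_split(np.arange(n_samples), s)
    return [(sets[i], sets[j]) for i in range(s) for j in range(i, s)]


def default_demography() -> DemographicModel:
    """Bundled two-epoch European-like model (recent Ne 5,000; ancient 10,000)."""
    return DemographicModel([(0.0, 5000.0), (300.0, 10000.0)])


# ---------------------------------------------------------------------------
# File readers / writers
# ---------------------------------------------------------------------------


def _finalize_panel(individual_ids, chrom, phys, cols, fmt_hint):
    alleles = np.array(cols, dtype=np.uint8).T if cols else np.zeros((2 * len(individual_ids), 0), np.uint8)
    phys = np.asarray(phys, dtype=np.int64)
    freq = alleles.mean(axis=0)
    keep = (freq > 0.0) & (freq < 1.0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d monomorphic site(s) while reading %s input", dropped, fmt_hint)
    phys = phys[keep]
    alleles = alleles[:, keep]
    gen = (phys - phys[0]) / 1e6 if len(phys) else np.array([])  # 1 cM/Mb placeholder
    return HaplotypePanel(individual_ids, chrom, phys, gen, alleles)


def _read_vcf(path: Path) -> HaplotypePanel:
    import pysam

    vf = pysam.VariantFile(str(path))
    individual_ids = list(vf.header.samples)
    chrom = None
    phys, cols = [], []
    for rec in vf:
        if chrom is None:
            chrom = rec.chrom
        elif rec.chrom != chrom:
            raise ValueError(f"panel spans multiple chromosomes ({chrom}, {rec.chrom})")
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"record {rec.chrom}:{rec.pos} is not biallelic")
        col = []
        for sample in individual_ids:
            call = rec.samples[sample]
            gt = call["GT"]
            if gt is None or any(a is None for a in gt):
                raise ValueError(f"missing genotype at {rec.chrom}:{rec.pos} for {sample}")
            if len(gt) != 2:
                raise ValueError(f"non-diploid genotype at {rec.chrom}:{rec.pos} for {sample}")
            if not call.phased:
                raise ValueError(
                    f"unphased genotype at {rec.chrom}:{rec.pos} for {sample}: phased data required"
                )
            col.extend(int(a) for a in gt)
        phys.append(rec.pos)
        cols.append(col)
    if chrom is None:
        raise ValueError(f"no records in {path}")
    return _finalize_panel(individual_ids, chrom, phys, cols, "VCF")


def _read_hapssample(path: Path) -> HaplotypePanel:
    """Oxford haps/sample pair; *path* names the .haps file."""
    haps = Path(path)
    sample = haps.with_suffix(".sample")
    ids = []
    with open(sample) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    # two header lines (names + types) per Oxford convention
    for row in lines[2:]:
        ids.append(row[1] if len(row) > 1 else row[0])
    chrom = None
    phys, cols = [], []
    with open(haps) as fh:
        for ln in fh:
            parts = ln.split()
            if not parts:
                continue
            if chrom is None:
                chrom = parts[0]
            elif parts[0] != chrom:
                raise ValueError("panel spans multiple chromosomes")
            alleles = parts[5:]
            if len(alleles) != 2 * len(ids):
                raise ValueError(
                    f"haps record at {parts[2]} has {len(alleles)} alleles, expected {2 * len(ids)}"
                )
            if any(a not in ("0", "1") for a in alleles):
                raise ValueError(f"missing or non-binary allele in haps record at {parts[2]}")
            phys.append(int(parts[2]))
            cols.append([int(a) for a in alleles])
    if chrom is None:
        raise ValueError(f"no records in {path}")
    return _finalize_panel(ids, chrom, phys, cols, "haps/sample")


def read_haplotype_panel(path, format: str = "vcf") -> HaplotypePanel:
    """Read a phased panel from a VCF ('vcf') or Oxford haps/sample
    ('hapssample') file.  Monomorphic sites are dropped (logged); unphased,
    multiallelic or missing genotypes raise ``ValueError``."""
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "hapssample":
        return _read_hapssample(path)
    raise ValueError(f"unknown panel format {format!r}")


def write_panel(panel: HaplotypePanel, path, format: str = "vcf") -> None:
    """Write *panel* to disk in VCF or haps/sample form."""
    path = Path(path)
    if format == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={panel.chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(panel.individual_ids)
                + "\n"
            )
            for j in range(panel.n_sites):
                gts = "\t".join(
                    f"{panel.alleles[2 * i, j]}|{panel.alleles[2 * i + 1, j]}"
                    for i in range(len(panel.individual_ids))
                )
                fh.write(
                    f"{panel.chrom}\t{panel.phys_pos[j]}\tsite{j}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
                )
    elif format == "hapssample":
        with open(path, "w") as fh:
            for j in range(panel.n_sites):
                alleles = " ".join(str(a) for a in panel.alleles[:, j])
                fh.write(f"{panel.chrom} site{j} {panel.phys_pos[j]} A G {alleles}\n")
        with open(Path(path).with_suffix(".sample"), "w") as fh:
            fh.write("ID_1 ID_2 missing\n0 0 0\n")
            for ind in panel.individual_ids:
                fh.write(f"{ind} {ind} 0\n")
    else:
        raise ValueError(f"unknown panel format {format!r}")


def read_genetic_map(path, format: str = "auto") -> GeneticMap:
    """Read a PLINK-style (chrom, id, cM, bp) or HapMap-style (pos, rate,
    cM) genetic map.  ``format='auto'`` sniffs the column layout."""
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if ln and not ln.startswith("#"):
                rows.append(ln.split())
    if not rows:
        raise ValueError(f"empty genetic map file {path}")
    if format == "auto":
        # HapMap files start with a header line and have 3 columns
        try:
            float(rows[0][0])
            format = "plink" if len(rows[0]) == 4 else "hapmap"
        except ValueError:
            rows = rows[1:]
            format = "hapmap" if len(rows[0]) == 3 else "plink"
    if format == "plink":
        bp = [float(r[3]) for r in rows]
        cm = [float(r[2]) for r in rows]
    elif format == "hapmap":
        bp = [float(r[0]) for r in rows]
        cm = [float(r[2]) for r in rows]
    else:
        raise ValueError(f"unknown map format {format!r}")
    return GeneticMap(np.array(bp), np.array(cm))


def read_demography(path) -> DemographicModel:
    """Two-column whitespace file: generation_start, Ne; '#' comments."""
    epochs = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#", 1)[0].strip()
            if ln:
                s, n = ln.split()[:2]
                epochs.append((float(s), float(n)))
    if not epochs:
        raise ValueError(f"no epochs in demography file {path}")
    return DemographicModel(epochs)


def write_demography(model: DemographicModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("# generation_start Ne  (Ne = mean pairwise coalescence time)\n")
        for s, n in model.epochs:
            fh.write(f"{s:g} {n:g}\n")


def read_discretization(path, model: DemographicModel) -> TimeDiscretization:
    """One boundary per line; 0 and inf are added if absent."""
    vals = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#", 1)[0].strip()
            if ln:
                vals.append(float(ln))
    b = sorted(set(vals) | {0.0, np.inf})
    return coalescent_prior(model, b)
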