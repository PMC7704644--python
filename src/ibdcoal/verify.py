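"""Coalescent-HMM verification of candidate IBD segments.

Hidden states are discretized TMRCA intervals.  Transitions along the
genome follow an SMC-class kernel: recombination occurs at rate ``2t`` per
Morgan at TMRCA ``t``, the detaching lineage leaves from a point uniform on
``(0, t)`` and re-coalesces at rate ``1/Ne(s)``.  The kernel is integrated
against the coalescent prior into an interval-to-interval generator, whose
matrix exponential gives distance-d transition matrices; the prior is an
exact stationary distribution of this construction.

Emissions use a frequency-binned calibrated discordance curve
``P(discordant | t) = 1 - exp(-2 mu_b t)`` with one effective rate ``mu_b``
per allele-frequency bin, solved so the prior-expected discordance matches
the discordance observed in the panel.

Each candidate segment is decoded by forward-backward; sites where the
posterior mass below the time threshold T exceeds its prior are kept,
yielding trimmed IBD segments with a quality score (mean posterior mass
below T) and a MAP age estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

from .identify import CandidateSegment, IdentifyParams, find_candidates
from .panel_io import (
    DemographicModel,
    HaplotypePanel,
    TimeDiscretization,
    make_quantile_discretization,
)

__all__ = [
    "VerifyParams",
    "PairObservation",
    "PosteriorMatrix",
    "IBDSegment",
    "smc_rate_matrix",
    "transition_matrix",
    "EmissionModel",
    "calibrate_emission",
    "emission_probs",
    "decode_posterior",
    "refine_segment",
    "detect",
    "write_ibd_file",
    "read_ibd_file",
]


# ---------------------------------------------------------------------------
# Transition model
# ---------------------------------------------------------------------------


def _gauss_nodes(model: DemographicModel, lo: float, hi: float, order: int = 24):
    """Gauss-Legendre nodes/weights on [lo, hi], subdivided at epoch starts."""
    cuts = model.starts[(model.starts > lo) & (model.starts < hi)]
    edges = np.concatenate([[lo], cuts, [hi]])
    x0, w0 = leggauss(order)
    nodes, weights = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        nodes.append(0.5 * (b - a) * x0 + 0.5 * (a + b))
        weights.append(0.5 * (b - a) * w0)
    return np.concatenate(nodes), np.concatenate(weights)


def smc_rate_matrix(disc: TimeDiscretization, model: DemographicModel) -> np.ndarray:
    """Interval-to-interval SMC jump generator (rates per Morgan).

    ``R[k, l]`` for ``k != l`` is the prior-averaged rate of jumping from
    interval k to interval l; diagonal entries make rows sum to zero.  The
    prior satisfies ``pi @ R = 0`` up to quadrature error, so ``pi`` is
    stationary under ``expm(R d)`` for every distance d.
    """
    K = disc.n_intervals
    b = disc.boundaries.copy()
    t_max = model.upper_time_bound()
    b[-1] = max(t_max, b[-2] * 1.5 if np.isfinite(b[-2]) and b[-2] > 0 else t_max)
    pi = disc.probabilities

    f = model.density
    W = model.exp_hazard_integral
    S = model.survival

    # G_l = int_{I_l} f(t) W(t) dt  (closed form: t - W(t) S(t) evaluated at ends)
    G = np.empty(K)
    for l in range(K):
        lo, hi = b[l], b[l + 1]
        G[l] = (hi - W(hi) * S(hi)) - (lo - W(lo) * S(lo))

    A = np.zeros((K, K))
    for k in range(K):
        for l in range(K):
            if k < l:
                A[k, l] = 2.0 * pi[l] * G[k]
            elif k > l:
                A[k, l] = 2.0 * pi[k] * G[l]
        # diagonal: 2 * int_{I_k} f(t) [ int_{a}^{t} fW dt' + W(t)(S(t)-S(b_k)) ] dt
        lo, hi = b[k], b[k + 1]
        t, wt = _gauss_nodes(model, lo, hi)
        partial = (t - W(t) * S(t)) - (lo - W(lo) * S(lo))  # int_lo^t f W
        inner = partial + W(t) * (S(t) - S(hi))
        A[k, k] = 2.0 * np.sum(wt * f(t) * inner)

    R = A / pi[:, None]
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=1))
    return R


class TransitionModel:
    """Caches the eigendecomposition of the SMC generator so that
    per-distance transition matrices are cheap."""

    def __init__(self, disc: TimeDiscretization, model: DemographicModel):
        self.disc = disc
        self.model = model
        self.R = smc_rate_matrix(disc, model)
        evals, evecs = np.linalg.eig(self.R)
        self._evals = evals
        self._evecs = evecs
        self._evecs_inv = np.linalg.inv(evecs)
        # fall back to expm if the eigenbasis is poorly conditioned
        self._use_eig = np.linalg.cond(evecs) < 1e8

    def __call__(self, d_cM: float) -> np.ndarray:
        if d_cM < 0:
            raise ValueError("genetic distance must be non-negative")
        if d_cM == 0:
            return np.eye(self.disc.n_intervals)
        d_morgan = d_cM / 100.0
        if self._use_eig:
            P = (self._evecs * np.exp(self._evals * d_morgan)) @ self._evecs_inv
            P = np.real(P)
        else:  # pragma: no cover - degenerate numerics
            from scipy.linalg import expm

            P = expm(self.R * d_morgan)
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_matrix(
    d_cM: float, disc: TimeDiscretization, model: DemographicModel
) -> np.ndarray:
    """Distance-``d_cM`` stochastic transition matrix over TMRCA intervals."""
    return TransitionModel(disc, model)(d_cM)


# ---------------------------------------------------------------------------
# Emission model
# ---------------------------------------------------------------------------


@dataclass
class EmissionModel:
    """Frequency-binned discordance curve ``P(disc | t) = 1 - exp(-2 mu_b t)``."""

    freq_edges: np.ndarray  # len n_bins + 1, covering (0, 1)
    mu: np.ndarray  # len n_bins

    def bin_index(self, freq) -> np.ndarray:
        idx = np.searchsorted(self.freq_edges, np.asarray(freq, dtype=float), side="right") - 1
        return np.clip(idx, 0, len(self.mu) - 1)

    def p_discordant(self, freq, t) -> np.ndarray:
        mu = self.mu[self.bin_index(freq)]
        return -np.expm1(-2.0 * np.multiply.outer(mu, t))


def emission_probs(
    concordant: bool, derived_freq: float, t: float, emodel: EmissionModel
) -> float:
    """P(observation | TMRCA t) for one site."""
    if emodel is None:
        raise ValueError("emission model not calibrated")
    p_disc = float(emodel.p_discordant(derived_freq, t))
    return 1.0 - p_disc if concordant else p_disc


def _solve_mu(p_hat: float, reps: np.ndarray, pi: np.ndarray) -> float:
    if p_hat <= 0:
        return 0.0
    if p_hat >= 1.0:
        raise ValueError(
            f"observed discordance {p_hat} is not achievable under the emission model"
        )

    def g(mu):
        return float(np.sum(pi * -np.expm1(-2.0 * mu * reps))) - p_hat

    hi = 1.0
    while g(hi) < 0:
        hi *= 4.0
        if hi > 1e12:  # pragma: no cover
            raise ValueError("emission calibration failed to bracket a root")
    return brentq(g, 0.0, hi, rtol=1e-10)


def calibrate_emission(
    panel: HaplotypePanel,
    disc: TimeDiscretization,
    model: DemographicModel,
    n_freq_bins: int = 5,
    max_pairs: int = 200,
    seed: int = 0,
) -> EmissionModel:
    """Solve one effective mutation rate per allele-frequency bin.

    ``mu_b`` satisfies ``E_pi[1 - exp(-2 mu_b t)] = p_hat_b`` where
    ``p_hat_b`` is the mean pairwise allele discordance observed in bin b
    over a seeded random subsample of haplotype pairs, and the expectation
    runs over the discretization's interval representatives.
    """
    freqs = panel.derived_freq
    if len(freqs) == 0:
        raise ValueError("empty panel")
    qs = np.linspace(0, 1, n_freq_bins + 1)
    edges = np.quantile(freqs, qs)
    edges[0], edges[-1] = 0.0, 1.0
    edges = np.maximum.accumulate(edges)
    emodel = EmissionModel(edges, np.zeros(n_freq_bins))
    bin_idx = emodel.bin_index(freqs)
    for b in range(n_freq_bins):
        if not np.any(bin_idx == b):
            raise ValueError(f"frequency bin {b} contains no sites")

    rng = np.random.default_rng(seed)
    n = panel.n_haplotypes
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(all_pairs) > max_pairs:
        chosen = rng.choice(len(all_pairs), size=max_pairs, replace=False)
        pairs = [all_pairs[i] for i in chosen]
    else:
        pairs = all_pairs

    disc_sum = np.zeros(n_freq_bins)
    disc_count = np.zeros(n_freq_bins)
    for a, bb in pairs:
        mism = panel.alleles[a] != panel.alleles[bb]
        disc_sum += np.bincount(bin_idx, weights=mism, minlength=n_freq_bins)
        disc_count += np.bincount(bin_idx, minlength=n_freq_bins)
    p_hat = disc_sum / disc_count
    mu = np.array(
        [_solve_mu(p, disc.representatives, disc.probabilities) for p in p_hat]
    )
    return EmissionModel(edges, mu)


# ---------------------------------------------------------------------------
# Posterior decoding
# ---------------------------------------------------------------------------


@dataclass
class PairObservation:
    """Per-site concordance indicators and allele frequencies for one pair."""

    concordant: np.ndarray  # bool, length n_sites
    derived_freq: np.ndarray

    def __post_init__(self):
        self.concordant = np.asarray(self.concordant, dtype=bool)
        self.derived_freq = np.asarray(self.derived_freq, dtype=float)
        if self.concordant.shape != self.derived_freq.shape:
            raise ValueError("concordance and frequency arrays must align")


@dataclass
class PosteriorMatrix:
    """Forward-backward output: per-site distribution over TMRCA intervals."""

    posterior: np.ndarray  # (n_sites, K), rows sum to 1
    map_index: np.ndarray  # per-site argmax, ties toward most recent interval
    disc: TimeDiscretization

    def mass_below(self, T: float) -> np.ndarray:
        """Per-site posterior mass in intervals entirely below boundary T."""
        k = self.disc.index_of_boundary(T)
        return self.posterior[:, :k].sum(axis=1)


def decode_posterior(
    obs: PairObservation,
    disc: TimeDiscretization,
    model: DemographicModel,
    emodel: EmissionModel,
    gen_pos: np.ndarray,
    trans: TransitionModel | None = None,
) -> PosteriorMatrix:
    """Scaled forward-backward posterior over TMRCA intervals.

    ``gen_pos`` gives the decoded sites' genetic positions (cM); inter-site
    transition matrices come from the SMC generator.
    """
    n = len(obs.concordant)
    if n < 1:
        raise ValueError("observation must cover at least one site")
    if trans is None:
        trans = TransitionModel(disc, model)
    reps = disc.representatives
    pi = disc.probabilities
    p_disc = emodel.p_discordant(obs.derived_freq, reps)  # (n, K)
    emit = np.where(obs.concordant[:, None], 1.0 - p_disc, p_disc)

    alpha = np.empty((n, len(pi)))
    scale = np.empty(n)
    a = pi * emit[0]
    scale[0] = a.sum()
    if scale[0] <= 0:
        raise ValueError("zero likelihood at first site")
    alpha[0] = a / scale[0]
    mats = []
    for s in range(1, n):
        P = trans(float(gen_pos[s] - gen_pos[s - 1]))
        mats.append(P)
        a = (alpha[s - 1] @ P) * emit[s]
        scale[s] = a.sum()
        if scale[s] <= 0:
            raise ValueError(f"zero likelihood at site {s}")
        alpha[s] = a / scale[s]

    beta = np.empty_like(alpha)
    beta[-1] = 1.0
    for s in range(n - 2, -1, -1):
        beta[s] = (mats[s] @ (emit[s + 1] * beta[s + 1])) / scale[s + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    map_index = np.argmax(post, axis=1)  # argmax returns the first (most recent) max
    return PosteriorMatrix(post, map_index, disc)


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IBDSegment:
    """A verified IBD segment with quality score and MAP age estimate."""

    hap_a: int
    hap_b: int
    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    start_site: int
    end_site: int
    length_cM: float
    score: float
    age_est: float
    n_mismatch_windows: int

    @property
    def ind_a(self) -> int:
        return self.hap_a // 2

    @property
    def ind_b(self) -> int:
        return self.hap_b // 2


def refine_segment(
    candidate: CandidateSegment,
    post: PosteriorMatrix,
    T: float,
    panel: HaplotypePanel,
    min_output_cM: float = 0.0,
) -> list[IBDSegment]:
    """Posterior-vs-prior trimming of a candidate into IBD segments.

    Maximal runs of sites whose posterior mass below T strictly exceeds the
    prior mass below T each become one segment; the score is the mean mass
    over the run and the age estimate the mean MAP representative.  T must
    be a discretization boundary so the mass is an exact partial sum.
    """
    prior_mass = post.disc.mass_below(T)
    mass = post.mass_below(T)
    n = len(mass)
    if n != candidate.end_site - candidate.start_site:
        raise ValueError("posterior does not cover the candidate's site range")
    keep = mass > prior_mass
    reps = post.disc.representatives
    out = []
    s = 0
    while s < n:
        if not keep[s]:
            s += 1
            continue
        e = s
        while e < n and keep[e]:
            e += 1
        lo = candidate.start_site + s
        hi = candidate.start_site + e  # half-open
        length = float(panel.gen_pos[hi - 1] - panel.gen_pos[lo])
        if length >= min_output_cM:
            out.append(
                IBDSegment(
                    candidate.hap_a,
                    candidate.hap_b,
                    panel.chrom,
                    int(panel.phys_pos[lo]),
                    int(panel.phys_pos[hi - 1]),
                    float(panel.gen_pos[lo]),
                    float(panel.gen_pos[hi - 1]),
                    lo,
                    hi,
                    length,
                    float(mass[s:e].mean()),
                    float(reps[post.map_index[s:e]].mean()),
                    candidate.n_mismatch_windows,
                )
            )
        s = e
    return out


# ---------------------------------------------------------------------------
# End-to-end detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VerifyParams:
    """Verification-stage parameters (see module docstring)."""

    time_threshold: float = 50.0
    n_intervals: int = 30
    min_output_cM: float | None = None  # default: identify min_length_cM / 2
    n_freq_bins: int = 5
    calibration_pairs: int = 200
    calibration_seed: int = 0


def detect(
    panel: HaplotypePanel,
    model: DemographicModel,
    identify_params: IdentifyParams | None = None,
    verify_params: VerifyParams | None = None,
    disc: TimeDiscretization | None = None,
    candidates: Sequence[CandidateSegment] | None = None,
) -> list[IBDSegment]:
    """Run identification then HMM verification over a panel.

    Returns verified IBD segments, deterministically sorted.  A
    pre-computed discretization or candidate list may be supplied (the
    discretization must pin the time threshold as a boundary).
    """
    ip = identify_params or IdentifyParams()
    vp = verify_params or VerifyParams()
    if disc is None:
        disc = make_quantile_discretization(
            model, vp.n_intervals, pinned=[vp.time_threshold]
        )
    min_out = vp.min_output_cM if vp.min_output_cM is not None else ip.min_length_cM / 2.0
    if candidates is None:
        candidates = find_candidates(panel, ip)
    emodel = calibrate_emission(
        panel, disc, model, vp.n_freq_bins, vp.calibration_pairs, vp.calibration_seed
    )
    trans = TransitionModel(disc, model)
    out: list[IBDSegment] = []
    for cand in candidates:
        sl = slice(cand.start_site, cand.end_site)
        obs = PairObservation(
            panel.alleles[cand.hap_a, sl] == panel.alleles[cand.hap_b, sl],
            panel.derived_freq[sl],
        )
        post = decode_posterior(obs, disc, model, emodel, panel.gen_pos[sl], trans)
        out.extend(refine_segment(cand, post, vp.time_threshold, panel, min_out))
    out.sort(key=lambda s: (s.hap_a, s.hap_b, s.start_site))
    return out


# ---------------------------------------------------------------------------
# IBD file format
# ---------------------------------------------------------------------------

IBD_COLUMNS = [
    "ind_a",
    "hap_a",
    "ind_b",
    "hap_b",
    "chrom",
    "start_bp",
    "end_bp",
    "length_cM",
    "score",
    "age_est",
    "n_mismatch_windows",
]


def write_ibd_file(
    segments: Sequence[IBDSegment], path, individual_ids: Sequence[str] | None = None
) -> None:
    """TSV with fixed float formatting (score 4 dp, age 2 dp).

    ``individual_ids`` maps internal individual indices to panel sample
    names; without it the integer indices are written.
    """

    def ind(i):
        return individual_ids[i] if individual_ids is not None else i

    with open(path, "w") as fh:
        fh.write("\t".join(IBD_COLUMNS) + "\n")
        for s in segments:
            fh.write(
                f"{ind(s.ind_a)}\t{s.hap_a}\t{ind(s.ind_b)}\t{s.hap_b}\t{s.chrom}\t"
                f"{s.start_bp}\t{s.end_bp}\t{s.length_cM:.6f}\t"
                f"{s.score:.4f}\t{s.age_est:.2f}\t{s.n_mismatch_windows}\n"
            )


def read_ibd_file(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
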