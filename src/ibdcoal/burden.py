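"""LoF-segment burden association testing.

For a gene with known sequenced loss-of-function carriers, any IBD segment
linking a carrier to a non-sequenced individual and overlapping the gene is
a LoF-segment; a non-sequenced individual's burden is the sum of the
quality scores of their LoF-segments.  Ten increasingly stringent
score-decile cutoffs give ten burden transformations per gene, each tested
against an inverse-normal-transformed phenotype by OLS with covariates
(optionally including nearby tagging-SNP dosages); the per-gene statistic
is the minimum p over the ten transformations, with Bonferroni thresholds
for replication (alpha/10) and exome-wide (alpha/(10 x n_genes)) use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GeneCarrierSet",
    "AssocResult",
    "lof_segments",
    "burden_vectors",
    "inverse_normal_transform",
    "burden_test",
    "gene_scan",
    "wes_lof_burden",
    "synthesize_cohort",
]

N_TRANSFORMATIONS = 10


@dataclass(frozen=True)
class GeneCarrierSet:
    """A gene interval plus its sequenced rare-LoF carrier ids."""

    gene: str
    chrom: str
    start_bp: int
    end_bp: int
    carriers: frozenset

    def __post_init__(self):
        object.__setattr__(self, "carriers", frozenset(self.carriers))


@dataclass(frozen=True)
class AssocResult:
    gene: str
    transformation: int
    beta: float
    se: float
    p: float
    n: int
    covariates: tuple[str, ...] = ()


def _iter_segs(segments):
    if hasattr(segments, "itertuples"):
        for r in segments.itertuples():
            yield r.ind_a, r.ind_b, int(r.start_bp), int(r.end_bp), float(r.score)
    else:
        for s in segments:
            yield s.ind_a, s.ind_b, s.start_bp, s.end_bp, s.score


def lof_segments(
    segments,
    gene: GeneCarrierSet,
    sequenced_ids: set,
    nonsequenced_ids: set,
) -> dict:
    """Per non-sequenced-individual LoF-segment score lists for one gene.

    A segment qualifies iff one endpoint individual is a carrier, the other
    is non-sequenced, and the segment overlaps the gene interval by at
    least one bp.  Phase-agnostic: either haplotype of either individual
    qualifies.
    """
    sequenced_ids = set(sequenced_ids)
    nonsequenced_ids = set(nonsequenced_ids)
    overlap = sequenced_ids & nonsequenced_ids
    if overlap:
        raise ValueError(f"individuals in both cohorts: {sorted(overlap)[:5]}")
    if not gene.carriers <= sequenced_ids:
        raise ValueError("carriers must be a subset of the sequenced cohort")
    out: dict = {}
    for a, b, lo, hi, score in _iter_segs(segments):
        if hi < gene.start_bp or lo > gene.end_bp:
            continue
        for carrier, other in ((a, b), (b, a)):
            if carrier in gene.carriers and other in nonsequenced_ids:
                out.setdefault(other, []).append(score)
                break
    return out


def burden_vectors(segment_lists: Mapping, pooled_scores=None) -> dict:
    """Ten nested burdens per individual from score-decile cutoffs.

    Decile boundaries are empirical quantiles (d-1)/10 of the gene's
    LoF-segment scores (or of *pooled_scores* when supplied); burden_d sums
    the individual's scores >= boundary_d, with boundary_1 = -inf, so
    burdens are non-increasing in d.
    """
    all_scores = (
        np.asarray(pooled_scores, dtype=float)
        if pooled_scores is not None
        else np.concatenate([np.asarray(v, float) for v in segment_lists.values()])
        if segment_lists
        else np.array([])
    )
    if all_scores.size == 0:
        return {}
    qs = np.arange(1, N_TRANSFORMATIONS) / N_TRANSFORMATIONS
    cuts = np.concatenate([[-np.inf], np.quantile(all_scores, qs)])
    out = {}
    for ind, scores in segment_lists.items():
        s = np.asarray(scores, dtype=float)
        out[ind] = np.array([s[s >= c].sum() for c in cuts])
    return out


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^-1((rank - 0.5) / n)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two values")
    if np.all(values == values[0]):
        raise ValueError("all values identical; transform undefined")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(values))


def _collinear_names(X, names):
    full = np.linalg.matrix_rank(X)
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == full:
            bad.append(names[j])
    return bad or list(names)


def _ols_t_test(y, x, covariates, names):
    """OLS of y on [intercept, x, covariates]; two-sided t on x's slope."""
    n = len(y)
    cols = [np.ones(n), np.asarray(x, dtype=float)]
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient; collinear columns: {_collinear_names(X, names)}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, np.asarray(y, float), rcond=None)
    resid = y - X @ beta
    df = n - X.shape[1]
    if df <= 0:
        raise ValueError("not enough observations for the design")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0)))
    if se == 0.0:
        return float(beta[1]), 0.0, 0.0, n
    t = beta[1] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(beta[1]), float(se), float(max(p, 0.0)), n



def burden_test(
    burden,
    phenotype,
    covariates=None,
    snp_covariates=None,
    gene: str = "",
    transformation: int = 1,
    covariate_names: Sequence[str] = (),
) -> AssocResult:
    """OLS association of one burden transformation with a phenotype.

    ``snp_covariates`` (up to 3 dosage columns) are appended to the
    covariates for SNP-adjusted testing.  Missing-value handling is by
    listwise deletion.
    """
    burden = np.asarray(burden, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    blocks = [burden[:, None], phenotype[:, None]]
    names = ["intercept", "burden"] + list(covariate_names)
    cov = None
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if not covariate_names:
            names = names[:2] + [f"covar{i}" for i in range(cov.shape[1])]
    if snp_covariates is not None and np.size(snp_covariates):
        snp = np.asarray(snp_covariates, dtype=float)
        if snp.ndim == 1:
            snp = snp[:, None]
        if snp.shape[1] > 3:
            raise ValueError("at most 3 SNP covariates may be supplied")
        cov = snp if cov is None else np.column_stack([cov, snp])
        names += [f"snp{i}" for i in range(snp.shape[1])]
    if cov is not None:
        blocks.append(cov)
    stacked = np.column_stack(blocks)
    keep = ~np.isnan(stacked).any(axis=1)
    burden, phenotype = burden[keep], phenotype[keep]
    cov = cov[keep] if cov is not None else None
    beta, se, p, n = _ols_t_test(phenotype, burden, cov, names)
    return AssocResult(gene, transformation, beta, se, p, n, tuple(names[2:]))


def gene_scan(
    burdens_by_gene: Mapping[str, np.ndarray],
    phenotype,
    covariates=None,
    snp_covariates_by_gene: Mapping[str, np.ndarray] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Scan genes over the 10 burden transformations.

    ``burdens_by_gene[gene]`` is an (n_individuals, 10) burden matrix
    aligned with *phenotype*.  Returns per-gene results, each gene's
    minimum p over transformations, and the replication (alpha/10) and
    exome-wide (alpha/(10 x n_genes)) thresholds with significance flags.
    """
    genes = list(burdens_by_gene)
    if not genes:
        raise ValueError("no testable genes")
    exome_thr = alpha / (N_TRANSFORMATIONS * len(genes))
    repl_thr = alpha / N_TRANSFORMATIONS
    results: dict[str, list[AssocResult]] = {}
    min_p: dict[str, float] = {}
    for gene in genes:
        B = np.asarray(burdens_by_gene[gene], dtype=float)
        snp = snp_covariates_by_gene.get(gene) if snp_covariates_by_gene else None
        rows = []
        for d in range(B.shape[1]):
            col = B[:, d]
            if np.all(col == col[0]):  # degenerate transformation, skip
                continue
            rows.append(
                burden_test(col, phenotype, covariates, snp, gene=gene, transformation=d + 1)
            )
        if not rows:
            continue
        results[gene] = rows
        min_p[gene] = min(r.p for r in rows)
    return {
        "results": results,
        "min_p": min_p,
        "exome_wide_threshold": exome_thr,
        "replication_threshold": repl_thr,
        "exome_wide_significant": {g: p < exome_thr for g, p in min_p.items()},
        "replication_significant": {g: p < repl_thr for g, p in min_p.items()},
        "n_genes": len(genes),
    }


def wes_lof_burden(
    carrier_counts,
    phenotype,
    covariates=None,
    snp_covariates=None,
    gene: str = "",
) -> AssocResult:
    """Direct sequenced-cohort burden test: burden = LoF allele count (or
    carrier indicator) per individual."""
    return burden_test(
        carrier_counts, phenotype, covariates, snp_covariates, gene=gene, transformation=0
    )


def synthesize_cohort(
    n_seq: int,
    n_nonseq: int,
    beta: float,
    carrier_freq: float = 0.01,
    mean_partners: float = 3.0,
    seed: int = 0,
    gene: str = "GENE1",
    n_covariates: int = 2,
    tag_r: float = 0.0,
):
    """Seeded synthetic cohort for burden-test validation.

    Carriers are drawn at *carrier_freq* among the sequenced cohort; each
    carrier shares scored segments with a Poisson(*mean_partners*) number
    of non-sequenced individuals; a latent LoF is transmitted with
    probability score/2 (phase); the phenotype is
    ``beta * latent + covariate effects + N(0,1)``.  ``tag_r`` > 0 adds a
    SNP dosage column correlated with the latent LoF for SNP-adjustment
    experiments.
    """
    if min(n_seq, n_nonseq) <= 0 or carrier_freq <= 0:
        raise ValueError("cohort sizes and carrier frequency must be positive")
    rng = np.random.default_rng(seed)
    seq_ids = [f"seq{i}" for i in range(n_seq)]
    nonseq_ids = [f"ns{i}" for i in range(n_nonseq)]
    carrier_mask = rng.random(n_seq) < carrier_freq
    if not carrier_mask.any():
        carrier_mask[rng.integers(n_seq)] = True
    carriers = frozenset(np.array(seq_ids)[carrier_mask].tolist())
    gene_set = GeneCarrierSet(gene, "1", 1_000_000, 1_050_000, carriers)

    rows = []
    latent = np.zeros(n_nonseq)
    for c in sorted(carriers):
        n_partners = rng.poisson(mean_partners)
        partners = rng.choice(n_nonseq, size=min(n_partners, n_nonseq), replace=False)
        for p in partners:
            score = float(np.round(rng.uniform(0.05, 1.0), 4))
            rows.append(
                dict(
                    ind_a=c, hap_a=0, ind_b=nonseq_ids[p], hap_b=0, chrom="1",
                    start_bp=990_000, end_bp=1_060_000, length_cM=1.0,
                    score=score, age_est=20.0, n_mismatch_windows=0,
                )
            )
            if rng.random() < score * 0.5:
                latent[p] = 1.0

    import pandas as pd

    segments = pd.DataFrame(
        rows,
        columns=[
            "ind_a", "hap_a", "ind_b", "hap_b", "chrom", "start_bp", "end_bp",
            "length_cM", "score", "age_est", "n_mismatch_windows",
        ],
    )
    covariates = rng.standard_normal((n_nonseq, n_covariates))
    cov_effects = rng.uniform(-0.3, 0.3, size=n_covariates)
    phenotype = beta * latent + covariates @ cov_effects + rng.standard_normal(n_nonseq)
    snp = None
    if tag_r > 0:
        snp = tag_r * latent + np.sqrt(max(1 - tag_r**2, 0.0)) * rng.standard_normal(n_nonseq)
    return {
        "gene": gene_set,
        "segments": segments,
        "sequenced_ids": set(seq_ids),
        "nonsequenced_ids": set(nonseq_ids),
        "nonseq_order": nonseq_ids,
        "phenotype": phenotype,
        "covariates": covariates,
        "latent_lof": latent,
        "snp": snp,
    }
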