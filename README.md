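# ibdcoal

Two-stage detection and dating of identity-by-descent (IBD) segments in
phased haplotype panels, with a bundled ground-truth coalescent simulator
and the downstream statistics that IBD sharing supports.

The detector combines:

1. **Identification** — windowed genotype hashing with recursive bin
   diversification in low-complexity regions and gap-tolerant run
   extension, yielding candidate IBS segments for haplotype pairs
   (`ibdcoal.identify`).
2. **Verification** — a coalescent hidden Markov model over discretized
   TMRCA intervals (SMC transition kernel, frequency-calibrated emission
   curve). Candidates are posterior-decoded; sites where the posterior mass
   below the time threshold `T` exceeds its prior are kept. Each output
   segment carries an **IBD quality score** (mean posterior mass below `T`)
   and a **MAP age estimate** in generations (`ibdcoal.verify`).

Downstream modules:

- `ibdcoal.simulate` — SMC pair-path simulator and a native backward
  discrete-time Wright–Fisher simulator with per-pair TMRCA truth,
  mutation dropping and array-style SNP ascertainment.
- `ibdcoal.evaluate` — site-level precision/recall and auPRC under the
  TMRCA-threshold IBD definition; length-MLE vs MAP age-error summaries.
- `ibdcoal.drc_scan` — density-of-recent-coalescence selection scan with an
  iteratively refined Gamma null and Bonferroni calls.
- `ibdcoal.relatedness` — pairwise sharing summaries, genome coverage,
  `Ne = T / mean(f_T)` estimation, expected cousin sharing, kNN birth-location
  prediction, sparse average-linkage clustering.
- `ibdcoal.burden` — LoF-segment burden association with 10 score-decile
  transformations, inverse-normal phenotypes, covariate/SNP-adjusted OLS,
  and a synthetic-cohort generator.
- `ibdcoal.panel_io` — panel/map/demography/discretization types and file
  formats, coalescent priors, parallel job partitioning.

## CLI

All commands are under a single entry point:

```bash
ibdcoal simulate --n 100 --cm 10 --seed 1 --out sim          # panel + truth
ibdcoal detect --haps sim.haps --map map.txt --demo model.demo \
    --time-threshold 50 --min-length 1.0 --out segments.tsv
ibdcoal evaluate --truth truth.tsv --calls segments.tsv -t 50 --out report.json
ibdcoal drc --ibd segments.tsv --sites sites.tsv --n-pairs 4950 --out scan.tsv
ibdcoal relatedness summaries --ibd segments.tsv --map map.txt --out pairs.tsv
ibdcoal relatedness ne --ibd segments.tsv --map map.txt --n-pairs 4950 -t 50
ibdcoal burden --carriers genes.tsv --pheno pheno.tsv --ibd segments.tsv \
    --sequenced seq_ids.txt --out assoc.tsv
ibdcoal convert --vcf panel.vcf --to hapssample --out panel.haps
```

Inputs: phased VCF or Oxford haps/sample; PLINK- or HapMap-style genetic
maps; a two-column demography file (`generation_start Ne`, where `Ne` is
the mean pairwise coalescence time); optional one-boundary-per-line TMRCA
discretization files. The IBD output is a TSV with
`ind_a hap_a ind_b hap_b chrom start_bp end_bp length_cM score age_est
n_mismatch_windows`.

## Notes

- Biobank-scale empirical figures (hundreds of billions of segments,
  geographic error in km, specific selection/association loci) depend on
  restricted cohort data and are out of scope; the package validates the
  methods on simulations with known truth instead.
- `Ne` throughout is the mean pairwise coalescence time (a pair coalesces
  at rate `1/Ne(t)` per generation); demography files document this to
  avoid the diploid factor-of-two ambiguity.
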