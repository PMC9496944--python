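# Methods

## The P-TMB score

For a sample with mutation list *m*, positive-pathway gene union PP and
negative-pathway gene union NP, with per-gene coding lengths L (bp),

P-TMB = ( Σ_{g∈PP} P_g / Σ_{g∈PP} L_g − Σ_{g∈NP} N_g / Σ_{g∈NP} L_g ) × 10⁶,

where P_g (N_g) is the sample's count of nonsynonymous mutations in gene g.
Both denominators sum over *every* member of the set, mutated or not, so
the score is a difference of two per-Mb rates.  Consequences counted as
nonsynonymous are the ten classes: missense mutation, inframe
insertion/deletion, frameshift insertion/deletion, start lost, stop
gained, stop lost, and splice acceptor/donor variants; VEP and TCGA-MAF
vocabularies are mapped onto these via a synonym table at classification
time (MAF's undifferentiated `Splice_Site` is counted).  Consequences the
table does not know are never counted.

Properties used by the tests: the score is antisymmetric under swapping PP
and NP, additive over any partition of the mutation list, and ignores genes
outside PP ∪ NP.  Genes in both sets are counted on both sides (the formula
defines no exclusion rule) with a warning.  An empty NP (or PP) set is an
error unless explicitly allowed, in which case that term is zero; the
pipeline allows it because a study with no consistently NR-enriched
pathways is a legitimate outcome.

TMB uses a configurable coding-footprint denominator, default 30 Mb (a
conventional exome size; within-cohort comparisons are invariant to the
constant).

## Pathway enrichment and selection

The mutation-frequency matrix M holds, per sample and per gene mutated
anywhere in the cohort, the nonsynonymous count divided by the gene's
coding length × 10⁶ (default `per_mb`; `count` and `binary` modes exist
because "mutation frequency" admits several readings).

Enrichment scoring follows the GSVA construction: (1) each gene's values
are converted to cross-sample cumulative scores through a kernel CDF —
default `ecdf`, since a Gaussian kernel is ill-behaved on mostly-zero
mutation rows (it remains available, with an ecdf fallback for constant
rows, as does a Poisson kernel for count matrices); (2) within each sample
genes are ranked by decreasing score and the centered statistic
r = |n/2 − rank| is formed; (3) a weighted KS random walk over the ranked
list takes steps r^τ / Σ_set r^τ inside the set (τ = 1) and −1/(n−|set|)
outside; (4) the score is the maximum positive plus the minimum negative
deviation (`mx_diff`, default) or the single largest-magnitude deviation
(`two_sided_max`).  Both variants are bounded by 1 in magnitude.

Mutation matrices are zero-inflated, so rank ties are everywhere.  Ties are
broken by one seeded gene permutation fixed per call: deterministic,
reproducible, and unbiased on average.  The identical contract is honored
by the independent step-by-step reference walk the tests compare against
(agreement to 1e-10; the ecdf mode is additionally exactly invariant under
strictly monotone per-gene transforms because it depends on within-gene
orderings only).

Per cohort, responder and non-responder scores are compared per pathway by
a Mann–Whitney U test: full enumeration of group assignments when both
groups have ≤ 8 samples (extremeness = distance of U from its null mean,
which handles ties exactly), otherwise the tie-corrected normal
approximation with continuity correction.  A pathway is PP if p < 0.05
with responders higher in at least `min_datasets` cohorts (default 4, the
literal reading of "more than three"; configurable), NP symmetrically; a
pathway qualifying as both is excluded with a warning.  The raw p-value is
thresholded by design — no multiplicity correction — because the
cross-cohort replication requirement is the error control; a
Benjamini–Hochberg column is emitted for reference where relevant.

## Single-gene and survival analyses

Response-gene selection builds, per gene, the per-sample mutated/wild-type
2×2 table against R/NR (a sample counts once per gene) and requires Fisher
exact p < 0.05 and fold change of mutation frequencies > 1.5.  Fold change
is two-sided (max/min) so enrichment in either group qualifies; a frequency
of zero in one group gives +∞ (treated as passing), with an optional
Haldane +0.5 pseudocount mode for finite ranking.  The Fisher p-value is
computed by exact integer enumeration of the hypergeometric support
(`math.comb` table counts), i.e. the textbook two-sided rule without
floating-point tie ambiguity; tests verify exact agreement with a
factorial-formula enumeration over every table with n ≤ 40.

Recurrent-mutation exclusivity groups identical (gene, protein-change)
events across samples, keeps those with total recurrence ≥ 2 (the minimal
reading of "recurrent"), and classifies them R-only / NR-only / shared.

The gene-pair feature "A|B" is the per-sample indicator of a nonsynonymous
mutation in A or B.  Survival comparisons use the standard two-group
log-rank statistic (Σ(O−E))²/ΣV, and multivariate Cox fits (e.g. pair
indicator + age + sex) are delegated to lifelines' partial-likelihood
maximizer with Efron tie handling (the least-biased common default; the
method description names no policy), reporting hazard ratios with Wald 95%
intervals.

## Evaluation

ROC thresholds sit at midpoints between adjacent distinct scores plus ±∞;
responders are the positive class; the rule is score > threshold.  AUC is
the trapezoidal area, which equals the rank-sum estimator U/(n₁n₂) (exactly
on tie-free data, and with diagonal segments for ties).  The Youden cutoff
maximizes sensitivity + specificity − 1, breaking ties toward the smallest
candidate; with completely uninformative scores every candidate has J = 0
and the reported cutoff degenerates to −∞, which the pipeline simply
propagates.  The global threshold is the unweighted mean of per-cohort
cutoffs (a sample-size-weighted mean is available).

Because selecting pathways on the same cohorts one evaluates on is
circular, the pipeline defaults to leave-one-cohort-out: pathways for each
cohort are selected from the remaining cohorts (still requiring
`min_datasets` hits) and the cohort's AUC is out-of-sample.  Selection and
evaluation on the full set is available as `leave_one_out=False`, and the
report states which mode produced it.

## The synthetic generator

`simulate_cohorts` emulates the study design: `n_cohorts` independent
cohorts (default 6) of `n_samples` samples (60) with a fixed responder
fraction (0.5); `n_genes` genes (2000) with lognormal coding lengths
(median 1500 bp, σ = 0.8 — a realistic heavy right tail); `n_pathways`
gene sets (60) of `genes_per_pathway` genes (25), of which
`planted_pp_pathways` (10) draw disjoint gene blocks and carry a
`pp_effect` (3×) mutation-rate multiplier in responders (planted NP
pathways are symmetric in non-responders; default 0 planted NP, so the
null pathway pool is 50).  Per sample and gene the nonsynonymous count is
Poisson(length × rate/10⁶), with rate = `background_rate` (15/Mb, a
high-TMB melanoma-like setting chosen so pathway-level signal is present
at 60 samples) × a per-sample lognormal multiplier (σ = 0.8, normalized to
mean 1).  The multiplier reproduces the defining nuisance of real TMB
data — order-of-magnitude inter-patient burden variation — and is what
makes whole-exome TMB a weak response predictor in the simulation even
though planted-pathway genes mutate faster in responders, mirroring the
motivating observation.  A gamma-Poisson (negative-binomial) option adds
within-sample overdispersion for robustness checks.  Counts expand to
mutation records with missense-heavy consequence draws plus a configurable
fraction of synonymous decoys (0.3); missense records get protein changes,
25% of them from three fixed per-gene hotspots so recurrence exists.
Survival is exponential with hazard 0.05/month, halved
(`survival_hazard_ratio` = 0.5) for carriers of a designated gene pair
(the two longest non-planted genes, maximizing carrier frequency), with
independent exponential censoring (0.03/month).  A manifest records every
planted truth.

What the generator does *not* emulate: mutational signatures and
trinucleotide context, gene-gene mutation correlation (beyond the planted
sets), copy-number events, subclonality/VAF, panel/platform differences
between cohorts, and covariate-dependent censoring.  Passing recovery
tests therefore demonstrates that the pipeline detects the planted effect
structure under realistic burden heterogeneity — not that the score will
transfer to any particular clinical cohort.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical output files, and the pipeline is a pure
  function of (inputs, config).
- Consequence strings are normalized (case, separators, synonyms) only at
  classification time so files round-trip verbatim; compound VEP strings
  (`a&b`) count if any part is nonsynonymous.
- Clinical time units are cohort-local and never converted; only
  within-cohort comparisons are made.
- Problem sizes in the test suite (e.g. 10–20 simulation replicates, 8
  cohorts × 50 pathways for the null calibration, n = 500 Cox fits) are
  chosen so the whole default study re-runs in about a minute while
  keeping Monte-Carlo error well inside the asserted margins.
- Known limitations: the exact Mann–Whitney path enumerates
  C(n₁+n₂, n₁) assignments and is only used for groups ≤ 8 per side; Youden
  cutoffs are midpoints, so they inherit score discreteness; the Gaussian
  kernel falls back to ecdf for constant gene rows rather than erroring.
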