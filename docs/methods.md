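# Methods

This note documents the models implemented in `mircombo`, the synthetic-data
generator behind its tests, the parameter defaults, and the design decisions
taken where the procedures admitted more than one reasonable reading.

## Combination indices

Fractional inhibition of arm X at the endpoint is
`E_X = 1 − mean(signal_X) / mean(signal_control)`, replicate means taken at
the recorded imaging time nearest the requested endpoint (default 120 h;
live-cell imaging intervals are irregular, so the endpoint snaps rather than
interpolates). Negative values (growth promotion) are allowed and flagged.
The standard error comes from the delta method for a ratio of independent
replicate means.

Two combination indices are computed from the single-agent effects
`E_A, E_B, E_C` and the combination effect `E_ABC`:

- **linear interaction / response additivity**:
  `CI = (E_A + E_B + E_C) / E_ABC`;
- **Bliss independence, three-agent form**:
  `CI = ((E_A + E_B + E_C) − E_A·E_B·E_C) / E_ABC`.

The three-agent Bliss form omits the pairwise product terms of the canonical
inclusion–exclusion expansion `1 − (1−E_A)(1−E_B)(1−E_C)`; both are
implemented verbatim (`bliss_paper`, `bliss_canonical`) and reported side by
side rather than silently merging them — for small effects they differ
noticeably (e.g. 0.997 vs 0.903 at E = 0.1 each, E_ABC = 0.3). CI < 1 is
synergy, > 1 antagonism; |CI − 1| ≤ 0.05 (configurable) is called
additivity. Endpoint comparisons use one-way ANOVA with Tukey HSD
(`scipy.stats.tukey_hsd`); when every replicate value is identical the
omnibus test is reported as F = 0, p = 1 rather than NaN. Uncertainty on CI
is available via a seeded nonparametric bootstrap over replicates
(percentile interval, default 1,000 resamples; off by default in the CLI).

**Numerical note.** Under planted exact additivity with zero noise the
estimated linear CI equals 1 to double precision (~1e−15 rounding from the
ratio of means); tests assert |CI − 1| ≤ 1e−12.

## DE classification and overlap

A gene is differentially expressed when `padj < 0.05` and `|log2FC| ≥ 0.5`
(fold boundary inclusive, p boundary exclusive). The consensus set for a
direction contains genes with that direction in at least `min_studies = 2`
studies, minus every gene showing the opposite direction in *any* study
(direction conflicts are reported, not silently dropped), restricted to
protein-coding genes by default. lncRNAs passing the same consensus rule are
retained in a side channel for sequence-level analysis. Venn region counts
over the per-study direction sets always sum to the union.

## Target enrichment

Two routes, reported together:

- **Hypergeometric**: exact over/under-representation p for k annotated
  genes in a size-n set from a universe of N with K annotated, plus fold
  enrichment `(k/n)/(K/N)`.
- **Permutation**: `iters` (default 10,000) random subsets of the universe,
  matched in size to the observed set, drawn without replacement; the
  statistic is the fraction of genes targeted by ≥ `min_mirnas` (default 2)
  distinct miRNAs. The empirical p uses the add-one rule
  `(1 + #{null ≥ obs}) / (iters + 1)` and therefore cannot go below
  1/(iters+1); a one-sided normal-approximation p from the null mean/SD is
  reported alongside, explicitly labelled as an approximation, for effects
  far beyond the permutation floor. Null draws are generated in child-seeded
  blocks of 1,000 iterations, so the stream depends only on the seed and a
  longer run extends a shorter one.

The permutation universe defaults to the union of all genes classified up or
down in any study; the target map is always supplied at run time, never
hard-coded.

## Silencing vs targeting count and site burden

For each study, log2FC of downregulated plus not-DE genes (upregulated genes
are secondary effects and are excluded) is stratified by the number of
distinct targeting miRNAs (0–3); the 0 vs ≥ 1 comparison uses a two-sided
Wilcoxon rank-sum test — exact enumeration when both groups have ≤ 6 untied
observations, normal approximation with tie correction otherwise.

Consensus-downregulated genes get a mean and sample (n−1) SD of log2FC
across the studies reporting them; genes with SD > 0.5 are excluded as
inconsistent. Total binding-site burden sums per-miRNA site counts over all
three miRNAs indiscriminately. Quartiles of mean log2FC are computed on the
filtered set by linear interpolation (numpy default, type 7); **high**
silencing is mean log2FC ≤ Q1 (silencing means downregulation, so the most
negative tail is "high"), **low** is ≥ Q3, boundary ties included in the
extreme classes. The 2×2 table (high/low × single/multiple sites) is tested
by chi-squared without continuity correction, flagged unreliable if any
expected cell is < 1; total sites between classes additionally get a
rank-sum test. If Q1 = Q3 every gene is mid and downstream testing is
skipped with a warning.

## Family clustering

Families with ≥ `min_targets` predicted targets are kept. Pairwise overlap
counts and percentages are computed set-theoretically; the percentage is
normalised by the smaller set by default (one number per pair even with
asymmetric sizes; `jaccard` and `mean` normalisations available). For
clustering, each family becomes a binary membership vector over the genes
shared by ≥ 2 families (falling back to all targets if nothing is shared),
and Ward linkage on Euclidean distances builds the tree. Families are
processed in sorted label order, so merge heights are independent of input
order. Flat partitions are cut with `fcluster`; optional bootstrap support
resamples embedding columns with replacement and reports the fraction of
replicates reproducing the flat partition (off by default). The exact
embedding behind the original dendrogram is not documented anywhere; these
are declared defaults, not claims of equivalence.

## Seed-site scanning

Canonical sites only: every occurrence of the reverse complement of miRNA
seed positions 2–7 (the 6mer core) is located and classified by the m8 match
(target base 5' of the core pairing miRNA position 8) and the A1 anchor
(adenine 3' of the core): both → 8mer, m8 only → 7mer-m8, A1 only →
7mer-A1, neither → 6mer. 6mers are off by default (high false-positive
rate). No wobble pairs, 3' supplementary pairing or energy model; only the
provided sense strand is scanned. Coordinates are 0-based half-open; FASTA
ids are taken up to the first whitespace. U/T are normalised internally.
`triple_targeted` intersects the per-miRNA hit sets and warns if two miRNAs
share an identical seed (their site sets are then indistinguishable).

## Survival stratification

Each miRNA column is standardised across patients with the sample SD; the
per-patient score is the row mean. The cohort splits at the median score
(configurable quantile), ties to the low group. Kaplan–Meier estimation and
the two-group log-rank test use `lifelines` (events precede censorings at
tied times, the standard convention); a group with zero events is flagged
low-information rather than erroring. Pearson r with two-sided t-transform
p-values quantifies miRNA co-expression.

## Synthetic data generator

One master seed expands into fixed-identifier child streams (growth, DE,
families, sequences, survival), so adding a generator never perturbs
existing streams and identical config + seed is byte-identical.

- **Growth curves** (default 25 timepoints to 120 h, 3 replicates): logistic
  control trajectory (5% → ~91% confluence); arm X ramps linearly to an
  endpoint signal of `control·(1 − E_X)`; the combination effect is
  `sum(single_effects)/planted_ci` (defaults: singles 0.08/0.10/0.12,
  planted CI 0.35), so the noise-free linear CI equals the planted value
  exactly. Noise mirrors a **paired replicate design**: each biological
  replicate is one transfection batch carrying every arm alongside its own
  control, so the dominant term is a per-replicate log-normal batch factor
  (CV = `noise_cv`, default 0.05) shared across arms, plus independent
  per-observation measurement jitter (CV = 0.2·`noise_cv` unless
  `obs_noise_cv` is set). Batch effects dominate raw signal spread but
  largely cancel in arm/control ratios — a purely independent noise model
  of the same magnitude would swamp the small single-agent effects and make
  the CI estimator useless at 3 replicates.
- **DE studies** (default 5,000 genes, 3 studies): each of the three miRNAs
  targets a gene independently with probability 0.25; listed pairs carry
  1–3 sites. The planted shift is `delta_per_mirna·n_mirnas +
  delta_per_site·(total_sites − n_mirnas)` (defaults −0.3 and −0.15 log2
  units; one site per targeting miRNA is "free", extra sites add burden).
  log2FC = shift + shared gene component (σ = 0.30) + per-study noise
  (σ = 0.25), making the three studies correlated. Adjusted p is a monotone
  transform of |log2FC| (`exp(−8·|log2FC|)` with log-normal jitter,
  clipped at 1) — downstream stages only threshold it, so no real test is
  simulated. ~10% of genes are labelled lncRNA. Ground truth (targeting
  counts, total sites, true shift) is emitted alongside.
- **Biased target maps** for enrichment calibration: per-miRNA targeting at
  base rate 0.25, with the odds multiplied by a configurable odds ratio
  (3:1 for planted enrichment, 1:1 for the null) for a favoured gene set.
- **Family targets** (default 6 families of 150 targets in two groups of 3):
  a universal core realises the between-group sharing (default 0.1), a
  per-group core tops sharing up to the within-group level (default 0.8),
  privates fill the rest; all pools are disjoint, so planted overlaps are
  exact up to rounding.
- **Sequences** (default 30 × 300 nt): backgrounds are rejection-sampled to
  contain no 6mer seed core of any miRNA; sites are planted at spaced
  positions and each sequence is re-scanned and regenerated until the scan
  equals the planted table exactly — scanner false positives and negatives
  are zero **by construction**, which is what makes the exactness test
  meaningful. A `fraction_triple` share of sequences (default 0.5) carries
  ≥ 1 site for every miRNA; the rest are capped at 2 miRNAs so the triple
  ground truth is exact.
- **Survival cohorts** (default 300 patients): trivariate standard normal
  expression with pairwise correlation 0.5; exponential event times with
  rate `λ0·exp(hazard_beta·avg_z)` (λ0 = ln2/24 months; default
  hazard_beta = −ln 2, i.e. HR 0.5 per unit score — the three miRNAs are
  protective); independent exponential censoring tuned to the target
  censoring fraction (default 20%).

**What the generator does not emulate:** read-level RNA-seq (counts,
dispersion, library size), real p-value behaviour under correlation,
realistic 3'-UTR sequence composition, non-proportional hazards, batch
structure in patient cohorts. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under its stated model, not
that the biological conclusions transfer to any particular real dataset.

## Problem sizes used in the acceptance checks

Formula exactness uses 1,000 random effect tuples at 1e−12; CI recovery,
cluster recovery and scanner exactness use 100 seeds each; enrichment
calibration uses 200 null datasets at 500 iterations and 50 planted datasets
at 2,000 iterations (2,000 genes per dataset); dose monotonicity uses 5,000
genes; survival calibration uses 200 cohorts of 120, power uses 100 cohorts
of 300, and the log-rank cross-check uses a 10,000-permutation oracle on one
40-patient cohort (tolerance 0.02, covering Monte-Carlo noise plus the
chi-squared approximation at that size). These sizes make the full suite run
in well under a minute per stochastic block on a single CPU while keeping
every rate assertion far from its threshold.

## Known limitations

- The Bliss "paper" variant is a stated formula, not a derivation; for
  small effects it approaches the linear CI rather than canonical Bliss.
- Empirical permutation p-values are floored at 1/(iters+1); extreme
  enrichment is conveyed by the z-score / normal-approximation p, which
  assumes an adequately normal null.
- The seed scanner is canonical-match only; it neither scores site context
  nor predicts repression efficacy, and equivalence with any external
  prediction tool is not claimed.
- Median-split survival analysis discards within-group score variation; no
  Cox regression is provided.
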