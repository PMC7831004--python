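# mircombo

Analysis toolkit for **synergistic miRNA combinations** in glioma, built
around the proneurogenic trio miR-124 / miR-128 / miR-137. Low doses of
tumor-suppressor miRNAs that individually do little can, in combination,
strongly suppress glioma and neuroblastoma cells; `mircombo` provides the
computational side of that claim as a tested, reusable pipeline:

1. **Synergy quantification** from replicate growth/viability time-courses.
   Fractional inhibition of each arm at a fixed endpoint,
   `E = 1 − mean(arm)/mean(control)`, enters two combination indices:

   - linear interaction (response additivity):
     `CI = (E_A + E_B + E_C) / E_ABC`
   - Bliss independence, three-agent form:
     `CI = ((E_A + E_B + E_C) − E_A·E_B·E_C) / E_ABC`,
     with the canonical expectation `1 − (1−E_A)(1−E_B)(1−E_C)` reported
     side by side.

   CI < 1 means synergy, CI = 1 additivity, CI > 1 antagonism. Endpoint
   groups are compared by one-way ANOVA with Tukey HSD.
2. **Multi-study DE overlap and target enrichment.** Genes are classified
   up/down per study (`padj < 0.05`, `|log2FC| ≥ 0.5`), consensus sets
   require the same direction in ≥ 2 studies, direction conflicts are
   removed, and (optionally) only protein-coding genes are kept. Enrichment
   of miRNA targets in a set is tested with the exact hypergeometric test
   and with a 10,000-iteration permutation null of size-matched random
   subsets of the DE universe (empirical p with the add-one rule, plus a
   labelled normal-approximation p and z).
3. **Silencing vs binding-site burden.** Median log2FC stratified by the
   number of targeting miRNAs (rank-sum 0 vs ≥ 1), and among
   consensus-downregulated genes a high/low silencing classification by the
   1st/3rd quartiles of mean log2FC (cross-study SD > 0.5 excluded), tested
   against single vs multiple total binding sites by chi-squared.
4. **Shared-target clustering.** Pairwise target-overlap matrices of miRNA
   families and Ward/Euclidean hierarchical clustering on binary
   shared-target membership vectors.
5. **Seed-site scanning.** Canonical 8mer / 7mer-m8 / 7mer-A1 (optionally
   6mer) seed matches on lncRNA/transcript sequences, and the intersection
   of sequences carrying sites for all three miRNAs.
6. **Survival stratification.** Per-patient average z-score of the three
   miRNAs, median split, Kaplan–Meier curves with a log-rank test, and the
   Pearson co-expression matrix.

A **synthetic-data generator** (`mircombo.synth`) produces every input with
planted ground truth — planted combination index, planted per-miRNA/per-site
expression shifts, planted family clusters, planted seed sites with
rejection-sampled clean background, planted hazard — so the whole pipeline
is testable offline with no external data.

## Worked example

```bash
mircombo simulate --seed 7 --out demo_inputs
mircombo synergy demo_inputs/growth_curves.tsv
```

```
model           ci        interpretation  ci_low  ci_high
linear          0.346804  synergy         nan     nan
bliss_paper     0.345739  synergy         nan     nan
bliss_canonical 0.314234  synergy         nan     nan
```

The generator planted a combination index of 0.35 (its default): three
single arms with small effects (0.08, 0.10, 0.12) and a combination arm
whose endpoint inhibition is their sum divided by 0.35. All three CI
estimates land near the planted value and well below 1 — strong synergy.
(Pass `--bootstrap 1000` for percentile confidence bounds instead of `nan`.)

```bash
mircombo overlap demo_inputs/de_study{1,2,3}.tsv \
    --target-map demo_inputs/target_map.tsv --iters 10000 --seed 7 \
    --out demo_overlap
```

```
consensus=1532 observed_fraction=0.3760 empirical_p=9.999e-05 z=18.918
```

1,532 protein-coding genes are downregulated in ≥ 2 of the 3 synthetic
studies with no direction conflict. 37.6% of them are targeted by ≥ 2 of the
three miRNAs — the permutation null never reaches that fraction, so the
empirical p sits at its floor of 1/10001 and the z-score (18.9) carries the
effect size. That is the expected signature: the generator shifts expression
down per targeting miRNA, so targets concentrate in the down-consensus.

```bash
mircombo survival demo_inputs/survival_cohort.tsv --out demo_surv
```

```
logrank_p=1.061e-07 medians={'low': 16.81859296, 'high': 38.32807746}
```

Patients in the high average-z half of the cohort live substantially longer
(median 38.3 vs 16.8 months) — the planted protective hazard
(HR = 0.5 per unit average z) recovered by the median-split log-rank test.

`mircombo run-all --seed 7 --out run/` executes all seven stages from one
master seed and writes a `summary.json` whose per-file SHA-256 hashes
reproduce exactly on rerun.

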