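"""DE classification, consensus overlap, hypergeometric and permutation
enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mircombo.overlap import (
    SchemaError,
    build_overlap,
    classify_de,
    hypergeom_enrichment,
    permutation_enrichment,
    target_fraction,
)


def de_table(rows, study="s1"):
    df = pd.DataFrame(
        rows, columns=["gene_id", "biotype", "log2fc", "padj"]
    )
    df.insert(0, "study", study)
    return df


class TestClassifyDE:
    @pytest.mark.parametrize(
        "log2fc,padj,expected",
        [
            (0.5, 0.049, "up"),      # fold boundary inclusive
            (-0.5, 0.049, "down"),
            (-3.0, 0.05, "ns"),      # padj boundary exclusive
            (0.49, 1e-10, "ns"),     # below fold threshold
            (2.0, 0.01, "up"),
            (-2.0, 0.01, "down"),
        ],
    )
    def test_threshold_boundaries(self, log2fc, padj, expected):
        table = de_table([("g", "protein_coding", log2fc, padj)])
        assert classify_de(table).iloc[0] == expected

    def test_missing_columns_named_in_error(self):
        with pytest.raises(SchemaError, match="log2fc"):
            classify_de(pd.DataFrame({"gene_id": ["g"], "padj": [0.1],
                                      "biotype": ["protein_coding"]}))

    def test_nonpositive_thresholds_rejected(self):
        table = de_table([("g", "protein_coding", 1.0, 0.01)])
        with pytest.raises(ValueError):
            classify_de(table, lfc_thresh=0.0)


def three_studies():
    # g1: down in s1,s2, ns in s3 -> consensus
    # g2: down in s1, up in s2    -> conflict
    # g3: lncRNA down in all 3    -> lncRNA side channel
    # g4: down only in s1         -> below min_studies
    # g5: up in s1,s2             -> up consensus
    s1 = de_table(
        [
            ("g1", "protein_coding", -2.0, 0.001),
            ("g2", "protein_coding", -1.5, 0.001),
            ("g3", "lncRNA", -1.0, 0.001),
            ("g4", "protein_coding", -1.2, 0.001),
            ("g5", "protein_coding", 1.4, 0.001),
        ],
        "s1",
    )
    s2 = de_table(
        [
            ("g1", "protein_coding", -1.8, 0.001),
            ("g2", "protein_coding", 1.5, 0.001),
            ("g3", "lncRNA", -0.9, 0.001),
            ("g4", "protein_coding", 0.1, 0.9),
            ("g5", "protein_coding", 0.9, 0.001),
        ],
        "s2",
    )
    s3 = de_table(
        [
            ("g1", "protein_coding", -0.1, 0.9),
            ("g2", "protein_coding", -0.2, 0.9),
            ("g3", "lncRNA", -1.1, 0.001),
            ("g4", "protein_coding", 0.0, 1.0),
            ("g5", "protein_coding", 0.2, 0.8),
        ],
        "s3",
    )
    return [s1, s2, s3]


class TestBuildOverlap:
    def test_consensus_needs_two_studies_same_direction(self):
        ov = build_overlap(three_studies(), "down")
        assert "g1" in ov.consensus
        assert "g4" not in ov.consensus

    def test_direction_conflicts_removed_and_listed(self):
        ov = build_overlap(three_studies(), "down")
        assert "g2" not in ov.consensus
        assert "g2" in ov.removed_conflicts

    def test_lncrna_kept_in_side_channel_under_coding_filter(self):
        ov = build_overlap(three_studies(), "down", coding_only=True)
        assert "g3" not in ov.consensus
        assert "g3" in ov.lncrna_consensus
        ov_all = build_overlap(three_studies(), "down", coding_only=False)
        assert "g3" in ov_all.consensus

    def test_venn_region_counts_sum_to_union(self):
        for direction in ("up", "down"):
            ov = build_overlap(three_studies(), direction)
            assert sum(ov.venn_counts.values()) == len(ov.union)

    def test_duplicate_gene_within_study_rejected(self):
        s1, s2, s3 = three_studies()
        dup = pd.concat([s1, s1.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicated gene"):
            build_overlap([dup, s2, s3], "down")


class TestTargetFraction:
    def target_map(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g2"],
                "mirna": ["miR-124", "miR-128", "miR-124"],
                "site_count": [1, 2, 1],
            }
        )

    def test_counting(self):
        frac, k = target_fraction({"g1", "g3"}, self.target_map(), min_mirnas=1)
        assert (frac, k) == (0.5, 1)

    def test_min_mirnas_saturation_and_zero(self):
        tm = self.target_map()
        assert target_fraction({"g1", "g2"}, tm, min_mirnas=1) == (1.0, 2)
        assert target_fraction({"g1", "g2"}, tm, min_mirnas=3) == (0.0, 0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            target_fraction(set(), self.target_map())


class TestHypergeometric:
    def test_exact_enumeration_example(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        res = hypergeom_enrichment(k=4, n=4, K=5, N=10)
        assert res["p_over"] == pytest.approx(5 / 210, abs=1e-12)

    def test_fold_is_one_at_expectation(self):
        res = hypergeom_enrichment(k=2, n=4, K=5, N=10)
        assert res["fold"] == pytest.approx(1.0, abs=1e-12)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            hypergeom_enrichment(k=0, n=3, K=10, N=10)  # all annotated, k must be n
        with pytest.raises(ValueError, match="impossible"):
            hypergeom_enrichment(k=5, n=4, K=10, N=20)

    def test_matches_exhaustive_subset_enumeration_small_universe(self):
        # enumerate all subsets of a size-9 universe
        N, K = 9, 4
        annotated = set(range(K))
        for n in range(1, N + 1):
            tallies = {}
            for subset in itertools.combinations(range(N), n):
                hits = len(annotated & set(subset))
                tallies[hits] = tallies.get(hits, 0) + 1
            total = math.comb(N, n)
            for k in range(max(0, n - (N - K)), min(n, K) + 1):
                res = hypergeom_enrichment(k, n, K, N)
                p_over = sum(v for h, v in tallies.items() if h >= k) / total
                p_under = sum(v for h, v in tallies.items() if h <= k) / total
                assert res["p_over"] == pytest.approx(p_over, abs=1e-12)
                assert res["p_under"] == pytest.approx(p_under, abs=1e-12)


class TestPermutationEnrichment:
    def build(self, n_universe=60, n_targeted=30):
        universe = {f"g{i}" for i in range(n_universe)}
        rows = []
        for i in range(n_targeted):
            rows.append({"gene_id": f"g{i}", "mirna": "miR-124", "site_count": 1})
            rows.append({"gene_id": f"g{i}", "mirna": "miR-128", "site_count": 1})
        return universe, pd.DataFrame(rows)

    def test_observed_above_every_null_hits_pseudocount_floor(self):
        universe, tm = self.build()
        observed = {f"g{i}" for i in range(20)}  # all targeted
        res = permutation_enrichment(
            observed, universe, tm, min_mirnas=2, iters=200, seed=1
        )
        assert res.observed_fraction == 1.0
        assert res.empirical_p == pytest.approx(1 / 201)

    def test_fully_targeted_universe_is_degenerate(self):
        universe, _ = self.build(40, 40)
        tm = pd.DataFrame(
            [
                {"gene_id": f"g{i}", "mirna": m, "site_count": 1}
                for i in range(40)
                for m in ("miR-124", "miR-128", "miR-137")
            ]
        )
        res = permutation_enrichment(
            {f"g{i}" for i in range(10)}, universe, tm, min_mirnas=3,
            iters=200, seed=2,
        )
        assert res.observed_fraction == 1.0
        assert res.null_mean == 1.0
        assert res.empirical_p == 1.0

    def test_normal_approximation_converges_to_empirical(self):
        universe, tm = self.build(200, 80)
        observed = {f"g{i}" for i in range(30, 80)}  # mixed set
        diffs = []
        for iters in (200, 5000):
            res = permutation_enrichment(
                observed, universe, tm, min_mirnas=2, iters=iters, seed=3
            )
            diffs.append(abs(res.empirical_p - res.normal_approx_p))
        assert diffs[1] <= diffs[0] + 0.01

    def test_subset_and_iters_validation(self):
        universe, tm = self.build()
        with pytest.raises(ValueError, match="subset"):
            permutation_enrichment({"zzz"}, universe, tm, iters=200, seed=0)
        with pytest.raises(ValueError, match="iters"):
            permutation_enrichment({"g1"}, universe, tm, iters=50, seed=0)

    def test_null_stream_reproducible_and_extends_with_iters(self):
        universe, tm = self.build(100, 50)
        observed = {f"g{i}" for i in range(25, 45)}
        r1 = permutation_enrichment(
            observed, universe, tm, iters=600, seed=7, return_null=True
        )
        r2 = permutation_enrichment(
            observed, universe, tm, iters=600, seed=7, return_null=True
        )
        assert np.array_equal(r1.null_fractions, r2.null_fractions)
        longer = permutation_enrichment(
            observed, universe, tm, iters=1600, seed=7, return_null=True
        )
        assert np.array_equal(longer.null_fractions[:600], r1.null_fractions)
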