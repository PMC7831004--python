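"""Silencing vs targeting count and binding-site burden analyses."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mircombo.dose import (
    InsufficientDataError,
    burden_classification,
    lfc_by_targeting,
    rank_sum_test,
    site_category_test,
)
from mircombo.overlap import build_overlap
from mircombo.synth import SynthConfig, gen_de_studies


def exact_rank_sum_oracle(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    x, y = list(x), list(y)
    combined = x + y
    n = len(x)
    ranks = {v: r for r, v in enumerate(sorted(combined), start=1)}
    obs = sum(ranks[v] for v in x)
    mu = n * (len(combined) + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(combined)), n):
        s = sum(ranks[combined[i]] for i in idx)
        total += 1
        if abs(s - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


class TestRankSum:
    @pytest.mark.parametrize("nx,ny,seed", [(4, 4, 0), (3, 5, 1), (6, 6, 2), (2, 6, 3)])
    def test_exact_matches_full_enumeration(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, nx)
        y = rng.normal(0.8, 1, ny)
        assert rank_sum_test(x, y) == pytest.approx(
            exact_rank_sum_oracle(x, y), abs=1e-12
        )

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 50)
        y = rng.normal(1, 1, 50)
        p = rank_sum_test(x, y)
        assert 0 < p < 1e-4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestLfcByTargeting:
    def test_planted_monotone_effect_recovered(self):
        cfg = SynthConfig(
            seed=3, n_genes=5000, delta_per_mirna=-0.3, delta_per_site=0.0
        )
        studies, tmap, _ = gen_de_studies(cfg)
        res = lfc_by_targeting(studies, tmap)
        for study, r in res.items():
            meds = [r["medians"][c] for c in sorted(r["medians"])]
            assert all(a > b for a, b in zip(meds, meds[1:])), study
            assert r["monotone_decreasing"]
            assert r["p_value"] < 1e-6

    def test_null_config_shows_no_targeting_signal(self):
        # single fixed null dataset: medians nearly flat, p not extreme
        cfg = SynthConfig(
            seed=12, n_genes=4000, delta_per_mirna=0.0, delta_per_site=0.0
        )
        studies, tmap, _ = gen_de_studies(cfg)
        res = lfc_by_targeting(studies, tmap)
        for r in res.values():
            meds = list(r["medians"].values())
            assert max(meds) - min(meds) < 0.1
            assert r["p_value"] > 1e-4

    def test_empty_stratum_warns_and_is_skipped(self):
        table = pd.DataFrame(
            {
                "study": "s1",
                "gene_id": ["g1", "g2"],
                "biotype": "protein_coding",
                "log2fc": [-1.0, -0.5],
                "padj": [0.5, 0.5],
            }
        )
        tmap = pd.DataFrame(
            {"gene_id": ["g1"], "mirna": ["miR-124"], "site_count": [1]}
        )
        with pytest.warns(UserWarning, match="stratum skipped"):
            res = lfc_by_targeting([table], tmap)
        assert set(res["s1"]["medians"]) == {0, 1}


def make_studies(per_gene_lfcs: dict[str, tuple]) -> list[pd.DataFrame]:
    """Three-study tables with given per-gene per-study log2fc, all padj=0."""
    studies = []
    for i in range(3):
        rows = [
            {
                "study": f"s{i+1}",
                "gene_id": g,
                "biotype": "protein_coding",
                "log2fc": v[i],
                "padj": 0.001,
            }
            for g, v in per_gene_lfcs.items()
        ]
        studies.append(pd.DataFrame(rows))
    return studies


class TestBurdenClassification:
    def test_type7_quartiles_and_extreme_classes(self):
        # means {-2.0, -1.5, -1.0, -0.5}: Q1=-1.625, Q3=-0.875 (linear interp)
        lfcs = {
            "g1": (-2.0, -2.0, -2.0),
            "g2": (-1.5, -1.5, -1.5),
            "g3": (-1.0, -1.0, -1.0),
            "g4": (-0.5, -0.5, -0.5),
        }
        studies = make_studies(lfcs)
        tmap = pd.DataFrame(
            {"gene_id": list(lfcs), "mirna": "miR-124", "site_count": 1}
        )
        res = burden_classification(set(lfcs), studies, tmap)
        assert res.q1 == pytest.approx(-1.625)
        assert res.q3 == pytest.approx(-0.875)
        cls = res.records.set_index("gene_id")["silencing_class"]
        assert cls["g1"] == "high"  # most negative = most silenced
        assert cls["g4"] == "low"
        assert cls["g2"] == "mid" and cls["g3"] == "mid"

    def test_sd_filter_excludes_inconsistent_gene(self):
        lfcs = {
            "g1": (-1.0, -1.0, -2.2),  # sample sd 0.6928 > 0.5
            "g2": (-1.5, -1.5, -1.5),
            "g3": (-1.0, -1.0, -1.0),
            "g4": (-0.5, -0.5, -0.5),
            "g5": (-2.0, -2.0, -2.0),
        }
        studies = make_studies(lfcs)
        tmap = pd.DataFrame(
            {"gene_id": list(lfcs), "mirna": "miR-124", "site_count": 1}
        )
        res = burden_classification(set(lfcs), studies, tmap)
        rec = res.records.set_index("gene_id")
        assert rec.loc["g1", "sd_log2fc"] == pytest.approx(0.6928, abs=5e-5)
        assert rec.loc["g1", "silencing_class"] == "excluded"
        assert res.n_excluded == 1

    def test_identical_means_degenerate_all_mid(self):
        lfcs = {f"g{i}": (-1.0, -1.0, -1.0) for i in range(5)}
        studies = make_studies(lfcs)
        tmap = pd.DataFrame(
            {"gene_id": list(lfcs), "mirna": "miR-124", "site_count": 1}
        )
        with pytest.warns(UserWarning, match="identical"):
            res = burden_classification(set(lfcs), studies, tmap)
        assert res.degenerate
        assert (res.records["silencing_class"] == "mid").all()

    def test_too_few_genes_after_filter(self):
        lfcs = {"g1": (-1.0, -1.0, -1.0), "g2": (-2.0, -2.0, -2.0)}
        studies = make_studies(lfcs)
        tmap = pd.DataFrame(
            {"gene_id": list(lfcs), "mirna": "miR-124", "site_count": 1}
        )
        with pytest.raises(InsufficientDataError):
            burden_classification(set(lfcs), studies, tmap)

    def test_total_sites_summed_indiscriminately(self):
        lfcs = {f"g{i}": (-1.0 - 0.1 * i,) * 3 for i in range(6)}
        studies = make_studies(lfcs)
        tmap = pd.DataFrame(
            {
                "gene_id": ["g0", "g0", "g0", "g1"],
                "mirna": ["miR-124", "miR-128", "miR-137", "miR-124"],
                "site_count": [2, 1, 3, 1],
            }
        )
        res = burden_classification(set(lfcs), studies, tmap)
        rec = res.records.set_index("gene_id")
        assert rec.loc["g0", "total_sites"] == 6
        assert rec.loc["g0", "n_mirnas"] == 3
        assert rec.loc["g2", "total_sites"] == 0

    def test_row_order_invariance(self):
        cfg = SynthConfig(seed=5, n_genes=2000)
        studies, tmap, _ = gen_de_studies(cfg)
        ov = build_overlap(studies, "down")
        r1 = burden_classification(ov.consensus, studies, tmap)
        shuffled = [s.sample(frac=1, random_state=9) for s in studies]
        r2 = burden_classification(
            ov.consensus, shuffled, tmap.sample(frac=1, random_state=9)
        )
        pd.testing.assert_frame_equal(r1.records, r2.records)


class FakeBurden:
    def __init__(self, records):
        self.records = records


class TestSiteCategoryTest:
    def make_records(self, high_sites, low_sites):
        rows = []
        for i, s in enumerate(high_sites):
            rows.append(
                {"gene_id": f"h{i}", "mean_log2fc": -2.0, "sd_log2fc": 0.1,
                 "n_mirnas": 1, "total_sites": s, "silencing_class": "high"}
            )
        for i, s in enumerate(low_sites):
            rows.append(
                {"gene_id": f"l{i}", "mean_log2fc": -0.1, "sd_log2fc": 0.1,
                 "n_mirnas": 1, "total_sites": s, "silencing_class": "low"}
            )
        return FakeBurden(pd.DataFrame(rows))

    def test_perfect_association_hand_chi_square(self):
        # 2x2 table [[10,0],[0,10]] -> chi2 = 20, p ~ 7.7e-6
        res = site_category_test(
            self.make_records([2] * 10, [1] * 10)
        )
        assert res["table"].tolist() == [[0, 10], [10, 0]]
        assert res["chi2"] == pytest.approx(20.0)
        assert res["chi2_p"] == pytest.approx(7.7e-6, rel=0.01)

    def test_identical_proportions_no_association(self):
        res = site_category_test(
            self.make_records([1] * 5 + [3] * 5, [1] * 5 + [3] * 5)
        )
        assert res["chi2"] == 0.0
        assert res["chi2_p"] == 1.0

    def test_tiny_expected_cell_flagged_unreliable(self):
        res = site_category_test(self.make_records([1, 2], [1, 1]))
        assert res["chi2_unreliable"]

    def test_empty_class_rejected(self):
        rec = self.make_records([1, 2], [])
        with pytest.raises(InsufficientDataError):
            site_category_test(rec)
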