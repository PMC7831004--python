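"""Silencing magnitude versus targeting count and binding-site burden.

Two questions about the transfected miRNA trio: (1) do genes targeted by
more of the miRNAs show stronger downregulation (per-study medians of log2FC
by targeting count 0-3, with a rank-sum test of 0 vs >=1); and (2) among
consensus-downregulated genes, does total binding-site burden (sites summed
indiscriminately across the three miRNAs) associate with silencing depth?
For (2), genes are classified high/low silencing by the 1st/3rd quartiles of
their mean log2FC (more negative = more silenced), genes with a cross-study
log2FC standard deviation above 0.5 are excluded, and single- versus
multiple-site membership is tested against silencing class by chi-squared,
with a rank-sum test on total sites between classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .overlap import classify_de, target_mirna_counts


class InsufficientDataError(ValueError):
    pass


def rank_sum_test(x, y, *, exact_max: int = 6) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact enumeration when both groups have at most ``exact_max``
    observations and there are no ties; otherwise the normal approximation
    with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if max(x.size, y.size) <= exact_max and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


def lfc_by_targeting(
    studies: list[pd.DataFrame],
    target_map: pd.DataFrame,
    *,
    lfc_thresh: float = 0.5,
    padj_thresh: float = 0.05,
) -> dict[str, dict]:
    """Per-study medians of log2FC stratified by targeting count.

    Only downregulated and not-differentially-expressed genes enter the
    analysis (upregulated genes reflect secondary effects). Returns, per
    study: median log2FC per count 0-3, group sizes, the two-sided rank-sum
    p comparing the 0-miRNA group with all targeted genes, and whether the
    medians decrease monotonically with count.
    """
    n_mirnas = target_mirna_counts(target_map)
    out: dict[str, dict] = {}
    for i, table in enumerate(studies):
        name = (
            str(table["study"].iloc[0]) if "study" in table.columns else f"study{i+1}"
        )
        labels = classify_de(table, lfc_thresh, padj_thresh)
        keep = table[labels.isin(["down", "ns"])].copy()
        keep["n_mirnas"] = (
            n_mirnas.reindex(keep["gene_id"], fill_value=0).to_numpy()
        )
        medians, sizes = {}, {}
        for c in range(4):
            vals = keep.loc[keep["n_mirnas"] == c, "log2fc"]
            if vals.empty:
                warnings.warn(
                    f"{name}: no genes with targeting count {c}; stratum skipped",
                    stacklevel=2,
                )
                continue
            medians[c] = float(vals.median())
            sizes[c] = int(vals.size)
        untargeted = keep.loc[keep["n_mirnas"] == 0, "log2fc"].to_numpy()
        targeted = keep.loc[keep["n_mirnas"] >= 1, "log2fc"].to_numpy()
        p = rank_sum_test(untargeted, targeted)
        present = sorted(medians)
        mono = all(
            medians[a] > medians[b]
            for a, b in zip(present, present[1:])
        )
        out[name] = {
            "medians": medians,
            "n_per_count": sizes,
            "p_value": p,
            "monotone_decreasing": mono,
        }
    return out


@dataclass
class BurdenResult:
    records: pd.DataFrame  # gene_id, mean_log2fc, sd_log2fc, n_mirnas, total_sites, silencing_class
    q1: float
    q3: float
    n_excluded: int
    degenerate: bool  # Q1 == Q3: every gene mid, downstream test skipped


def burden_classification(
    consensus_down: set[str],
    studies: list[pd.DataFrame],
    target_map: pd.DataFrame,
    *,
    sd_max: float = 0.5,
) -> BurdenResult:
    """Classify consensus-downregulated genes by silencing depth.

    Each gene's mean and (n-1) standard deviation of log2FC are taken across
    the studies reporting it; genes with SD above ``sd_max`` are excluded as
    inconsistent. Quartiles of the mean log2FC are computed on the filtered
    set by linear interpolation; ``high`` silencing is mean log2FC <= Q1
    (most negative), ``low`` is >= Q3, ``mid`` otherwise. Total binding-site
    burden sums site counts over all three miRNAs indiscriminately.
    """
    frames = []
    for table in studies:
        sub = table[table["gene_id"].isin(consensus_down)]
        frames.append(sub[["gene_id", "log2fc"]])
    merged = pd.concat(frames)
    stats_df = merged.groupby("gene_id")["log2fc"].agg(["mean", "std", "count"])
    stats_df = stats_df[stats_df["count"] >= 2]

    sites = target_map.groupby("gene_id")["site_count"].sum()
    mirnas = target_mirna_counts(target_map)

    records = pd.DataFrame(
        {
            "gene_id": stats_df.index,
            "mean_log2fc": stats_df["mean"].to_numpy(),
            "sd_log2fc": stats_df["std"].to_numpy(),
            "n_mirnas": mirnas.reindex(stats_df.index, fill_value=0).to_numpy(),
            "total_sites": sites.reindex(stats_df.index, fill_value=0).to_numpy(),
        }
    ).reset_index(drop=True)
    excluded = records["sd_log2fc"] > sd_max
    kept = records[~excluded]
    if len(kept) < 4:
        raise InsufficientDataError(
            f"only {len(kept)} genes remain after the SD filter; "
            "quartile classification needs at least 4"
        )
    q1, q3 = np.quantile(kept["mean_log2fc"], [0.25, 0.75])
    degenerate = q1 == q3
    cls = pd.Series("mid", index=records.index)
    cls[excluded] = "excluded"
    if degenerate:
        warnings.warn(
            "all mean log2FC values identical; every gene classified mid",
            stacklevel=2,
        )
    else:
        cls[~excluded & (records["mean_log2fc"] <= q1)] = "high"
        cls[~excluded & (records["mean_log2fc"] >= q3)] = "low"
    records["silencing_class"] = cls
    records = records.sort_values("gene_id", ignore_index=True)
    return BurdenResult(records, float(q1), float(q3), int(excluded.sum()), degenerate)


def site_category_test(result: BurdenResult) -> dict:
    """Association of silencing class with single- vs multiple-site burden.

    Builds the 2x2 table (high/low silencing x single/multiple total sites)
    and applies the chi-squared test without continuity correction, flagging
    it unreliable when any expected cell is below 1; also reports the
    two-sided rank-sum p on total sites between the high and low classes.
    """
    rec = result.records
    high = rec[rec["silencing_class"] == "high"]
    low = rec[rec["silencing_class"] == "low"]
    if high.empty or low.empty:
        raise InsufficientDataError("high and low silencing classes must be non-empty")
    table = np.array(
        [
            [(high["total_sites"] <= 1).sum(), (high["total_sites"] > 1).sum()],
            [(low["total_sites"] <= 1).sum(), (low["total_sites"] > 1).sum()],
        ],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p, expected = 0.0, 1.0, table
    else:
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    unreliable = bool((expected < 1).any())
    wilcoxon_p = rank_sum_test(
        high["total_sites"].to_numpy(), low["total_sites"].to_numpy()
    )
    return {
        "table": table.astype(int),
        "chi2": float(chi2),
        "chi2_p": float(p),
        "chi2_unreliable": unreliable,
        "sites_rank_sum_p": wilcoxon_p,
        "n_high": int(len(high)),
        "n_low": int(len(low)),
    }
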