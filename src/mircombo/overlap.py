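"""Multi-study differential-expression overlap and target enrichment.

Genes are classified up/down/ns per study (padj < 0.05 and |log2FC| >= 0.5
by default), consensus sets are built as genes moving in the same direction
in a minimum number of studies with direction conflicts removed and,
optionally, restricted to protein-coding genes. Enrichment of miRNA targets
in a gene set is tested two ways: an exact hypergeometric test, and a
permutation null drawing size-matched random subsets of the
differentially-expressed universe and recomputing the targeted fraction
(10,000 iterations by default). Because an empirical permutation p cannot go
below 1/(iters+1), a one-sided normal-approximation p from the null mean and
SD is reported alongside and labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DE_COLUMNS = ("gene_id", "biotype", "log2fc", "padj")


class SchemaError(ValueError):
    pass


def _check_schema(table: pd.DataFrame) -> None:
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"DE table is missing columns: {missing}")


def classify_de(
    table: pd.DataFrame,
    lfc_thresh: float = 0.5,
    padj_thresh: float = 0.05,
) -> pd.Series:
    """Label each gene ``up``/``down``/``ns``.

    A gene is differentially expressed when ``padj < padj_thresh`` and
    ``|log2fc| >= lfc_thresh`` (the fold-change boundary is inclusive).
    """
    if lfc_thresh <= 0 or padj_thresh <= 0:
        raise ValueError("thresholds must be positive")
    _check_schema(table)
    sig = table["padj"] < padj_thresh
    label = pd.Series("ns", index=table.index)
    label[sig & (table["log2fc"] >= lfc_thresh)] = "up"
    label[sig & (table["log2fc"] <= -lfc_thresh)] = "down"
    return label


@dataclass
class OverlapSets:
    """Consensus overlap of one direction across studies."""

    direction: str
    per_study: dict[str, set[str]]
    consensus: set[str]
    removed_conflicts: set[str]
    venn_counts: dict[tuple[str, ...], int]
    lncrna_consensus: set[str] = field(default_factory=set)

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.per_study.values():
            out |= s
        return out


def build_overlap(
    studies: list[pd.DataFrame],
    direction: str,
    *,
    min_studies: int = 2,
    coding_only: bool = True,
    lfc_thresh: float = 0.5,
    padj_thresh: float = 0.05,
) -> OverlapSets:
    """Consensus set of genes moving in ``direction`` in >= min_studies.

    Genes moving in the opposite direction in *any* study are removed as
    conflicts. With ``coding_only`` the consensus keeps protein-coding genes;
    lncRNAs meeting the same consensus rule are retained in a side channel
    (``lncrna_consensus``) for sequence-level analysis.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    opposite = "down" if direction == "up" else "up"

    per_study: dict[str, set[str]] = {}
    opp_sets: dict[str, set[str]] = {}
    biotype: dict[str, str] = {}
    for i, table in enumerate(studies):
        _check_schema(table)
        name = (
            str(table["study"].iloc[0]) if "study" in table.columns else f"study{i+1}"
        )
        if table["gene_id"].duplicated().any():
            dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicated gene {dup!r} within study {name}")
        labels = classify_de(table, lfc_thresh, padj_thresh)
        per_study[name] = set(table.loc[labels == direction, "gene_id"])
        opp_sets[name] = set(table.loc[labels == opposite, "gene_id"])
        biotype.update(dict(zip(table["gene_id"], table["biotype"])))

    names = list(per_study)
    counts: dict[str, int] = {}
    for s in per_study.values():
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    conflicts = set().union(*opp_sets.values())

    union_dir = set(counts)
    candidates = {g for g, c in counts.items() if c >= min_studies}
    consensus_all = candidates - conflicts
    lnc = {g for g in consensus_all if biotype.get(g) == "lncRNA"}
    if coding_only:
        consensus = {g for g in consensus_all if biotype.get(g) == "protein_coding"}
    else:
        consensus = consensus_all
    # any gene moving both ways across studies is a conflict, whether or
    # not it reached the consensus count
    removed = union_dir & conflicts

    venn: dict[tuple[str, ...], int] = {}
    union = set().union(*per_study.values())
    for g in union:
        key = tuple(n for n in names if g in per_study[n])
        venn[key] = venn.get(key, 0) + 1
    return OverlapSets(direction, per_study, consensus, removed, venn, lnc)


def target_mirna_counts(target_map: pd.DataFrame) -> pd.Series:
    """Distinct targeting miRNAs per gene from a (gene, mirna, sites) map."""
    if target_map.empty:
        raise ValueError("target map is empty")
    return target_map.groupby("gene_id")["mirna"].nunique()


def target_fraction(
    gene_set: set[str], target_map: pd.DataFrame, min_mirnas: int = 1
) -> tuple[float, int]:
    """Fraction (and count) of the set targeted by >= min_mirnas miRNAs."""
    if not gene_set:
        raise ValueError("gene set is empty; targeted fraction undefined")
    counts = target_mirna_counts(target_map)
    hits = counts.reindex(list(gene_set), fill_value=0)
    k = int((hits >= min_mirnas).sum())
    return k / len(gene_set), k


def hypergeom_enrichment(k: int, n: int, K: int, N: int) -> dict:
    """Exact over/under-representation p-values and fold enrichment.

    ``k`` annotated genes observed in a size-``n`` set drawn from a universe
    of ``N`` genes of which ``K`` are annotated.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(
            f"impossible counts: k={k}, n={n}, K={K}, N={N} "
            "(need 0 <= k <= min(n, K), n <= N, K <= N)"
        )
    if k < n - (N - K):  # fewer hits than forced by the unannotated pool
        raise ValueError(
            f"impossible counts: a size-{n} set from N={N}, K={K} must "
            f"contain at least {n - (N - K)} annotated genes, got k={k}"
        )
    rv = stats.hypergeom(N, K, n)
    p_over = float(rv.sf(k - 1))
    p_under = float(rv.cdf(k))
    expected = n * K / N
    fold = (k / n) / (K / N) if n > 0 and K > 0 else float("nan")
    return {
        "p_over": p_over,
        "p_under": p_under,
        "fold": fold,
        "expected": expected,
    }


@dataclass
class EnrichmentResult:
    observed_fraction: float
    observed_count: int
    set_size: int
    null_mean: float
    null_sd: float
    empirical_p: float
    normal_approx_p: float
    z: float
    hypergeom_p_over: float
    hypergeom_p_under: float
    fold: float
    iters: int
    null_fractions: np.ndarray | None = None


def permutation_enrichment(
    observed_set: set[str],
    universe: set[str],
    target_map: pd.DataFrame,
    *,
    min_mirnas: int = 2,
    iters: int = 10_000,
    seed: int = 0,
    return_null: bool = False,
) -> EnrichmentResult:
    """Permutation test of the targeted fraction of a gene set.

    Draws ``iters`` random subsets of ``|observed_set|`` genes without
    replacement from ``universe`` and recomputes the fraction targeted by at
    least ``min_mirnas`` miRNAs. ``empirical_p`` uses the add-one rule
    ``(1 + #{null >= observed}) / (iters + 1)``. Iterations are generated in
    child-seeded blocks of fixed width, so the null stream depends only on
    ``seed`` (a run with more iterations extends, never reshuffles, a
    shorter one).
    """
    if not observed_set <= universe:
        raise ValueError("observed set must be a subset of the universe")
    if len(observed_set) > len(universe):
        raise ValueError("observed set larger than universe")
    if iters < 100:
        raise ValueError("iters must be >= 100")
    if not observed_set:
        raise ValueError("observed set is empty")

    genes = np.array(sorted(universe))
    counts = target_mirna_counts(target_map)
    targeted = (
        counts.reindex(genes, fill_value=0).to_numpy() >= min_mirnas
    )
    k = len(observed_set)
    obs_idx = np.isin(genes, list(observed_set))
    obs_count = int(targeted[obs_idx].sum())
    obs_frac = obs_count / k

    n = genes.size
    block_width = 1000
    null_counts = np.empty(iters, dtype=np.int64)
    done = 0
    block = 0
    while done < iters:
        b = min(block_width, iters - done)
        rng = np.random.default_rng([seed, block])
        keys = rng.random((b, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null_counts[done : done + b] = targeted[idx].sum(axis=1)
        done += b
        block += 1

    null_fracs = null_counts / k
    null_mean = float(null_fracs.mean())
    null_sd = float(null_fracs.std(ddof=1))
    empirical_p = (1 + int((null_counts >= obs_count).sum())) / (iters + 1)
    if null_sd > 0:
        z = (obs_frac - null_mean) / null_sd
        normal_p = float(stats.norm.sf(z))
    else:
        z = float("nan")
        normal_p = 1.0 if obs_frac <= null_mean else 0.0

    hyp = hypergeom_enrichment(
        obs_count, k, int(targeted.sum()), n
    )
    return EnrichmentResult(
        observed_fraction=obs_frac,
        observed_count=obs_count,
        set_size=k,
        null_mean=null_mean,
        null_sd=null_sd,
        empirical_p=empirical_p,
        normal_approx_p=normal_p,
        z=float(z),
        hypergeom_p_over=hyp["p_over"],
        hypergeom_p_under=hyp["p_under"],
        fold=(obs_frac / null_mean) if null_mean > 0 else float("nan"),
        iters=iters,
        null_fractions=null_fracs if return_null else None,
    )
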