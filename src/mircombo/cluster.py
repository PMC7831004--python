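"""Shared-target matrices and hierarchical clustering of miRNA families.

Families (miRNA seed families with their predicted target sets) are compared
by pairwise target overlap and clustered hierarchically. Each family is
embedded as a binary membership vector over the genes shared by at least two
families, and Ward linkage on Euclidean distances builds the dendrogram. The
pairwise overlap percentage is normalised by the smaller set by default
(``min``), with Jaccard and mean-size normalisations available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def families_from_long(table: pd.DataFrame) -> dict[str, set[str]]:
    """family -> target set from a long (family, gene_id) table."""
    return {
        str(fam): set(sub["gene_id"]) for fam, sub in table.groupby("family")
    }


def read_gmt(path) -> dict[str, set[str]]:
    """GMT-like TSV: family, optional description, then gene ids."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            out[parts[0]] = {g for g in parts[1:] if g}
    return out


def filter_families(
    families: dict[str, set[str]], min_targets: int = 1000
) -> tuple[dict[str, set[str]], set[str]]:
    """Keep families with >= min_targets targets; also return the genes
    shared by at least two retained families."""
    kept = {f: set(t) for f, t in families.items() if len(t) >= min_targets}
    if not kept:
        warnings.warn(
            f"no family has >= {min_targets} targets; result is empty",
            stacklevel=2,
        )
        return {}, set()
    count: dict[str, int] = {}
    for targets in kept.values():
        for g in targets:
            count[g] = count.get(g, 0) + 1
    shared = {g for g, c in count.items() if c >= 2}
    return kept, shared


@dataclass
class SharedTargetMatrix:
    families: list[str]
    overlap_counts: np.ndarray  # symmetric int; diagonal = set sizes
    overlap_pct: np.ndarray  # symmetric, 0-100
    normalization: str

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.overlap_counts, index=self.families, columns=self.families
        )

    def pct_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.overlap_pct, index=self.families, columns=self.families
        )


def shared_matrix(
    families: dict[str, set[str]], *, normalization: str = "min"
) -> SharedTargetMatrix:
    """Pairwise overlap counts and percentages between family target sets.

    ``overlap_pct[i, j] = 100 * |T_i & T_j| / norm`` where ``norm`` is the
    smaller set size (default), the union (``jaccard``) or the mean size.
    """
    if not families:
        raise ValueError("need at least one family")
    labels = sorted(families)
    sets = [families[f] for f in labels]
    m = len(labels)
    counts = np.zeros((m, m), dtype=int)
    pct = np.zeros((m, m))
    for i in range(m):
        counts[i, i] = len(sets[i])
        pct[i, i] = 100.0
        for j in range(i + 1, m):
            inter = len(sets[i] & sets[j])
            counts[i, j] = counts[j, i] = inter
            if normalization == "min":
                denom = min(len(sets[i]), len(sets[j]))
            elif normalization == "jaccard":
                denom = len(sets[i] | sets[j])
            elif normalization == "mean":
                denom = 0.5 * (len(sets[i]) + len(sets[j]))
            else:
                raise ValueError(f"unknown normalization {normalization!r}")
            pct[i, j] = pct[j, i] = 100.0 * inter / denom if denom else 0.0
    return SharedTargetMatrix(labels, counts, pct, normalization)


@dataclass
class ClusterResult:
    families: list[str]
    linkage: np.ndarray  # scipy linkage matrix, canonically ordered
    heights: np.ndarray
    flat: dict[str, int] | None  # family -> cluster id at requested k
    degenerate: bool  # all embedding vectors identical
    bootstrap_support: float | None = None


def _embed(
    families: dict[str, set[str]], labels: list[str]
) -> tuple[np.ndarray, list[str]]:
    count: dict[str, int] = {}
    for f in labels:
        for g in families[f]:
            count[g] = count.get(g, 0) + 1
    shared_genes = sorted(g for g, c in count.items() if c >= 2)
    if not shared_genes:  # no shared structure: fall back to all targets
        shared_genes = sorted(set().union(*(families[f] for f in labels)))
    mat = np.zeros((len(labels), len(shared_genes)))
    gene_idx = {g: i for i, g in enumerate(shared_genes)}
    for r, f in enumerate(labels):
        for g in families[f]:
            j = gene_idx.get(g)
            if j is not None:
                mat[r, j] = 1.0
    return mat, shared_genes


def cluster_families(
    families: dict[str, set[str]],
    *,
    method: str = "ward",
    metric: str = "euclidean",
    k: int | None = None,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> ClusterResult:
    """Hierarchically cluster families on binary shared-target vectors.

    Families are embedded over the genes shared by >= 2 families and merged
    by Ward linkage on Euclidean distances. Labels are processed in sorted
    order so the tree is independent of input ordering. With ``k`` a flat
    partition is cut; with ``n_bootstrap > 0`` the support of that partition
    is estimated by resampling embedding columns with replacement.
    """
    if len(families) < 2:
        raise ValueError("need at least two families to cluster")
    labels = sorted(families)
    mat, _genes = _embed(families, labels)
    degenerate = bool(np.all(mat == mat[0]))
    if degenerate:
        warnings.warn(
            "all family vectors identical; dendrogram is a zero-height chain",
            stacklevel=2,
        )
    dist = pdist(mat, metric=metric)
    z = hierarchy.linkage(dist, method=method)
    z = z[:, :4].copy()

    flat = None
    if k is not None:
        assign = hierarchy.fcluster(z, t=k, criterion="maxclust")
        flat = dict(zip(labels, (int(a) for a in assign)))

    support = None
    if n_bootstrap > 0 and k is not None:
        rng = np.random.default_rng(seed)
        ref = _canonical_partition([flat[f] for f in labels])
        hits = 0
        ncols = mat.shape[1]
        for _ in range(n_bootstrap):
            cols = rng.integers(0, ncols, size=ncols)
            bz = hierarchy.linkage(pdist(mat[:, cols], metric=metric), method=method)
            ba = hierarchy.fcluster(bz, t=k, criterion="maxclust")
            if _canonical_partition(list(ba)) == ref:
                hits += 1
        support = hits / n_bootstrap

    return ClusterResult(
        families=labels,
        linkage=z,
        heights=z[:, 2].copy(),
        flat=flat,
        degenerate=degenerate,
        bootstrap_support=support,
    )


def _canonical_partition(assign: list[int]) -> tuple[int, ...]:
    """Relabel cluster ids by first appearance so partitions compare
    independently of arbitrary numbering."""
    mapping: dict[int, int] = {}
    out = []
    for a in assign:
        if a not in mapping:
            mapping[a] = len(mapping)
        out.append(mapping[a])
    return tuple(out)


def to_newick(result: ClusterResult) -> str:
    """Newick string of the dendrogram with merge heights as branch lengths."""
    tree = hierarchy.to_tree(result.linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{result.families[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def merge_table(result: ClusterResult) -> pd.DataFrame:
    """Tidy merge list: children indices and heights, leaf-count per merge."""
    z = result.linkage
    return pd.DataFrame(
        {
            "merge": np.arange(1, z.shape[0] + 1),
            "child1": z[:, 0].astype(int),
            "child2": z[:, 1].astype(int),
            "height": z[:, 2],
            "n_leaves": z[:, 3].astype(int),
        }
    )
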