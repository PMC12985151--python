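"""Genetic distances, UPGMA dendrograms, and matrix comparison.

The distance between two multilocus SSR profiles is the allele-sharing
distance ``1 - shared_alleles / (2 * loci_compared)`` (Dps-style), with loci
missing in either sample skipped pairwise.  Trees are built by UPGMA
(size-weighted average linkage) and serialized as newick with ultrametric
node heights (a pair at distance d joins at height d/2).  Two distance
matrices over the same samples are compared by cophenetic correlation and a
one-sided permutation Mantel test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .identity import genotype_mismatch_count
from .model import GenotypeTable

__all__ = ["MantelResult", "allele_sharing_distance", "upgma", "to_newick",
           "cophenetic_distances", "cophenetic_correlation", "mantel_test"]


def allele_sharing_distance(table: GenotypeTable) -> DistanceMatrix:
    """Pairwise allele-sharing distance over a consolidated table.

    ``d(i,j) = 1 - sum_loci |multiset intersection| / (2 * loci_compared)``;
    identical profiles are at 0 and fully disjoint profiles at 1.  A pair
    with no comparable loci has no defined distance and raises.
    """
    n = len(table)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mm, loci = genotype_mismatch_count(table.row(i), table.row(j))
            if loci == 0:
                raise ValueError(
                    f"no comparable loci between {table.samples[i]!r} and "
                    f"{table.samples[j]!r}")
            shared = 2 * loci - mm
            d[i, j] = d[j, i] = 1.0 - shared / (2 * loci)
    return DistanceMatrix(d, ids=table.samples)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """UPGMA tree with ultrametric heights; ties broken deterministically by
    agglomerating over lexicographically sorted labels."""
    order = np.argsort(np.asarray(dm.ids, dtype=object))
    ids = [dm.ids[i] for i in order]
    data = dm.data[np.ix_(order, order)]
    z = hierarchy.average(squareform(data, checks=False))

    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in ids]
    heights = [0.0] * len(ids)
    for a, b, dist, _ in z:
        h = dist / 2.0
        left, right = nodes[int(a)], nodes[int(b)]
        left.length = h - heights[int(a)]
        right.length = h - heights[int(b)]
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
        heights.append(h)
    root = nodes[-1]
    root.length = None
    return root


def to_newick(tree: TreeNode) -> str:
    return str(tree)  # skbio writes newick with branch lengths


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    return tree.tip_tip_distances()


def _aligned_condensed(d1: DistanceMatrix, d2: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must share the same label set")
    d2 = d2.filter(d1.ids)
    return (squareform(d1.data, checks=False), squareform(d2.data, checks=False))


def cophenetic_correlation(dm: DistanceMatrix, tree: TreeNode) -> float:
    """Pearson correlation between a distance matrix and a tree's cophenetic
    distances, aligned by label.  Degenerate (constant) vectors raise."""
    v1, v2 = _aligned_condensed(dm, cophenetic_distances(tree))
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("cophenetic correlation undefined for constant distances")
    return float(np.corrcoef(v1, v2)[0, 1])


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
                seed: int = 0) -> MantelResult:
    """One-sided ("greater") permutation Mantel test.

    r is the Pearson correlation of the lower triangles;
    ``p = (1 + #{r* >= r}) / (1 + n_perm)`` with rows and columns of the
    second matrix permuted jointly.  Reproducible for a given seed.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must share the same label set")
    d2 = d2.filter(d1.ids)
    v1 = squareform(d1.data, checks=False)
    m2 = d2.data
    r_obs = float(np.corrcoef(v1, squareform(m2, checks=False))[0, 1])

    rng = np.random.default_rng(seed)
    n = m2.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        v2p = squareform(m2[np.ix_(perm, perm)], checks=False)
        if np.corrcoef(v1, v2p)[0, 1] >= r_obs:
            hits += 1
    return MantelResult(r=r_obs, p=(1 + hits) / (1 + n_perm), n_perm=n_perm, seed=seed)
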