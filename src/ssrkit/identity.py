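"""Clone, synonym and misidentification detection; deduplication.

Two multilocus profiles are compared allele-by-allele: at each locus scored
in both samples the mismatch contribution is ``2 - |multiset intersection|``
of the two allele pairs, so a shared heterozygote contributes 0, one shared
allele contributes 1, and disjoint genotypes contribute 2.  Pairs totalling
0 mismatching alleles are treated as the same genotype (clones / synonyms);
pairs differing by only one or two alleles are near-matches — reported for
curatorial review but never merged automatically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .model import GenotypeCall, GenotypeTable

__all__ = ["MatchReport", "CloneCluster", "genotype_mismatch_count",
           "pairwise_reports", "find_duplicates", "deduplicate"]


def _classify(mismatches: int) -> str:
    return {0: "identical", 1: "near-1", 2: "near-2"}.get(mismatches, "distinct")


@dataclass(frozen=True)
class MatchReport:
    sample_a: str
    sample_b: str
    mismatching_alleles: int
    loci_compared: int
    low_confidence: bool  # fewer than half the panel's loci were comparable

    @property
    def match_class(self) -> str:
        return _classify(self.mismatching_alleles)


@dataclass
class CloneCluster:
    members: list[str]
    representative: str
    profile: dict[str, GenotypeCall] = field(default_factory=dict)


def genotype_mismatch_count(row_a: Mapping[str, GenotypeCall],
                            row_b: Mapping[str, GenotypeCall]) -> tuple[int, int]:
    """Allele-level mismatch count and number of loci compared.

    Loci missing in either profile are skipped; homozygous-null genotypes
    compare as ordinary (0,0) calls, so two null homozygotes match.
    """
    shared = set(row_a) & set(row_b)
    if not shared:
        return 0, 0
    mismatches = 0
    for m in shared:
        ca, cb = Counter(row_a[m].alleles), Counter(row_b[m].alleles)
        overlap = sum((ca & cb).values())
        mismatches += 2 - overlap
    return mismatches, len(shared)


def pairwise_reports(table: GenotypeTable) -> list[MatchReport]:
    """Mismatch report for every unordered sample pair (consolidated table)."""
    n_panel = len(table.panel)
    out = []
    for i in range(len(table)):
        for j in range(i + 1, len(table)):
            mm, loci = genotype_mismatch_count(table.row(i), table.row(j))
            out.append(MatchReport(table.samples[i], table.samples[j], mm, loci,
                                   low_confidence=loci < 0.5 * n_panel))
    return out


def find_duplicates(table: GenotypeTable, max_mismatch: int = 0,
                    ) -> tuple[list[CloneCluster], list[MatchReport]]:
    """Single-linkage clusters of samples within ``max_mismatch`` alleles.

    Returns only multi-member clusters, ordered by first appearance, along
    with the full pairwise report.  At threshold 0 the clusters are exact
    genotype-identity classes.
    """
    reports = pairwise_reports(table)
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(range(len(table)))
    index = {s: i for i, s in reversed(list(enumerate(table.samples)))}
    for r in reports:
        if r.loci_compared > 0 and r.mismatching_alleles <= max_mismatch:
            g.add_edge(index[r.sample_a], index[r.sample_b])
    clusters = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        idx = sorted(comp)
        rep = idx[0]
        clusters.append(CloneCluster(
            members=[table.samples[i] for i in idx],
            representative=table.samples[rep],
            profile=dict(table.row(rep)),
        ))
    clusters.sort(key=lambda c: table.samples.index(c.representative))
    return clusters, reports


def deduplicate(table: GenotypeTable) -> tuple[GenotypeTable, list[CloneCluster]]:
    """One row per exact-identity (0-mismatch) cluster.

    The representative is the first member in input order.  Near-matches
    (1-2 alleles apart) remain distinct rows; they appear in the pairwise
    reports of :func:`find_duplicates` for human review.  Idempotent.
    """
    clusters, _ = find_duplicates(table, max_mismatch=0)
    drop: set[str] = set()
    for c in clusters:
        drop.update(c.members[1:])
    keep = [s for s in table.samples if s not in drop]
    return table.subset(keep), clusters
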