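"""Exhaustive Mendelian parent-pair search under zero trio mismatches.

A candidate parent pair (sex unknown, selfing permitted) is compatible with
an offspring at a locus when the offspring's allele pair can be split as one
allele from each parent.  A trio's mismatch count is the number of fully
scored loci failing that test; the search keeps pairs with zero mismatches —
a strict exclusion criterion with no tolerance for genotyping error.

Compatible pairs can be ranked by a likelihood-ratio LOD: per locus,
log10 of the Mendelian transmission probability of the offspring genotype
given the parents over its Hardy-Weinberg probability from population
allele frequencies, summed over scored loci (no genotyping-error model).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .model import GenotypeCall, GenotypeTable
from .popgen import AlleleFrequencies, allele_frequencies, marker_stats

__all__ = ["TrioResult", "ParentageSummary", "locus_compatible", "trio_mismatch",
           "search_parent_pairs", "lod_score", "parentage_summary"]


@dataclass(frozen=True)
class TrioResult:
    offspring: str
    parent_a: str
    parent_b: str
    mismatch_loci: int
    lod: float | None = None

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.parent_a, self.parent_b))


def _usable(call: GenotypeCall | None) -> bool:
    return call is not None and not call.is_null


def locus_compatible(o: GenotypeCall, p: GenotypeCall, q: GenotypeCall) -> bool:
    """True iff the offspring pair can be one allele from p plus one from q."""
    a, b = o.alleles
    return ((a in p.alleles and b in q.alleles)
            or (b in p.alleles and a in q.alleles))


def trio_mismatch(offspring: Mapping[str, GenotypeCall],
                  p: Mapping[str, GenotypeCall],
                  q: Mapping[str, GenotypeCall],
                  loci: Sequence[str] | None = None) -> int:
    """Count of loci with complete data in all three members that fail the
    Mendelian test.  Loci missing or homozygous-null in any member are
    skipped (null alleles would otherwise fabricate exclusions)."""
    if loci is None:
        loci = list(offspring)
    n = 0
    for m in loci:
        o, cp, cq = offspring.get(m), p.get(m), q.get(m)
        if not (_usable(o) and _usable(cp) and _usable(cq)):
            continue
        if not locus_compatible(o, cp, cq):
            n += 1
    return n


def _mendel_prob(o: GenotypeCall, p: GenotypeCall, q: GenotypeCall) -> float:
    """P(offspring genotype | parents) by enumerating the four equally
    likely gamete combinations."""
    hits = sum(GenotypeCall.of(x, y) == o for x in p.alleles for y in q.alleles)
    return hits / 4.0


def _hwe_prob(o: GenotypeCall, freqs: AlleleFrequencies) -> float:
    a, b = o.alleles
    pa = freqs.freqs.get(a, 0.0)
    pb = freqs.freqs.get(b, 0.0)
    return pa * pb * (2.0 if a != b else 1.0)


def lod_score(offspring: Mapping[str, GenotypeCall],
              p: Mapping[str, GenotypeCall],
              q: Mapping[str, GenotypeCall],
              freqs: Mapping[str, AlleleFrequencies]) -> float:
    """Sum over loci of log10[P(o | p, q, Mendelian) / P(o | HWE)].

    Only loci with complete data in all trio members and available
    frequencies contribute; a zero HWE probability (offspring allele absent
    from the frequency table) is an inconsistency and raises."""
    total = 0.0
    for m, fr in freqs.items():
        o, cp, cq = offspring.get(m), p.get(m), q.get(m)
        if not (_usable(o) and _usable(cp) and _usable(cq)):
            continue
        trans = _mendel_prob(o, cp, cq)
        if trans == 0.0:
            return -math.inf
        hwe = _hwe_prob(o, fr)
        if hwe <= 0.0:
            raise ValueError(
                f"offspring genotype at {m} has zero HWE probability under the "
                "supplied frequencies")
        total += math.log10(trans / hwe)
    return total


def _clone_lookup(clone_clusters) -> dict[str, str]:
    lookup: dict[str, str] = {}
    for c in clone_clusters or []:
        for member in c.members:
            lookup[member] = c.representative
    return lookup


def search_parent_pairs(table: GenotypeTable, offspring: str, *,
                        allow_selfing: bool = True,
                        exclude: set[str] | None = None,
                        freqs: Mapping[str, AlleleFrequencies] | None = None,
                        clone_clusters=None,
                        loci_order: Sequence[str] | None = None,
                        max_pairs: int | None = None) -> list[TrioResult]:
    """All candidate parent pairs with zero trio mismatches for one offspring.

    The offspring itself is never a candidate parent; with ``allow_selfing``
    a single other sample may serve as both parents.  When frequencies are
    supplied, results carry LOD scores and are ranked by descending LOD.
    Pairs identical up to clone-cluster membership are collapsed to the
    cluster representatives and reported once.
    """
    if offspring not in table.samples:
        raise KeyError(offspring)
    exclude = set(exclude or ())
    o_row = table.row_by_name(offspring)
    candidates = [s for s in table.samples if s != offspring and s not in exclude]
    loci = list(loci_order) if loci_order is not None else table.panel.marker_names
    rep = _clone_lookup(clone_clusters)

    results: list[TrioResult] = []
    seen_pairs: set[frozenset[str]] = set()
    n = len(candidates)
    for i in range(n):
        p_name = candidates[i]
        p_row = table.row_by_name(p_name)
        start = i if allow_selfing else i + 1
        for j in range(start, n):
            q_name = candidates[j]
            q_row = table.row_by_name(q_name)
            ok = True
            for m in loci:  # early exit on first mismatching locus
                o, cp, cq = o_row.get(m), p_row.get(m), q_row.get(m)
                if not (_usable(o) and _usable(cp) and _usable(cq)):
                    continue
                if not locus_compatible(o, cp, cq):
                    ok = False
                    break
            if not ok:
                continue
            key = frozenset((rep.get(p_name, p_name), rep.get(q_name, q_name)))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            lod = lod_score(o_row, p_row, q_row, freqs) if freqs is not None else None
            a, b = sorted((p_name, q_name))
            results.append(TrioResult(offspring, a, b, 0, lod))
    if freqs is not None:
        results.sort(key=lambda t: (-(t.lod if t.lod is not None else -math.inf),
                                    t.parent_a, t.parent_b))
    if max_pairs is not None:
        results = results[:max_pairs]
    return results


@dataclass
class ParentageSummary:
    """Collection-wide zero-mismatch parentage results.

    ``histogram`` maps the number of compatible pairs per offspring to how
    many offspring had that count (mass at 0 = unresolved offspring);
    counts are after clone collapsing when clusters were supplied.
    """

    pairs_per_offspring: dict[str, list[TrioResult]]
    histogram: dict[int, int]
    n_offspring_with_pair: int
    mean_pairs_per_resolved: float
    total_pairs: int


def parentage_summary(table: GenotypeTable, *, allow_selfing: bool = True,
                      clone_clusters=None, with_lod: bool = False,
                      max_pairs: int | None = None,
                      order_loci_by_pic: bool = True) -> ParentageSummary:
    """Run the zero-mismatch search for every sample as putative offspring.

    Loci are screened in descending-PIC order so incompatible pairs are
    rejected on the most informative loci first (early exit).
    """
    loci = table.panel.marker_names
    if order_loci_by_pic:
        by_pic = {m: marker_stats(table, m).pic for m in loci}
        loci = sorted(loci, key=lambda m: -by_pic[m])
    freqs = None
    if with_lod:
        freqs = {m: allele_frequencies(table, m) for m in table.panel.marker_names}

    per: dict[str, list[TrioResult]] = {}
    for s in table.samples:
        per[s] = search_parent_pairs(table, s, allow_selfing=allow_selfing,
                                     freqs=freqs, clone_clusters=clone_clusters,
                                     loci_order=loci, max_pairs=max_pairs)
    histogram = dict(Counter(len(v) for v in per.values()))
    resolved = [v for v in per.values() if v]
    total = sum(len(v) for v in per.values())
    return ParentageSummary(
        pairs_per_offspring=per,
        histogram=dict(sorted(histogram.items())),
        n_offspring_with_pair=len(resolved),
        mean_pairs_per_resolved=(total / len(resolved)) if resolved else 0.0,
        total_pairs=total,
    )
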