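"""Per-marker and panel-level SSR diversity statistics.

Implemented measures, all computed from population allele proportions
``p_i`` at a locus:

* ``He`` — Nei gene diversity ``1 - sum(p_i^2)`` (default, "biased" form;
  an unbiased small-sample correction ``n/(n-1)`` over gene copies is
  available by flag),
* ``PIC`` — Botstein polymorphic information content
  ``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``,
* ``Ae`` — effective number of alleles ``1 / sum(p_i^2)``,
* ``PI`` — probability of identity, the chance two independent
  Hardy-Weinberg genotypes at the locus coincide:
  ``sum(p_i^4) + sum_{i<j} (2 p_i p_j)^2``; across a panel of independent
  loci the total ``PI_t`` is the product of per-locus values,
* Shannon's information index ``-sum(p_i ln p_i)`` (natural log),
* allelic richness by hypergeometric rarefaction to ``g`` gene copies,
* a null-allele rate from the heterozygote deficit, Chakraborty's
  ``(He - Ho) / (He + Ho)`` by default or Brookfield's
  ``(He - Ho) / (1 + He)`` by flag.

Homozygous-null genotypes (no amplification) contribute no observable
alleles: they are excluded from frequency denominators and from the
observed-heterozygosity denominator.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .model import GenotypeTable, Panel

__all__ = [
    "AlleleFrequencies", "MarkerStats", "PanelStats", "SubsetResult",
    "allele_frequencies", "observed_heterozygosity", "expected_heterozygosity",
    "pic", "effective_alleles", "probability_identity", "shannon_index",
    "null_allele_estimate", "allelic_richness", "marker_stats",
    "panel_summary", "subset_stats", "summarize_marker_stats",
]


@dataclass(frozen=True)
class AlleleFrequencies:
    """Population allele proportions at one marker."""

    marker: str
    freqs: dict[int, float]
    n_gene_copies: int

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.freqs.values()):
            raise ValueError("all allele proportions must be > 0")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele proportions must sum to 1, got {total}")

    @property
    def k(self) -> int:
        return len(self.freqs)

    @property
    def p(self) -> list[float]:
        return list(self.freqs.values())


def allele_frequencies(table: GenotypeTable, marker: str) -> AlleleFrequencies:
    """Empirical allele proportions; each called allele counts one gene copy.

    Homozygous-null calls are excluded entirely (they contribute no
    observable gene copies); a half-null call contributes its one called
    allele.
    """
    if marker not in table.panel:
        raise KeyError(f"marker {marker!r} not in panel")
    counts: Counter[int] = Counter()
    for i in range(len(table)):
        call = table.row(i).get(marker)
        if call is None:
            continue
        counts.update(call.called_alleles)
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"no called alleles at marker {marker!r}")
    freqs = {a: c / n for a, c in sorted(counts.items())}
    return AlleleFrequencies(marker, freqs, n)


def observed_heterozygosity(table: GenotypeTable, marker: str) -> float:
    """Fraction of scored individuals carrying two different alleles.

    Homozygous-null individuals are excluded from the denominator.
    """
    if marker not in table.panel:
        raise KeyError(f"marker {marker!r} not in panel")
    het = tot = 0
    for i in range(len(table)):
        call = table.row(i).get(marker)
        if call is None or call.is_null:
            continue
        tot += 1
        het += call.is_heterozygous
    if tot == 0:
        raise ValueError(f"no non-null calls at marker {marker!r}")
    return het / tot


def expected_heterozygosity(freqs: AlleleFrequencies, unbiased: bool = False) -> float:
    he = 1.0 - sum(p * p for p in freqs.p)
    if unbiased:
        n = freqs.n_gene_copies
        if n < 2:
            raise ValueError("unbiased He needs at least 2 gene copies")
        he *= n / (n - 1)
    return he


def pic(freqs: AlleleFrequencies) -> float:
    p = freqs.p
    sum_p2 = sum(x * x for x in p)
    cross = sum(2.0 * p[i] ** 2 * p[j] ** 2
                for i in range(len(p)) for j in range(i + 1, len(p)))
    return 1.0 - sum_p2 - cross


def effective_alleles(freqs: AlleleFrequencies) -> float:
    return 1.0 / sum(p * p for p in freqs.p)


def probability_identity(freqs: AlleleFrequencies) -> float:
    """Per-locus probability that two independent HWE genotypes coincide."""
    p = freqs.p
    return (sum(x ** 4 for x in p)
            + sum((2.0 * p[i] * p[j]) ** 2
                  for i in range(len(p)) for j in range(i + 1, len(p))))


def shannon_index(freqs: AlleleFrequencies) -> float:
    return -sum(p * math.log(p) for p in freqs.p)


def null_allele_estimate(ho: float, he: float, method: str = "chakraborty") -> float | None:
    """Heterozygote-deficit null-allele rate; negative values are permitted
    (an excess of heterozygotes). Returns None when undefined (Ho = He = 0)."""
    if not (0 <= ho <= 1 and 0 <= he <= 1):
        raise ValueError("Ho and He must be proportions")
    if method == "chakraborty":
        if he + ho == 0:
            return None
        return (he - ho) / (he + ho)
    if method == "brookfield":
        return (he - ho) / (1.0 + he)
    raise ValueError(f"unknown null-allele estimator {method!r}")


def _allele_counts(table: GenotypeTable, marker: str) -> Counter[int]:
    counts: Counter[int] = Counter()
    for i in range(len(table)):
        call = table.row(i).get(marker)
        if call is not None:
            counts.update(call.called_alleles)
    return counts


def allelic_richness(table: GenotypeTable, marker: str, g: int) -> float:
    """Expected allele count in a random subsample of ``g`` gene copies.

    Hypergeometric rarefaction: ``k - sum_a C(N - N_a, g) / C(N, g)`` with
    ``N`` total gene copies and ``N_a`` copies of allele ``a``.
    """
    counts = _allele_counts(table, marker)
    n_total = sum(counts.values())
    if n_total == 0:
        raise ValueError(f"no called alleles at marker {marker!r}")
    if not 1 <= g <= n_total:
        raise ValueError(f"rarefaction size g={g} outside [1, {n_total}]")
    denom = math.comb(n_total, g)
    return len(counts) - sum(math.comb(n_total - na, g) for na in counts.values()) / denom


@dataclass(frozen=True)
class MarkerStats:
    marker: str
    k: int
    n: int                       # individuals with a non-null called genotype
    ho: float
    he: float
    pic: float
    ae: float
    pi: float
    shannon: float
    richness: float | None
    null_rate: float | None
    min_len: int
    max_len: int


def marker_stats(table: GenotypeTable, marker: str, *, unbiased_he: bool = False,
                 richness_g: int | None = None,
                 null_method: str = "chakraborty") -> MarkerStats:
    """All per-marker statistics from one frequency pass."""
    freqs = allele_frequencies(table, marker)
    ho = observed_heterozygosity(table, marker)
    he = expected_heterozygosity(freqs, unbiased=unbiased_he)
    rich = None
    if richness_g is not None:
        rich = allelic_richness(table, marker, richness_g)
    n_ind = sum(1 for i in range(len(table))
                if (c := table.row(i).get(marker)) is not None and not c.is_null)
    alleles = list(freqs.freqs)
    return MarkerStats(
        marker=marker,
        k=freqs.k,
        n=n_ind,
        ho=ho,
        he=he,
        pic=pic(freqs),
        ae=effective_alleles(freqs),
        pi=probability_identity(freqs),
        shannon=shannon_index(freqs),
        richness=rich,
        null_rate=null_allele_estimate(ho, expected_heterozygosity(freqs), null_method),
        min_len=min(alleles),
        max_len=max(alleles),
    )


_AVG_FIELDS = ("k", "ho", "he", "pic", "ae", "pi", "shannon", "richness", "null_rate")


@dataclass(frozen=True)
class PanelStats:
    """Per-marker statistics plus panel aggregates.

    ``pi_total`` is the product of per-marker probabilities of identity
    (independent loci); ``averages`` are arithmetic means over markers.
    """

    per_marker: tuple[MarkerStats, ...]
    averages: dict[str, float]
    pi_total: float

    def to_dataframe(self):
        import pandas as pd

        rows = [{
            "marker": s.marker, "k": s.k, "n": s.n, "Ho": s.ho, "He": s.he,
            "PIC": s.pic, "Ae": s.ae, "PI": s.pi, "Shannon": s.shannon,
            "richness": s.richness, "null_rate": s.null_rate,
            "min_len": s.min_len, "max_len": s.max_len,
        } for s in self.per_marker]
        return pd.DataFrame(rows)


def summarize_marker_stats(per_marker: Sequence[MarkerStats]) -> PanelStats:
    """Aggregate per-marker statistics: arithmetic means and the product
    of per-locus probabilities of identity."""
    if not per_marker:
        raise ValueError("no marker statistics to summarize")
    averages: dict[str, float] = {}
    for f in _AVG_FIELDS:
        vals = [getattr(s, f) for s in per_marker if getattr(s, f) is not None]
        if vals:
            averages[f] = sum(vals) / len(vals)
    pi_total = math.prod(s.pi for s in per_marker)
    return PanelStats(tuple(per_marker), averages, pi_total)


def panel_summary(table: GenotypeTable, panel: Panel | None = None, *,
                  unbiased_he: bool = False, richness_g: int | None = None,
                  rarefy_to_min: bool = False,
                  null_method: str = "chakraborty") -> PanelStats:
    """Statistics for every marker of the panel plus aggregates.

    With ``rarefy_to_min`` allelic richness is rarefied to the smallest
    per-marker gene-copy count.
    """
    panel = panel or table.panel
    g = richness_g
    if g is None and rarefy_to_min:
        g = min(sum(_allele_counts(table, m).values()) for m in panel.marker_names)
    stats = [marker_stats(table, m, unbiased_he=unbiased_he, richness_g=g,
                          null_method=null_method)
             for m in panel.marker_names]
    return summarize_marker_stats(stats)


@dataclass(frozen=True)
class SubsetResult:
    stats: PanelStats
    #: marker -> alleles present in the full table but absent from the subset
    allele_losses: dict[str, list[int]]


def subset_stats(table: GenotypeTable, members: Sequence[str], **kwargs) -> SubsetResult:
    """Panel statistics restricted to a sample subset, e.g. an inbred family
    defined by ancestry-fraction membership, with per-marker allele losses
    relative to the full table."""
    if len(members) == 0:
        raise ValueError("empty subset")
    sub = table.subset(members)
    stats = panel_summary(sub, **kwargs)
    losses: dict[str, list[int]] = {}
    for m in table.panel.marker_names:
        full = set(_allele_counts(table, m))
        kept = set(_allele_counts(sub, m))
        lost = sorted(full - kept)
        if lost:
            losses[m] = lost
    return SubsetResult(stats, losses)
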