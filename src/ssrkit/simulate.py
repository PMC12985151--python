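"""Synthetic diploid SSR data with the statistical structure the analysis
assumes: Hardy-Weinberg populations from Dirichlet-drawn allele frequencies,
Mendelian crosses and multi-generation founder-restricted pedigrees, plus
injection of the artifacts real fragment-analysis data carries (hidden null
alleles, planted clones, replicate typos).

Allele lengths live on a motif-length lattice (base + m * motif length), so
simulated spectra look like real SSR ladders.  Every stochastic operation
takes an explicit seed and is fully reproducible (numpy PCG64).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import NULL_ALLELE, GenotypeCall, GenotypeTable, MarkerDef, Panel
from .popgen import AlleleFrequencies, pic

__all__ = ["SimConfig", "max_pic", "simulate_frequencies", "simulate_panel_frequencies",
           "simulate_population", "simulate_cross", "simulate_founder_population",
           "inject_artifacts", "PedigreeRecord", "ArtifactLog"]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated SSR study."""

    n_markers: int = 16
    alleles_per_marker: tuple[int, int] = (4, 12)   # inclusive range for k
    concentration: float = 1.0                      # Dirichlet concentration
    target_pic: float | None = None
    n_samples: int = 100
    null_allele_rate: float = 0.0
    replicate_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.null_allele_rate, self.replicate_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


def max_pic(k: int) -> float:
    """PIC of k equifrequent alleles — the maximum attainable with k alleles."""
    freqs = AlleleFrequencies("_", {100 + 2 * i: 1.0 / k for i in range(k)}, 2 * k)
    return pic(freqs)


def _lattice(k: int, motif_len: int, base_len: int) -> list[int]:
    return [base_len + m * motif_len for m in range(k)]


def simulate_frequencies(k: int, concentration: float = 1.0, *,
                         target_pic: float | None = None, seed: int = 0,
                         motif_len: int = 2, base_len: int = 100,
                         marker: str = "sim", tol: float = 0.02,
                         max_tries: int = 100_000) -> AlleleFrequencies:
    """Dirichlet-distributed allele frequencies over k lattice lengths.

    With ``target_pic`` draws are rejection-sampled until the realized PIC is
    within ``tol`` of the target; a target above the k-allele maximum raises.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    lengths = _lattice(k, motif_len, base_len)
    if k == 1:
        return AlleleFrequencies(marker, {lengths[0]: 1.0}, 2)
    if target_pic is not None:
        ceiling = max_pic(k)
        if target_pic > ceiling + tol:
            raise ValueError(
                f"target PIC {target_pic} unattainable with k={k} alleles "
                f"(maximum {ceiling:.4f} at equifrequency)")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        p = rng.dirichlet([concentration] * k)
        if p.min() <= 0:
            continue
        freqs = AlleleFrequencies(marker, dict(zip(lengths, map(float, p))), 2 * k)
        if target_pic is None or abs(pic(freqs) - target_pic) <= tol:
            return freqs
    raise RuntimeError(f"no draw within {tol} of target PIC {target_pic} "
                       f"after {max_tries} tries")


def simulate_panel_frequencies(config: SimConfig) -> dict[str, AlleleFrequencies]:
    """One frequency vector per marker, named M01..Mnn, seeded from config."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.alleles_per_marker
    out: dict[str, AlleleFrequencies] = {}
    for i in range(config.n_markers):
        name = f"M{i + 1:02d}"
        k = int(rng.integers(lo, hi + 1))
        sub = int(rng.integers(0, 2**31))
        out[name] = simulate_frequencies(
            k, config.concentration, target_pic=config.target_pic,
            seed=sub, marker=name, base_len=100 + 30 * i)
    return out


def _panel_from_freqs(freqs: Mapping[str, AlleleFrequencies]) -> Panel:
    return Panel.of([MarkerDef(name=m) for m in freqs], name="simulated")


def simulate_population(freqs: Mapping[str, AlleleFrequencies], n: int,
                        seed: int = 0, *, prefix: str = "S") -> GenotypeTable:
    """n unrelated Hardy-Weinberg individuals: each genotype is two
    independent draws from the marker's allele-frequency vector."""
    rng = np.random.default_rng(seed)
    samples = [f"{prefix}{i + 1:04d}" for i in range(n)]
    rows: list[dict[str, GenotypeCall]] = [{} for _ in range(n)]
    for m, fr in freqs.items():
        alleles = np.array(list(fr.freqs))
        p = np.array(list(fr.freqs.values()))
        draws = rng.choice(alleles, size=(n, 2), p=p / p.sum())
        for i in range(n):
            rows[i][m] = GenotypeCall.of(int(draws[i, 0]), int(draws[i, 1]))
    return GenotypeTable(samples, _panel_from_freqs(freqs), rows)


def simulate_cross(p_row: Mapping[str, GenotypeCall],
                   q_row: Mapping[str, GenotypeCall],
                   n_offspring: int, seed: int = 0, *,
                   mutation_rate: float = 0.0, motif_len: int = 2,
                   ) -> list[dict[str, GenotypeCall]]:
    """Mendelian offspring of two fully genotyped parents: per locus one
    uniformly chosen allele from each parent, with optional single-step
    (+-1 repeat unit) mutations at ``mutation_rate`` per transmitted allele."""
    loci = [m for m in p_row if m in q_row]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_offspring):
        row: dict[str, GenotypeCall] = {}
        for m in loci:
            a = p_row[m].alleles[rng.integers(0, 2)]
            b = q_row[m].alleles[rng.integers(0, 2)]
            if mutation_rate > 0.0:
                if rng.random() < mutation_rate:
                    a += motif_len * (1 if rng.random() < 0.5 else -1)
                if rng.random() < mutation_rate:
                    b += motif_len * (1 if rng.random() < 0.5 else -1)
            row[m] = GenotypeCall.of(int(a), int(b))
        out.append(row)
    return out


@dataclass(frozen=True)
class PedigreeRecord:
    child: str
    parent_a: str
    parent_b: str


def simulate_founder_population(founders: GenotypeTable, n_generations: int,
                                pop_size: int, seed: int = 0, *,
                                selfing_allowed: bool = True,
                                mutation_rate: float = 0.0,
                                ) -> tuple[GenotypeTable, list[PedigreeRecord]]:
    """Closed breeding population descending from the founders.

    Each generation is formed by random crosses among the previous one
    (a breeding bottleneck: the allele pool can only shrink).  The returned
    table holds founders plus every generation; the pedigree records each
    child's parents.
    """
    if len(founders) < 1:
        raise ValueError("at least one founder required")
    if len(founders) == 1 and not selfing_allowed:
        raise ValueError("a single founder requires selfing")
    rng = np.random.default_rng(seed)
    samples = list(founders.samples)
    rows = [dict(founders.row(i)) for i in range(len(founders))]
    pedigree: list[PedigreeRecord] = []

    prev = list(range(len(samples)))
    for gen in range(1, n_generations + 1):
        current: list[int] = []
        for j in range(pop_size):
            pi = int(rng.integers(0, len(prev)))
            if selfing_allowed:
                qi = int(rng.integers(0, len(prev)))
            else:
                qi = pi
                while qi == pi:
                    qi = int(rng.integers(0, len(prev)))
            p_idx, q_idx = prev[pi], prev[qi]
            child_row = simulate_cross(rows[p_idx], rows[q_idx], 1,
                                       seed=int(rng.integers(0, 2**31)),
                                       mutation_rate=mutation_rate)[0]
            name = f"G{gen}_{j + 1:03d}"
            samples.append(name)
            rows.append(child_row)
            current.append(len(samples) - 1)
            pedigree.append(PedigreeRecord(name, samples[p_idx], samples[q_idx]))
        prev = current
    return GenotypeTable(samples, founders.panel, rows), pedigree


@dataclass
class ArtifactLog:
    """Ground truth of injected artifacts, for planted-truth recovery tests."""

    null_alleles: dict[str, list[tuple[str, GenotypeCall]]] = field(default_factory=dict)
    clones: dict[str, list[str]] = field(default_factory=dict)   # original -> copies
    typos: list[tuple[str, str, GenotypeCall, GenotypeCall]] = field(default_factory=list)


def inject_artifacts(table: GenotypeTable, *, null_allele_rate: float = 0.0,
                     replicate_error_rate: float = 0.0,
                     clone_spec: Mapping[str, int] | None = None,
                     seed: int = 0, motif_len: int = 2,
                     ) -> tuple[GenotypeTable, ArtifactLog]:
    """Overlay data artifacts on a clean table; the truth log records them.

    * hidden null allele: each transmitted allele independently becomes null
      at ``null_allele_rate``; a heterozygote with one null appears
      homozygous for its visible allele, a double null appears as a
      no-amplification (homozygous-null) genotype;
    * clones: ``clone_spec`` maps a sample to the number of extra copies of
      its row appended under derived names (``<name>__dupN``);
    * replicate typos: each call is replaced, at ``replicate_error_rate``,
      by a one-repeat-unit slip in one allele.
    """
    rng = np.random.default_rng(seed)
    log = ArtifactLog()
    samples = list(table.samples)
    rows = [dict(table.row(i)) for i in range(len(table))]

    for i, label in enumerate(samples):
        for m, call in list(rows[i].items()):
            a, b = call.alleles
            changed = False
            if null_allele_rate > 0.0:
                if rng.random() < null_allele_rate:
                    a, changed = NULL_ALLELE, True
                if rng.random() < null_allele_rate:
                    b, changed = NULL_ALLELE, True
            if changed:
                log.null_alleles.setdefault(m, []).append((label, call))
                if a == NULL_ALLELE and b == NULL_ALLELE:
                    rows[i][m] = GenotypeCall.of(NULL_ALLELE, NULL_ALLELE)
                else:
                    vis = b if a == NULL_ALLELE else a
                    rows[i][m] = GenotypeCall.of(vis, vis)  # appears homozygous
                continue
            if replicate_error_rate > 0.0 and rng.random() < replicate_error_rate:
                slip = motif_len * (1 if rng.random() < 0.5 else -1)
                new = GenotypeCall.of(a + slip, b)
                log.typos.append((label, m, call, new))
                rows[i][m] = new

    if clone_spec:
        for label, n_copies in clone_spec.items():
            src = table.samples.index(label)
            for c in range(n_copies):
                name = f"{label}__dup{c + 1}"
                samples.append(name)
                rows.append(dict(rows[src]))
                log.clones.setdefault(label, []).append(name)
    return GenotypeTable(samples, table.panel, rows), log
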