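"""Candidate-SSR filtering and one-reaction multiplex panel design.

Candidates (motif, repeat-tract length, sequence-resolved allele spectrum,
mapping failures across the sequenced cohort) are screened by conjunctive
quality criteria; survivors are assembled into a single-PCR panel where each
marker occupies one (fluorescent dye x amplicon size window) slot, with at
most two markers per chromosome separated by a minimum distance to avoid
genetic linkage.

Default criteria: at most 2 mapping failures in the cohort; at least three
alleles; repeat tract at most 60 nt (longer tracts stutter badly); no allele
above frequency 0.5; sequence-based PIC of at least 0.8 / 0.7 / 0.6 for
di- / tri- / longer-motif repeats.  Default slot grid: four dyes by four
nominal windows 100-150, 200-250, 300-350, 400-450 nt; default linkage
threshold 1 Mbp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .model import MarkerDef

__all__ = ["CandidateSSR", "SelectionCriteria", "Verdict", "filter_candidates",
           "check_linkage_distance", "PanelDesign", "design_multiplex",
           "validate_design", "DEFAULT_DYES", "DEFAULT_WINDOWS"]

DEFAULT_DYES = ("6-FAM", "VIC", "NED", "PET")
DEFAULT_WINDOWS = ((100, 150), (200, 250), (300, 350), (400, 450))


@dataclass(frozen=True)
class CandidateSSR:
    """A candidate marker as reported by sequence-based STR discovery."""

    name: str
    chromosome: str
    position_bp: int | None
    motif: str
    pic_seq: float                      # PIC on sequence-distinct alleles
    allele_freqs: Mapping[int, float] | None = None
    repeat_length_nt: int | None = None  # total repeat-tract length
    map_failures: int = 0
    n_samples: int = 0
    expected_size_range: tuple[int, int] | None = None
    quality: float | None = None        # score used by the designer; defaults to pic_seq

    @property
    def n_alleles(self) -> int | None:
        return len(self.allele_freqs) if self.allele_freqs is not None else None

    @property
    def score(self) -> float:
        return self.quality if self.quality is not None else self.pic_seq


@dataclass(frozen=True)
class SelectionCriteria:
    max_map_failures: int = 2
    min_alleles: int = 3
    max_repeat_length_nt: int = 60
    max_allele_freq: float = 0.5
    #: motif length -> minimum sequence-based PIC; lengths above the largest
    #: key fall back to the largest key's threshold
    pic_thresholds: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.8, 3: 0.7, 4: 0.6})

    def pic_threshold(self, motif_len: int) -> float:
        if motif_len in self.pic_thresholds:
            return self.pic_thresholds[motif_len]
        return self.pic_thresholds[max(self.pic_thresholds)]


@dataclass(frozen=True)
class Verdict:
    name: str
    passed: bool
    failed_criteria: tuple[str, ...]


def filter_candidates(candidates: Sequence[CandidateSSR],
                      criteria: SelectionCriteria = SelectionCriteria(),
                      ) -> tuple[list[CandidateSSR], list[Verdict]]:
    """Pure conjunction of the quality criteria; a candidate passes iff all
    applicable criteria hold.  Criteria whose inputs are absent from the
    record (e.g. no allele spectrum) are not applied."""
    passing, verdicts = [], []
    for c in candidates:
        failed: list[str] = []
        if c.map_failures > criteria.max_map_failures:
            failed.append("max_map_failures")
        if c.n_alleles is not None and c.n_alleles < criteria.min_alleles:
            failed.append("min_alleles")
        if (c.repeat_length_nt is not None
                and c.repeat_length_nt > criteria.max_repeat_length_nt):
            failed.append("max_repeat_length")
        if (c.allele_freqs is not None
                and max(c.allele_freqs.values()) > criteria.max_allele_freq):
            failed.append("max_allele_freq")
        if c.pic_seq < criteria.pic_threshold(len(c.motif)):
            failed.append("min_pic")
        verdicts.append(Verdict(c.name, not failed, tuple(failed)))
        if not failed:
            passing.append(c)
    return passing, verdicts


@dataclass(frozen=True)
class LinkageViolation:
    marker_a: str
    marker_b: str
    chromosome: str
    distance_bp: int


def check_linkage_distance(markers: Sequence[MarkerDef | CandidateSSR],
                           min_distance_bp: int = 1_000_000) -> list[LinkageViolation]:
    """Same-chromosome marker pairs closer than the linkage threshold.

    Markers without a known position are skipped (legacy markers mapped on
    other references)."""
    out = []
    placed = [m for m in markers if m.position_bp is not None and m.chromosome]
    for a, b in combinations(placed, 2):
        if a.chromosome != b.chromosome:
            continue
        dist = abs(a.position_bp - b.position_bp)
        if dist < min_distance_bp:
            out.append(LinkageViolation(a.name, b.name, a.chromosome, dist))
    return out


@dataclass
class PanelDesign:
    """Assignment of markers to (dye, window) multiplex slots."""

    slots: dict[tuple[str, tuple[int, int]], str]
    unassigned: dict[str, str] = field(default_factory=dict)  # marker -> reason
    warnings: list[str] = field(default_factory=list)

    @property
    def assigned_markers(self) -> list[str]:
        return list(self.slots.values())


class InfeasibleDesign(RuntimeError):
    """Raised when the requested number of markers cannot be slotted."""


def _fits(size_range: tuple[int, int] | None, window: tuple[int, int],
          guard: int) -> tuple[bool, int]:
    """(fits-with-guard, excursion-nt) of an expected size range vs a window."""
    if size_range is None:
        return True, 0
    lo, hi = size_range
    wlo, whi = window
    excursion = max(0, wlo - lo) + max(0, hi - whi)
    return lo >= wlo + guard and hi <= whi - guard, excursion


def validate_design(markers: Sequence[MarkerDef],
                    observed_ranges: Mapping[str, tuple[int, int]] | None = None,
                    *, min_distance_bp: int = 1_000_000, guard_nt: int = 5,
                    max_per_chromosome: int = 2,
                    ) -> tuple[list[str], list[str]]:
    """Check a finished panel against the multiplex constraints.

    Returns (errors, warnings).  Errors: duplicate (dye, window) slots,
    overlapping observed size ranges within one dye, more than the allowed
    markers per chromosome, and same-chromosome pairs closer than the
    linkage threshold.  Size-range excursions beyond a nominal window are
    warnings only — the windows are approximate guides, and unambiguous
    scoring needs separation within a dye, not strict window containment.
    """
    errors, warnings = [], []
    observed_ranges = observed_ranges or {}

    seen_slots: dict[tuple[str, tuple[int, int]], str] = {}
    for m in markers:
        if not m.dye or m.size_window is None:
            errors.append(f"{m.name}: no (dye, window) slot assigned")
            continue
        key = (m.dye, m.size_window)
        if key in seen_slots:
            errors.append(f"slot {key} assigned to both {seen_slots[key]} and {m.name}")
        seen_slots[key] = m.name

    # observed fragment ranges within one dye must not overlap
    by_dye: dict[str, list[MarkerDef]] = {}
    for m in markers:
        if m.dye:
            by_dye.setdefault(m.dye, []).append(m)
    for dye, ms in by_dye.items():
        ranged = [(m.name, observed_ranges[m.name]) for m in ms if m.name in observed_ranges]
        for (na, ra), (nb, rb) in combinations(ranged, 2):
            if ra[0] <= rb[1] and rb[0] <= ra[1]:
                errors.append(f"dye {dye}: size ranges of {na} {ra} and {nb} {rb} overlap")

    for m in markers:
        rng = observed_ranges.get(m.name)
        if rng is not None and m.size_window is not None:
            fits, exc = _fits(rng, m.size_window, guard_nt)
            if not fits and exc > 0:
                warnings.append(
                    f"{m.name}: observed range {rng} leaves nominal window "
                    f"{m.size_window} by {exc} nt")

    by_chrom: dict[str, int] = {}
    for m in markers:
        if m.chromosome:
            by_chrom[m.chromosome] = by_chrom.get(m.chromosome, 0) + 1
    for chrom, n in sorted(by_chrom.items()):
        if n > max_per_chromosome:
            errors.append(f"chromosome {chrom}: {n} markers (max {max_per_chromosome})")

    for v in check_linkage_distance(list(markers), min_distance_bp):
        errors.append(f"chromosome {v.chromosome}: {v.marker_a} and {v.marker_b} "
                      f"only {v.distance_bp:,} bp apart (< {min_distance_bp:,})")
    return errors, warnings


def design_multiplex(candidates: Sequence[CandidateSSR],
                     dyes: Sequence[str] = DEFAULT_DYES,
                     windows: Sequence[tuple[int, int]] = DEFAULT_WINDOWS,
                     *, fixed: Mapping[tuple[str, tuple[int, int]], CandidateSSR] | None = None,
                     min_distance_bp: int = 1_000_000, guard_nt: int = 5,
                     max_per_chromosome: int = 2,
                     require_full: bool = False) -> PanelDesign:
    """Greedy-then-repair assignment of markers to (dye x window) slots.

    Candidates are taken in descending quality score; each is placed into a
    free slot whose window accommodates its expected size range (with the
    guard margin), subject to the per-chromosome cap and the linkage
    distance.  A local repair pass then tries to swap unassigned candidates
    into slots held by lower-scoring markers.  Deterministic given input
    order.  ``fixed`` pre-assigns legacy markers to slots; the designer
    fills around them.  With ``require_full`` an incomplete grid raises
    :class:`InfeasibleDesign` instead of returning a partial design.
    """
    windows = [tuple(w) for w in windows]
    slots: dict[tuple[str, tuple[int, int]], str] = {}
    by_name: dict[str, CandidateSSR] = {}
    chrom_members: dict[str, list[CandidateSSR]] = {}
    unassigned: dict[str, str] = {}

    def can_place(c: CandidateSSR) -> str | None:
        """Reason the candidate cannot be placed anywhere, else None."""
        members = chrom_members.get(c.chromosome, [])
        if len(members) >= max_per_chromosome:
            return f"chromosome {c.chromosome} already has {max_per_chromosome} markers"
        for other in members:
            if c.position_bp is not None and other.position_bp is not None:
                d = abs(c.position_bp - other.position_bp)
                if d < min_distance_bp:
                    return (f"only {d:,} bp from {other.name} "
                            f"(< {min_distance_bp:,} bp linkage threshold)")
        return "no free compatible (dye, window) slot"

    def place(c: CandidateSSR) -> bool:
        members = chrom_members.get(c.chromosome, [])
        if len(members) >= max_per_chromosome:
            return False
        for other in members:
            if (c.position_bp is not None and other.position_bp is not None
                    and abs(c.position_bp - other.position_bp) < min_distance_bp):
                return False
        for w in windows:
            fits, _ = _fits(c.expected_size_range, w, guard_nt)
            if not fits:
                continue
            for dye in dyes:
                key = (dye, w)
                if key not in slots:
                    slots[key] = c.name
                    by_name[c.name] = c
                    chrom_members.setdefault(c.chromosome, []).append(c)
                    return True
        return False

    if fixed:
        for key, c in fixed.items():
            if key in slots:
                raise ValueError(f"fixed slot {key} assigned twice")
            slots[key] = c.name
            by_name[c.name] = c
            chrom_members.setdefault(c.chromosome, []).append(c)

    ranked = sorted(candidates, key=lambda c: -c.score)
    for c in ranked:
        if c.name in by_name:
            continue
        if not place(c):
            unassigned[c.name] = can_place(c)

    # repair: a stranded candidate may displace a strictly lower-scoring
    # same-chromosome holder whose slot it can occupy
    fixed_names = {c.name for c in (fixed or {}).values()}
    for name in list(unassigned):
        c = next(x for x in candidates if x.name == name)
        for key, held_name in list(slots.items()):
            if held_name in fixed_names:
                continue
            held = by_name[held_name]
            if held.score >= c.score:
                continue
            fits, _ = _fits(c.expected_size_range, key[1], guard_nt)
            if not fits:
                continue
            del slots[key]
            chrom_members[held.chromosome].remove(held)
            del by_name[held_name]
            if place(c):
                del unassigned[name]
                if not place(held):
                    unassigned[held_name] = "displaced during repair"
                break
            slots[key] = held_name  # revert
            by_name[held_name] = held
            chrom_members.setdefault(held.chromosome, []).append(held)

    design = PanelDesign(slots=slots, unassigned=unassigned)
    if require_full and len(slots) < len(dyes) * len(windows):
        raise InfeasibleDesign(
            f"only {len(slots)} of {len(dyes) * len(windows)} slots filled; "
            f"unassigned: {unassigned}")
    return design
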