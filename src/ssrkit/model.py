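"""Core data model and I/O for diploid SSR genotype tables and marker panels.

An SSR (microsatellite) genotype is scored as a pair of amplicon lengths in
nucleotides. Three states are distinguished per sample and marker:

* a called genotype — two positive allele lengths (a homozygote carries the
  same length twice);
* a homozygous-null genotype — the marker failed to amplify in that sample,
  recorded with the null sentinel ``0`` for both alleles.  This is a real
  observation (a null/null individual), not absent data;
* missing data — the sample was simply not scored at that marker.

The on-disk dialect is a wide CSV/TSV with a ``sample`` column followed by two
columns per marker named ``<marker>_1`` and ``<marker>_2``.  Empty cells mean
missing; the literal null token (default ``"0"``) means a null allele.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Sentinel allele length for a null (non-amplifying) allele.
NULL_ALLELE = 0

VALID_MOTIF_LENGTHS = (2, 3, 4, 5, 6)


@dataclass(frozen=True, order=True)
class GenotypeCall:
    """Unordered diploid allele pair, stored canonically with ``a <= b``."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if self.a > self.b:
            raise ValueError(f"GenotypeCall not canonical: {self.a} > {self.b}; use GenotypeCall.of()")
        if self.a < 0 or self.b < 0:
            raise ValueError("allele lengths must be >= 0 (0 is the null sentinel)")

    @classmethod
    def of(cls, x: int, y: int) -> "GenotypeCall":
        """Build a canonical call from alleles in any order."""
        x, y = int(x), int(y)
        return cls(min(x, y), max(x, y))

    @property
    def alleles(self) -> tuple[int, int]:
        return (self.a, self.b)

    @property
    def is_heterozygous(self) -> bool:
        return self.a != self.b

    @property
    def is_null(self) -> bool:
        """True for a homozygous-null (no-amplification) genotype."""
        return self.a == NULL_ALLELE and self.b == NULL_ALLELE

    @property
    def called_alleles(self) -> tuple[int, ...]:
        """Alleles excluding the null sentinel."""
        return tuple(x for x in (self.a, self.b) if x != NULL_ALLELE)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"({self.a},{self.b})"


@dataclass(frozen=True)
class MarkerDef:
    """Definition of one SSR marker.

    ``position_bp`` is a 1-based coordinate on the reference genome named by
    the panel; ``None`` for legacy markers whose position on the working
    reference is unknown (linkage-distance checks skip those).
    ``size_window`` is the nominal (dye, size) multiplex slot window in nt.
    """

    name: str
    chromosome: str = ""
    position_bp: int | None = None
    motif: str = ""
    dye: str = ""
    size_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("marker name must be non-empty")
        if self.position_bp is not None and self.position_bp < 1:
            raise ValueError(f"{self.name}: position_bp must be >= 1 (1-based)")
        if self.motif and len(self.motif) not in VALID_MOTIF_LENGTHS:
            raise ValueError(f"{self.name}: motif length must be 2-6 nt, got {self.motif!r}")
        if self.size_window is not None and not self.size_window[0] < self.size_window[1]:
            raise ValueError(f"{self.name}: size window min must be < max")


@dataclass(frozen=True)
class Panel:
    """Ordered collection of markers genotyped together (one multiplex)."""

    markers: tuple[MarkerDef, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        dupes = [n for n, c in Counter(names).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate marker names in panel: {dupes}")

    @classmethod
    def of(cls, markers: Iterable[MarkerDef | str], name: str = "panel") -> "Panel":
        defs = tuple(m if isinstance(m, MarkerDef) else MarkerDef(name=m) for m in markers)
        return cls(defs, name)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(m.name == name for m in self.markers)


Row = Mapping[str, GenotypeCall]


class GenotypeTable:
    """Sample x marker matrix of unordered diploid allele-length pairs.

    Rows are positional; duplicate sample labels are permitted and denote
    biological replicates (see :func:`consolidate_replicates`).  A marker
    absent from a row's mapping is missing data for that sample.
    """

    def __init__(self, samples: Sequence[str], panel: Panel,
                 rows: Sequence[Mapping[str, GenotypeCall]]):
        if len(samples) != len(rows):
            raise ValueError("samples and rows must have equal length")
        marker_set = set(panel.marker_names)
        for label, row in zip(samples, rows):
            unknown = set(row) - marker_set
            if unknown:
                raise ValueError(f"row {label!r} references markers not in panel: {sorted(unknown)}")
        self.samples: list[str] = list(samples)
        self.panel = panel
        self._rows: list[dict[str, GenotypeCall]] = [dict(r) for r in rows]

    # -- access ---------------------------------------------------------
    def row(self, i: int) -> dict[str, GenotypeCall]:
        return self._rows[i]

    def row_by_name(self, sample: str) -> dict[str, GenotypeCall]:
        try:
            return self._rows[self.samples.index(sample)]
        except ValueError:
            raise KeyError(sample) from None

    def call(self, sample: str, marker: str) -> GenotypeCall | None:
        """Call for the first row labelled ``sample``; None when missing."""
        return self.row_by_name(sample).get(marker)

    def n_typed(self, marker: str) -> int:
        """Number of rows with a (possibly null) call at ``marker``."""
        if marker not in self.panel:
            raise KeyError(marker)
        return sum(1 for r in self._rows if marker in r)

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (self.samples == other.samples
                and self.panel.marker_names == other.panel.marker_names
                and self._rows == other._rows)

    def subset(self, samples: Sequence[str]) -> "GenotypeTable":
        """Table restricted to the given sample labels (first match each)."""
        missing = [s for s in samples if s not in self.samples]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        if len(samples) == 0:
            raise ValueError("empty sample subset")
        idx = [self.samples.index(s) for s in samples]
        return GenotypeTable([self.samples[i] for i in idx], self.panel,
                             [self._rows[i] for i in idx])

    # -- dataframe bridge ----------------------------------------------
    def to_dataframe(self, null_token: str = "0") -> pd.DataFrame:
        cols: dict[str, list[str]] = {"sample": list(self.samples)}
        for m in self.panel.marker_names:
            c1, c2 = [], []
            for r in self._rows:
                call = r.get(m)
                if call is None:
                    c1.append("")
                    c2.append("")
                else:
                    c1.append(null_token if call.a == NULL_ALLELE else str(call.a))
                    c2.append(null_token if call.b == NULL_ALLELE else str(call.b))
            cols[f"{m}_1"] = c1
            cols[f"{m}_2"] = c2
        return pd.DataFrame(cols)


def _parse_allele(text: str, null_token: str, where: str) -> int | None:
    text = text.strip()
    if text == "":
        return None
    if text == null_token:
        return NULL_ALLELE
    try:
        v = int(text)
    except ValueError:
        raise ValueError(f"non-integer allele {text!r} at {where}") from None
    if v <= 0:
        raise ValueError(f"allele length must be positive at {where}: {v}")
    return v


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_genotype_table(path: str | Path, panel: Panel | None = None, *,
                        sep: str | None = None, null_token: str = "0") -> GenotypeTable:
    """Read a wide genotype CSV/TSV into a :class:`GenotypeTable`.

    Expects a ``sample`` column then ``<marker>_1``/``<marker>_2`` pairs.
    When ``panel`` is given, every marker column must match a panel marker;
    otherwise a bare panel is inferred from the header.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str, keep_default_na=False)
    if df.columns[0] != "sample":
        raise ValueError(f"first column must be 'sample', got {df.columns[0]!r}")
    marker_cols = list(df.columns[1:])
    markers: list[str] = []
    for col in marker_cols:
        if not (col.endswith("_1") or col.endswith("_2")):
            raise ValueError(f"unknown genotype column {col!r}: expected '<marker>_1'/'<marker>_2'")
        base = col[:-2]
        if base not in markers:
            markers.append(base)
    for m in markers:
        if f"{m}_1" not in df.columns or f"{m}_2" not in df.columns:
            raise ValueError(f"marker {m!r} must have exactly two allele columns")
    if panel is None:
        panel = Panel.of(markers)
    else:
        unknown = [m for m in markers if m not in panel]
        if unknown:
            raise ValueError(f"genotype columns reference markers not in panel: {unknown}")

    samples: list[str] = []
    rows: list[dict[str, GenotypeCall]] = []
    for i, rec in df.iterrows():
        label = str(rec["sample"])
        row: dict[str, GenotypeCall] = {}
        for m in markers:
            where = f"row {label!r}, marker {m}"
            a = _parse_allele(str(rec[f"{m}_1"]), null_token, where)
            b = _parse_allele(str(rec[f"{m}_2"]), null_token, where)
            if (a is None) != (b is None):
                raise ValueError(f"odd allele count (one of two cells empty) at {where}")
            if a is not None and b is not None:
                row[m] = GenotypeCall.of(a, b)
        samples.append(label)
        rows.append(row)
    return GenotypeTable(samples, panel, rows)


def write_genotype_table(table: GenotypeTable, path: str | Path, *,
                         sep: str | None = None, null_token: str = "0") -> None:
    """Write the table so that ``read_genotype_table`` round-trips exactly."""
    path = Path(path)
    table.to_dataframe(null_token).to_csv(path, sep=_infer_sep(path, sep), index=False)


# -- panel files --------------------------------------------------------

PANEL_COLUMNS = ["name", "chromosome", "position_bp", "motif", "dye", "window_min", "window_max"]


def read_panel(path: str | Path, *, name: str | None = None) -> Panel:
    """Read a marker panel TSV (columns: name, chromosome, position_bp, motif,
    dye, window_min, window_max; empty cells for unknown fields)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file missing columns: {missing}")
    defs = []
    for _, rec in df.iterrows():
        pos = rec["position_bp"].replace(",", "").strip()
        wmin, wmax = rec["window_min"].strip(), rec["window_max"].strip()
        defs.append(MarkerDef(
            name=rec["name"],
            chromosome=rec["chromosome"].strip(),
            position_bp=int(pos) if pos else None,
            motif=rec["motif"].strip(),
            dye=rec["dye"].strip(),
            size_window=(int(wmin), int(wmax)) if wmin and wmax else None,
        ))
    return Panel(tuple(defs), name=name or path.stem)


def write_panel(panel: Panel, path: str | Path) -> None:
    recs = []
    for m in panel.markers:
        recs.append({
            "name": m.name,
            "chromosome": m.chromosome,
            "position_bp": "" if m.position_bp is None else str(m.position_bp),
            "motif": m.motif,
            "dye": m.dye,
            "window_min": "" if m.size_window is None else str(m.size_window[0]),
            "window_max": "" if m.size_window is None else str(m.size_window[1]),
        })
    pd.DataFrame(recs, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


# -- replicate consolidation -------------------------------------------


@dataclass
class ReplicateGroup:
    """Replicate rows sharing a sample label, with their consensus calls.

    ``conflicts`` maps a marker to the list of (call, multiplicity) pairs
    observed whenever replicates disagreed there; ``unresolved`` lists markers
    where the majority vote tied and the first-listed replicate's call won.
    """

    label: str
    member_indices: list[int]
    consensus: dict[str, GenotypeCall] = field(default_factory=dict)
    conflicts: dict[str, list[tuple[GenotypeCall, int]]] = field(default_factory=dict)
    unresolved: list[str] = field(default_factory=list)


def consolidate_replicates(table: GenotypeTable) -> tuple[GenotypeTable, list[ReplicateGroup]]:
    """Collapse replicate rows (shared sample label) to one prevailing row each.

    Per marker the majority call among replicates with data wins.  On a tie
    the call of the earliest-listed replicate carrying a tied call is used and
    the marker is flagged ``unresolved`` — deterministic and auditable, since
    a tie has no principled majority.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, label in enumerate(table.samples):
        if label not in groups:
            groups[label] = []
            order.append(label)
        groups[label].append(i)

    out_rows: list[dict[str, GenotypeCall]] = []
    reports: list[ReplicateGroup] = []
    for label in order:
        idx = groups[label]
        grp = ReplicateGroup(label=label, member_indices=list(idx))
        for m in table.panel.marker_names:
            calls = [(i, table.row(i)[m]) for i in idx if m in table.row(i)]
            if not calls:
                continue
            counts = Counter(c for _, c in calls)
            best_n = max(counts.values())
            winners = [c for c, n in counts.items() if n == best_n]
            if len(winners) == 1:
                winner = winners[0]
            else:
                # tie: first replicate in file order holding a tied call wins
                winner = next(c for _, c in calls if c in winners)
                grp.unresolved.append(m)
            grp.consensus[m] = winner
            if len(counts) > 1:
                grp.conflicts[m] = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out_rows.append(grp.consensus)
        reports.append(grp)
    return GenotypeTable(order, table.panel, out_rows), reports
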