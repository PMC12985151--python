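"""Bundled reference tables.

Small published summary tables ship with the package so the selection and
validation machinery can be exercised without access to the original
fragment-analysis data:

* the 30 novel sweet-cherry SSR candidates (position on the 'Tieton' v2.0
  reference, motif, sequence-based PIC, and fragment-analysis statistics
  from the 49-sample verification cohort);
* the 16in1 one-reaction panel layout (dye and nominal size-window slots;
  legacy markers carry no position on the working reference);
* per-marker summary statistics (k, Ho, He, PIC, Ae) published for the
  16in1 and ECPGR panels on the 294 unique genotypes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import MarkerDef, Panel
from .selection import CandidateSSR

__all__ = ["load_novel_candidates", "load_novel_marker_table", "load_panel_16in1",
           "load_observed_size_ranges", "load_published_stats"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("ssrkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t").fillna("")


def load_novel_marker_table() -> pd.DataFrame:
    """The 30 novel SSR candidates with discovery and verification statistics."""
    return _read("novel_ssr_markers.tsv")


def load_novel_candidates() -> list[CandidateSSR]:
    """Novel candidates as :class:`CandidateSSR` records.

    ``quality`` is the fragment-analysis PIC from the verification cohort,
    the score actually used to rank markers for multiplexing.
    """
    df = load_novel_marker_table()
    out = []
    for _, r in df.iterrows():
        out.append(CandidateSSR(
            name=r["name"],
            chromosome=str(r["chromosome"]),
            position_bp=int(r["position_bp"]),
            motif=r["motif"],
            pic_seq=float(r["pic_seq"]),
            expected_size_range=(int(r["min_len"]), int(r["max_len"])),
            quality=float(r["pic"]),
        ))
    return out


def load_panel_16in1() -> Panel:
    """The published 16-marker one-reaction panel with its slot layout."""
    defs = []
    for _, r in _read("panel_16in1.tsv").iterrows():
        pos = str(r["position_bp"]).strip()
        defs.append(MarkerDef(
            name=r["name"],
            chromosome=str(r["chromosome"]),
            position_bp=int(float(pos)) if pos else None,
            motif=str(r["motif"]),
            dye=r["dye"],
            size_window=(int(r["window_min"]), int(r["window_max"])),
        ))
    return Panel(tuple(defs), name="16in1")


def load_observed_size_ranges() -> dict[str, tuple[int, int]]:
    """Observed fragment-length extremes for the novel markers (verification
    cohort); legacy markers have no entry."""
    df = load_novel_marker_table()
    return {r["name"]: (int(r["min_len"]), int(r["max_len"]))
            for _, r in df.iterrows()}


def load_published_stats(panel: str = "16in1") -> pd.DataFrame:
    """Published per-marker k/Ho/He/PIC/Ae for ``"16in1"`` or ``"ecpgr"``."""
    key = panel.lower().replace("-", "")
    if key not in {"16in1", "ecpgr"}:
        raise ValueError(f"unknown panel {panel!r}")
    return _read(f"published_stats_{key}.tsv")
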