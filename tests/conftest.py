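from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from ssrkit.model import GenotypeCall, GenotypeTable, Panel

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_table(rows: dict[str, dict[str, tuple[int, int] | None]],
               markers: list[str] | None = None) -> GenotypeTable:
    """Build a table from {sample: {marker: (a, b) | None}}; None = missing."""
    if markers is None:
        markers = []
        for r in rows.values():
            for m in r:
                if m not in markers:
                    markers.append(m)
    panel = Panel.of(markers)
    samples, data = [], []
    for s, r in rows.items():
        samples.append(s)
        data.append({m: GenotypeCall.of(*v) for m, v in r.items() if v is not None})
    return GenotypeTable(samples, panel, data)


@pytest.fixture
def table_factory():
    return make_table
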