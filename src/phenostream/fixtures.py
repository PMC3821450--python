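"""Packaged reference datasets.

Two hand-coded study datasets ship with the package:

``unamuno_journal``
    A Spanish introspective journal excerpt evaluated by a panel of sixteen
    psychology students: 16 candidate boundaries with published per-boundary
    agreement indices, nine consensus segments, and a 9 × 7 mental-category
    attribution table with published high/low significance marks.  Judge-level
    marks were not published; the fixture reconstructs a deterministic
    synthetic panel whose column sums match the published indices (judges
    1..m mark boundary b, where m = round(index_b × 16)) — agreement indices
    depend on column sums only.  Published cells that no integer count can
    reproduce within rounding are stored with the nearest count and listed in
    the fixture's discrepancy report, never silently corrected.

``joyce_penelope``
    A 30-sentence interior-monolog excerpt hand-coded into four content lanes
    (sensations, emotions, thoughts, mental images) with binding of
    simultaneous contents, causal links, and seven micro-episodes.

All files are plain JSON/CSV under ``phenostream/data/`` and are regenerated
by ``scripts/build_fixtures.py``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .attribution import FlagMatrix
from .corpus import (
    AttributionProtocol,
    CodedStream,
    PhenomenologicalText,
    SegmentationProtocol,
    read_attribution_protocol,
    read_coded_stream,
    read_segmentation_protocol,
    read_text,
)

__all__ = [
    "FixtureBundle",
    "FIXTURE_NAMES",
    "load_fixture",
    "fixture_path",
    "round_half_up",
    "reconstruct_count",
    "count_discrepancies",
]

FIXTURE_NAMES = ("unamuno_journal", "joyce_penelope")

# A published proportion and an integer count k agree when |k/n - printed|
# does not exceed half of the last printed decimal place (inclusive, so that
# e.g. 0.125 -> "0.13" at n=16 is not a discrepancy).
COUNT_TOL = 0.005 + 1e-9


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def reconstruct_count(proportion: float, n: int) -> int:
    """Nearest integer count for a published proportion over denominator ``n``."""
    return round_half_up(proportion * n)


def count_discrepancies(
    printed: np.ndarray, counts: np.ndarray, n: np.ndarray, codes: list[str]
) -> list[dict]:
    """Cells where no integer count reproduces the published proportion.

    Returns one record per offending cell with the published value, the
    stored nearest count, and the implied proportion.
    """
    out = []
    for s in range(printed.shape[0]):
        for k in range(printed.shape[1]):
            implied = counts[s, k] / n[s]
            if abs(implied - printed[s, k]) > COUNT_TOL:
                out.append(
                    {
                        "segment": s + 1,
                        "category": codes[k],
                        "printed": float(printed[s, k]),
                        "stored_count": int(counts[s, k]),
                        "implied": round(float(implied), 4),
                    }
                )
    return out


@dataclass
class FixtureBundle:
    """Everything a packaged dataset provides, already parsed."""

    name: str
    text: PhenomenologicalText
    segmentation: SegmentationProtocol | None = None
    attribution: AttributionProtocol | None = None
    coded_stream: CodedStream | None = None
    printed_indices: dict[int, float] = field(default_factory=dict)
    printed_proportions: np.ndarray | None = None
    printed_flags: FlagMatrix | None = None
    label_map: dict[str, str] = field(default_factory=dict)
    discrepancies: list[dict] = field(default_factory=list)
    notes: dict = field(default_factory=dict)


def fixture_path(name: str) -> Path:
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return Path(str(resources.files("phenostream") / "data" / name))


def load_fixture(name: str) -> FixtureBundle:
    root = fixture_path(name)
    text = read_text(root / "text.json", format="json")
    if name == "joyce_penelope":
        stream = read_coded_stream(root / "stream.json")
        label_map = dict(
            pd.read_csv(root / "label_map.csv").itertuples(index=False, name=None)
        )
        return FixtureBundle(
            name=name, text=text, coded_stream=stream, label_map=label_map
        )

    segmentation = read_segmentation_protocol(root / "segmentation.csv", format="csv")
    attribution = read_attribution_protocol(root / "attribution.json", format="json")
    printed = json.loads((root / "printed.json").read_text(encoding="utf-8"))
    printed_indices = {int(b): float(v) for b, v in printed["agreement_indices"].items()}
    props = np.asarray(printed["table"]["proportions"], dtype=float)
    flags = FlagMatrix(
        scheme=attribution.scheme,
        segment_indices=list(range(1, props.shape[0] + 1)),
        flags=np.asarray(printed["table"]["flags"], dtype=object),
        alpha=float(printed["table"]["alpha"]),
        p0=None,
        source="printed",
        notes=dict(printed["table"].get("notes", {})),
    )
    return FixtureBundle(
        name=name,
        text=text,
        segmentation=segmentation,
        attribution=attribution,
        printed_indices=printed_indices,
        printed_proportions=props,
        printed_flags=flags,
        discrepancies=list(printed.get("discrepancies", [])),
        notes=dict(printed.get("notes", {})),
    )
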