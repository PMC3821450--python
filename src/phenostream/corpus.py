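"""Domain types and file IO for phenomenological texts, judge protocols, and coded streams.

A *phenomenological text* is a first-person verbal report of ongoing conscious
experience.  Panels of human judges produce two kinds of protocols over such a
text: segmentation marks (which candidate boundaries delimit distinct ideas)
and category attributions (which mental categories each consensus segment
expresses).  A *coded stream* is the hand-coded result: ordered segments, each
carrying one or more content labels mapped to a category scheme, plus
annotator-asserted causal links between consecutive segments.

Conventions
-----------
Token offsets are 0-based, half-open.  A candidate boundary ``b`` denotes the
inter-token gap *before* token ``b`` (i.e. between tokens ``b-1`` and ``b``),
with ``b`` in ``[1, n_tokens]``.  The terminal position ``b == n_tokens`` is a
legal candidate: judges may (and in practice do) mark the final line break of
an excerpt, and its agreement index enters the panel mean, but cutting there
never creates an extra segment.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Token",
    "PhenomenologicalText",
    "SegmentationProtocol",
    "Segment",
    "Category",
    "CategoryScheme",
    "AttributionProtocol",
    "Content",
    "StreamEntry",
    "CodedStream",
    "ValidationError",
    "tokenize",
    "unamuno_scheme",
    "joyce_scheme",
    "read_text",
    "write_text",
    "read_segmentation_protocol",
    "write_segmentation_protocol",
    "read_attribution_protocol",
    "write_attribution_protocol",
    "read_coded_stream",
    "write_coded_stream",
]

SCHEMA_TEXT = "phenostream/text-1"
SCHEMA_SEGMENTATION = "phenostream/segmentation-1"
SCHEMA_ATTRIBUTION = "phenostream/attribution-1"
SCHEMA_STREAM = "phenostream/coded-stream-1"

_TOKEN_RE = re.compile(r"\S+")


class ValidationError(ValueError):
    """Raised when a protocol or stream violates a structural invariant."""


# ---------------------------------------------------------------------------
# Text


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int  # half-open


def tokenize(raw: str) -> list[Token]:
    """Whitespace tokenization with character offsets into ``raw``."""
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(raw)]


@dataclass
class PhenomenologicalText:
    """A first-person report, tokenized, with candidate segment boundaries."""

    text_id: str
    language: str
    raw: str
    tokens: list[Token] = field(default_factory=list)
    candidate_boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tokens:
            self.tokens = tokenize(self.raw)
        if not self.tokens:
            raise ValidationError(f"text {self.text_id!r} contains no tokens")
        prev_end = -1
        for t in self.tokens:
            if not (0 <= t.start < t.end <= len(self.raw)):
                raise ValidationError(f"token offsets out of range: {t}")
            if t.start < prev_end:
                raise ValidationError(f"token offsets overlap or decrease at {t}")
            prev_end = t.end
        n = len(self.tokens)
        if not self.candidate_boundaries:
            self.candidate_boundaries = list(range(1, n))
        bs = self.candidate_boundaries
        if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
            raise ValidationError("candidate boundaries must be strictly increasing")
        if bs and (bs[0] < 1 or bs[-1] > n):
            raise ValidationError(
                f"candidate boundaries must lie in [1, {n}] (terminal gap included)"
            )

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    def span_text(self, first: int, last_exclusive: int) -> str:
        """Raw slice covering tokens ``[first, last_exclusive)``."""
        return self.raw[self.tokens[first].start : self.tokens[last_exclusive - 1].end]


@dataclass
class Segment:
    """One tile of a text partition (1-based ``index``, half-open token span)."""

    index: int
    token_span: tuple[int, int]
    text: str
    translation: str | None = None


# ---------------------------------------------------------------------------
# Segmentation protocol


@dataclass
class SegmentationProtocol:
    """Judges × candidate-boundary binary mark matrix.

    ``boundaries`` carries the candidate-boundary ids (inter-token positions)
    labelling the columns of ``marks``.
    """

    text_id: str
    judges: list[str]
    boundaries: list[int]
    marks: np.ndarray  # shape (J, B), entries in {0, 1}

    def __post_init__(self) -> None:
        self.marks = np.asarray(self.marks, dtype=int)
        if len(self.judges) == 0:
            raise ValidationError("segmentation protocol needs at least one judge")
        if self.marks.shape != (len(self.judges), len(self.boundaries)):
            raise ValidationError(
                f"marks shape {self.marks.shape} does not match "
                f"{len(self.judges)} judges x {len(self.boundaries)} boundaries"
            )
        if not np.isin(self.marks, (0, 1)).all():
            raise ValidationError("segmentation marks must be 0 or 1")

    @property
    def n_judges(self) -> int:
        return len(self.judges)

    def check_against(self, text: PhenomenologicalText) -> None:
        unknown = set(self.boundaries) - set(text.candidate_boundaries)
        if unknown:
            raise ValidationError(
                f"protocol references boundaries absent from text: {sorted(unknown)}"
            )


# ---------------------------------------------------------------------------
# Category schemes


@dataclass(frozen=True)
class Category:
    code: str
    name: str


@dataclass
class CategoryScheme:
    """Ordered mental-category codes, optionally coarsening a finer scheme.

    ``parent_map`` maps every code of a finer scheme onto a code of this one
    (e.g. the seven textbook categories onto the four plotting lanes).
    """

    name: str
    categories: list[Category]
    parent_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        codes = [c.code for c in self.categories]
        if len(set(codes)) != len(codes):
            raise ValidationError(f"duplicate category codes in scheme {self.name!r}")
        if self.parent_map is not None:
            bad = set(self.parent_map.values()) - set(codes)
            if bad:
                raise ValidationError(f"parent_map targets unknown codes: {sorted(bad)}")

    @property
    def codes(self) -> list[str]:
        return [c.code for c in self.categories]

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise ValidationError(f"unknown category {code!r} in scheme {self.name!r}") from None

    def map_code(self, fine_code: str) -> str:
        """Coarsen a finer scheme's code via ``parent_map`` (identity if absent)."""
        if self.parent_map is None or fine_code in self.codes:
            return fine_code
        try:
            return self.parent_map[fine_code]
        except KeyError:
            raise ValidationError(
                f"code {fine_code!r} has no parent in scheme {self.name!r}"
            ) from None


def unamuno_scheme() -> CategoryScheme:
    """The seven broad-spectrum mental categories handed to the judge panel."""
    names = [
        ("sensation", "Se"),
        ("perception", "Pr"),
        ("emotion", "Em"),
        ("thought", "Th"),
        ("image", "Im"),
        ("recall", "Re"),
        ("intention", "In"),
    ]
    return CategoryScheme("unamuno7", [Category(code, abbr) for code, abbr in names])


def joyce_scheme() -> CategoryScheme:
    """The four plotting lanes: sensations, emotions, thoughts, mental images.

    Thoughts include recollections and plans; images include fantasies.  The
    ``parent_map`` coarsens the seven-category scheme onto these lanes.
    """
    cats = [
        Category("S", "sensations"),
        Category("E", "emotions"),
        Category("T", "thoughts"),
        Category("I", "mental images"),
    ]
    parent = {
        "sensation": "S",
        "perception": "S",
        "emotion": "E",
        "thought": "T",
        "recall": "T",
        "intention": "T",
        "image": "I",
    }
    return CategoryScheme("joyce4", cats, parent_map=parent)


# ---------------------------------------------------------------------------
# Attribution protocol


@dataclass
class AttributionProtocol:
    """Per-segment, per-category attribution counts from a judge panel.

    ``n`` is the vector of per-segment recognition counts: how many judges
    identified and interpreted each segment at all.  Counts are taken over
    those judges only, never over the full panel.  The raw per-judge
    ``indicators`` tensor (J × S × K) and ``recognized`` matrix (J × S) are
    optional; when present, ``counts``/``n`` must equal their judge-sums.
    """

    text_id: str
    scheme: CategoryScheme
    n_judges: int
    n: np.ndarray  # (S,)
    counts: np.ndarray  # (S, K)
    judges: list[str] | None = None
    indicators: np.ndarray | None = None  # (J, S, K)
    recognized: np.ndarray | None = None  # (J, S)
    segment_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        S, K = self.counts.shape
        if K != len(self.scheme.codes):
            raise ValidationError(
                f"counts have {K} categories but scheme {self.scheme.name!r} "
                f"has {len(self.scheme.codes)}"
            )
        if self.n.shape != (S,):
            raise ValidationError("recognition vector length does not match counts rows")
        if not self.segment_indices:
            self.segment_indices = list(range(1, S + 1))
        if (self.n < 0).any() or (self.n > self.n_judges).any():
            raise ValidationError("recognition counts must lie in [0, n_judges]")
        if (self.counts < 0).any() or (self.counts > self.n[:, None]).any():
            raise ValidationError("attribution counts must satisfy 0 <= counts[s,k] <= n_s")
        if self.indicators is not None:
            self.indicators = np.asarray(self.indicators, dtype=int)
            if self.indicators.shape != (self.n_judges, S, K):
                raise ValidationError("indicator tensor shape must be (J, S, K)")
            if not np.isin(self.indicators, (0, 1)).all():
                raise ValidationError("indicators must be 0 or 1")
            if self.recognized is None:
                self.recognized = self.indicators.any(axis=2).astype(int)
            else:
                self.recognized = np.asarray(self.recognized, dtype=int)
                if self.recognized.shape != (self.n_judges, S):
                    raise ValidationError("recognized matrix shape must be (J, S)")
                if (self.indicators.sum(axis=2) > 0).astype(int).max(initial=0) and (
                    (self.indicators.any(axis=2) & ~self.recognized.astype(bool)).any()
                ):
                    raise ValidationError("judge attributed a segment they did not recognize")
            if not np.array_equal(self.indicators.sum(axis=0), self.counts):
                raise ValidationError("counts do not equal the judge-sum of indicators")
            if not np.array_equal(self.recognized.sum(axis=0), self.n):
                raise ValidationError("n does not equal the judge-sum of recognized")

    @classmethod
    def from_indicators(
        cls,
        text_id: str,
        scheme: CategoryScheme,
        indicators: np.ndarray,
        recognized: np.ndarray | None = None,
        judges: list[str] | None = None,
    ) -> "AttributionProtocol":
        indicators = np.asarray(indicators, dtype=int)
        J = indicators.shape[0]
        if recognized is None:
            recognized = indicators.any(axis=2).astype(int)
        recognized = np.asarray(recognized, dtype=int)
        return cls(
            text_id=text_id,
            scheme=scheme,
            n_judges=J,
            n=recognized.sum(axis=0),
            counts=indicators.sum(axis=0),
            judges=judges or [f"judge{j+1}" for j in range(J)],
            indicators=indicators,
            recognized=recognized,
        )

    @property
    def n_segments(self) -> int:
        return self.counts.shape[0]

    @property
    def unrecognized_segments(self) -> list[int]:
        """Segment indices no judge recognized (degenerate: excluded from proportions)."""
        return [self.segment_indices[s] for s in np.nonzero(self.n == 0)[0]]


# ---------------------------------------------------------------------------
# Coded stream


@dataclass(frozen=True)
class Content:
    """One coded content of a segment: a free label mapped to a scheme category."""

    label: str
    category: str


@dataclass
class StreamEntry:
    index: int
    contents: list[Content]
    causes_next: bool | None = None
    text: str | None = None
    annotation: str | None = None  # linguistic gloss, e.g. "Interjection"


@dataclass
class CodedStream:
    """Ordered hand-coded segments with contents and consecutive causal links."""

    text_id: str
    scheme: CategoryScheme
    entries: list[StreamEntry]

    def __post_init__(self) -> None:
        for pos, e in enumerate(self.entries, start=1):
            if e.index != pos:
                raise ValidationError("stream entry indices must be consecutive from 1")
            for c in e.contents:
                if c.category not in self.scheme.codes:
                    raise ValidationError(
                        f"entry {e.index}: category {c.category!r} not in scheme "
                        f"{self.scheme.name!r}"
                    )
        for e in self.entries[:-1]:
            if e.causes_next is None:
                raise ValidationError(
                    f"entry {e.index}: causes_next must be set for all but the last entry"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def causal_breaks(self) -> list[int]:
        """Indices i where no causal link joins segment i to i+1."""
        return [e.index for e in self.entries[:-1] if not e.causes_next]


# ---------------------------------------------------------------------------
# IO helpers


def _infer_format(path: Path, format: str | None, choices: tuple[str, ...]) -> str:
    if format is not None:
        if format not in choices:
            raise ValueError(f"format must be one of {choices}, got {format!r}")
        return format
    suffix = path.suffix.lstrip(".").lower()
    if suffix in choices:
        return suffix
    if suffix == "txt" and "plain" in choices:
        return "plain"
    raise ValueError(f"cannot infer format of {path} (expected one of {choices})")


def _scheme_to_json(scheme: CategoryScheme) -> dict:
    d: dict = {
        "name": scheme.name,
        "categories": [{"code": c.code, "name": c.name} for c in scheme.categories],
    }
    if scheme.parent_map is not None:
        d["parent_map"] = dict(scheme.parent_map)
    return d


def _scheme_from_json(d: Mapping) -> CategoryScheme:
    return CategoryScheme(
        name=d["name"],
        categories=[Category(c["code"], c["name"]) for c in d["categories"]],
        parent_map=dict(d["parent_map"]) if d.get("parent_map") else None,
    )


def read_text(path: str | Path, format: str | None = None) -> PhenomenologicalText:
    """Read a phenomenological text from a plain UTF-8 file or the JSON schema.

    Plain files get whitespace tokenization and a candidate boundary at every
    internal inter-token gap; JSON files may list explicit candidates
    (including the terminal gap).
    """
    path = Path(path)
    fmt = _infer_format(path, format, ("plain", "json"))
    data = path.read_bytes()
    try:
        content = data.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise ValidationError(f"{path} is not valid UTF-8: {exc}") from exc
    if fmt == "plain":
        if not content.strip():
            raise ValidationError(f"{path} contains no text")
        return PhenomenologicalText(text_id=path.stem, language="und", raw=content)
    doc = json.loads(content)
    return PhenomenologicalText(
        text_id=doc["text_id"],
        language=doc.get("language", "und"),
        raw=doc["raw"],
        candidate_boundaries=list(doc.get("candidate_boundaries", [])),
    )


def write_text(text: PhenomenologicalText, path: str | Path) -> None:
    doc = {
        "schema": SCHEMA_TEXT,
        "text_id": text.text_id,
        "language": text.language,
        "raw": text.raw,
        "candidate_boundaries": list(text.candidate_boundaries),
    }
    Path(path).write_text(json.dumps(doc, ensure_ascii=False, indent=1), encoding="utf-8")


def read_segmentation_protocol(
    path: str | Path, format: str | None = None
) -> SegmentationProtocol:
    """Read judge boundary marks.  CSV: rows = judges, columns = boundary ids."""
    path = Path(path)
    fmt = _infer_format(path, format, ("csv", "json"))
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        if df.shape[0] == 0:
            raise ValidationError(f"{path}: empty judge set")
        boundaries = [int(c) for c in df.columns]
        marks = df.to_numpy()
        if not np.isin(marks, (0, 1)).all():
            raise ValidationError(f"{path}: non-binary cell in mark matrix")
        return SegmentationProtocol(
            text_id=path.stem,
            judges=[str(j) for j in df.index],
            boundaries=boundaries,
            marks=marks,
        )
    doc = json.loads(path.read_text(encoding="utf-8"))
    return SegmentationProtocol(
        text_id=doc["text_id"],
        judges=[str(j) for j in doc["judges"]],
        boundaries=[int(b) for b in doc["boundaries"]],
        marks=np.asarray(doc["marks"], dtype=int),
    )


def write_segmentation_protocol(
    protocol: SegmentationProtocol, path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    fmt = _infer_format(path, format, ("csv", "json"))
    if fmt == "csv":
        df = pd.DataFrame(
            protocol.marks,
            index=pd.Index(protocol.judges, name="judge"),
            columns=[str(b) for b in protocol.boundaries],
        )
        df.to_csv(path)
        return
    doc = {
        "schema": SCHEMA_SEGMENTATION,
        "text_id": protocol.text_id,
        "judges": protocol.judges,
        "boundaries": protocol.boundaries,
        "marks": protocol.marks.tolist(),
    }
    path.write_text(json.dumps(doc, ensure_ascii=False, indent=1), encoding="utf-8")


def read_attribution_protocol(
    path: str | Path, format: str | None = None
) -> AttributionProtocol:
    """Read an attribution protocol.

    CSV carries per-judge indicators: rows = judges; for each segment ``s`` a
    recognition column ``seg{s}`` plus one column ``seg{s}:{code}`` per
    category (scheme inferred from the column codes, in order of appearance).
    JSON carries counts + recognition vector directly (optionally indicators).
    """
    path = Path(path)
    fmt = _infer_format(path, format, ("csv", "json"))
    if fmt == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        scheme = _scheme_from_json(doc["scheme"])
        indicators = doc.get("indicators")
        recognized = doc.get("recognized")
        if "counts" in doc:
            return AttributionProtocol(
                text_id=doc["text_id"],
                scheme=scheme,
                n_judges=int(doc["n_judges"]),
                n=np.asarray(doc["n"], dtype=int),
                counts=np.asarray(doc["counts"], dtype=int),
                judges=doc.get("judges"),
                indicators=None if indicators is None else np.asarray(indicators),
                recognized=None if recognized is None else np.asarray(recognized),
            )
        return AttributionProtocol.from_indicators(
            text_id=doc["text_id"],
            scheme=scheme,
            indicators=np.asarray(indicators, dtype=int),
            recognized=None if recognized is None else np.asarray(recognized),
            judges=doc.get("judges"),
        )
    df = pd.read_csv(path, index_col=0)
    seg_re = re.compile(r"^seg(\d+)$")
    cell_re = re.compile(r"^seg(\d+):(.+)$")
    seg_ids: list[int] = []
    codes: list[str] = []
    for col in df.columns:
        m = seg_re.match(col)
        if m:
            seg_ids.append(int(m.group(1)))
            continue
        m = cell_re.match(col)
        if not m:
            raise ValidationError(f"{path}: unrecognized column {col!r}")
        code = m.group(2)
        if code not in codes:
            codes.append(code)
    seg_ids.sort()
    if seg_ids != list(range(1, len(seg_ids) + 1)):
        raise ValidationError(f"{path}: segment columns must cover 1..S")
    J, S, K = df.shape[0], len(seg_ids), len(codes)
    if J == 0:
        raise ValidationError(f"{path}: empty judge set")
    recognized = np.zeros((J, S), dtype=int)
    indicators = np.zeros((J, S, K), dtype=int)
    for s in range(S):
        recognized[:, s] = df[f"seg{s+1}"].to_numpy()
        for k, code in enumerate(codes):
            col = f"seg{s+1}:{code}"
            if col in df.columns:
                indicators[:, s, k] = df[col].to_numpy()
    if not (np.isin(recognized, (0, 1)).all() and np.isin(indicators, (0, 1)).all()):
        raise ValidationError(f"{path}: non-binary cell in attribution matrix")
    scheme = CategoryScheme(path.stem + "-scheme", [Category(c, c) for c in codes])
    return AttributionProtocol.from_indicators(
        text_id=path.stem,
        scheme=scheme,
        indicators=indicators,
        recognized=recognized,
        judges=[str(j) for j in df.index],
    )


def write_attribution_protocol(
    protocol: AttributionProtocol, path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    fmt = _infer_format(path, format, ("csv", "json"))
    if fmt == "csv":
        if protocol.indicators is None:
            raise ValidationError("CSV attribution output requires per-judge indicators")
        cols: dict[str, np.ndarray] = {}
        for s in range(protocol.n_segments):
            cols[f"seg{s+1}"] = protocol.recognized[:, s]
            for k, code in enumerate(protocol.scheme.codes):
                cols[f"seg{s+1}:{code}"] = protocol.indicators[:, s, k]
        judges = protocol.judges or [f"judge{j+1}" for j in range(protocol.n_judges)]
        pd.DataFrame(cols, index=pd.Index(judges, name="judge")).to_csv(path)
        return
    doc: dict = {
        "schema": SCHEMA_ATTRIBUTION,
        "text_id": protocol.text_id,
        "scheme": _scheme_to_json(protocol.scheme),
        "n_judges": protocol.n_judges,
        "n": protocol.n.tolist(),
        "counts": protocol.counts.tolist(),
    }
    if protocol.judges is not None:
        doc["judges"] = protocol.judges
    if protocol.indicators is not None:
        doc["indicators"] = protocol.indicators.tolist()
        doc["recognized"] = protocol.recognized.tolist()
    path.write_text(json.dumps(doc, ensure_ascii=False, indent=1), encoding="utf-8")


def read_coded_stream(path: str | Path) -> CodedStream:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    scheme = _scheme_from_json(doc["scheme"])
    entries = [
        StreamEntry(
            index=int(e["index"]),
            contents=[Content(c["label"], c["category"]) for c in e["contents"]],
            causes_next=e.get("causes_next"),
            text=e.get("text"),
            annotation=e.get("annotation"),
        )
        for e in doc["entries"]
    ]
    return CodedStream(text_id=doc["text_id"], scheme=scheme, entries=entries)


def write_coded_stream(stream: CodedStream, path: str | Path) -> None:
    entries = []
    for e in stream.entries:
        d: dict = {
            "index": e.index,
            "contents": [{"label": c.label, "category": c.category} for c in e.contents],
        }
        if e.causes_next is not None:
            d["causes_next"] = e.causes_next
        if e.text is not None:
            d["text"] = e.text
        if e.annotation is not None:
            d["annotation"] = e.annotation
        entries.append(d)
    doc = {
        "schema": SCHEMA_STREAM,
        "text_id": stream.text_id,
        "scheme": _scheme_to_json(stream.scheme),
        "entries": entries,
    }
    Path(path).write_text(json.dumps(doc, ensure_ascii=False, indent=1), encoding="utf-8")
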