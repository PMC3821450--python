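"""Petri-net-style dynamic model of a coded stream of consciousness.

Each coded content becomes a *place* at time ``t`` (one arbitrary unit per
segment) in the lane of its mental category.  Simultaneous contents of one
segment are joined into a single mental state by a *binding* group (drawn as
a vertical line).  An annotator-asserted causal link from segment ``t`` to
``t+1`` becomes a *causal arc*; maximal runs of consecutively linked segments
are the stream's *micro-episodes*, delimited by breaks in the causality flow.

Causal links are annotator input, never inferred from the text: whether one
mental state generates the next is a human judgment about linguistic flow and
meaning, and this module only stores, validates, and renders it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lxml import etree

from .corpus import CategoryScheme, CodedStream, ValidationError

__all__ = [
    "Place",
    "StreamModel",
    "LayoutSpec",
    "build_stream",
    "detect_episodes",
    "to_dot",
    "to_pnml",
    "layout",
    "plot_stream",
]


@dataclass(frozen=True)
class Place:
    """One content token: segment time ``t``, category ``lane``, free ``label``."""

    t: int
    lane: str
    label: str


@dataclass
class StreamModel:
    scheme: CategoryScheme
    n_segments: int
    places: list[Place]
    bindings: list[list[int]]  # per multi-content segment: place indices sharing one t
    causal_arcs: list[tuple[int, int]]  # (t, t+1)
    episodes: list[tuple[int, int]] = field(default_factory=list)  # inclusive ranges

    def __post_init__(self) -> None:
        for p in self.places:
            if p.lane not in self.scheme.codes:
                raise ValidationError(f"place lane {p.lane!r} not in scheme")
            if not 1 <= p.t <= max(self.n_segments, 1):
                raise ValidationError(f"place time {p.t} outside [1, {self.n_segments}]")
        for group in self.bindings:
            ts = {self.places[i].t for i in group}
            if len(ts) != 1:
                raise ValidationError("a binding group must share a single time step")
        for a, b in self.causal_arcs:
            if b != a + 1:
                raise ValidationError("causal arcs connect consecutive segments only")

    def places_at(self, t: int) -> list[int]:
        return [i for i, p in enumerate(self.places) if p.t == t]


def build_stream(coded: CodedStream) -> StreamModel:
    """Deterministically assemble the model: one place per content (ordered by
    time, then lane order, then coded order), one binding group per
    multi-content segment, one causal arc per asserted link."""
    places: list[Place] = []
    bindings: list[list[int]] = []
    lane_rank = {c: i for i, c in enumerate(coded.scheme.codes)}
    for e in coded.entries:
        start = len(places)
        ordered = sorted(
            enumerate(e.contents), key=lambda ic: (lane_rank[ic[1].category], ic[0])
        )
        for _, c in ordered:
            places.append(Place(t=e.index, lane=c.category, label=c.label))
        if len(e.contents) >= 2:
            bindings.append(list(range(start, len(places))))
    arcs = [(e.index, e.index + 1) for e in coded.entries[:-1] if e.causes_next]
    model = StreamModel(
        scheme=coded.scheme,
        n_segments=len(coded.entries),
        places=places,
        bindings=bindings,
        causal_arcs=arcs,
    )
    model.episodes = detect_episodes(model)
    return model


def detect_episodes(model: StreamModel) -> list[tuple[int, int]]:
    """Maximal runs of consecutive segments joined by causal arcs.

    Splits exactly where no arc crosses a consecutive boundary; the returned
    inclusive ranges partition ``[1, n_segments]``.  Equivalent to the
    connected components of the chain graph whose edges are the causal arcs.
    """
    if model.n_segments == 0:
        return []
    linked = {a for a, _ in model.causal_arcs}
    episodes = []
    start = 1
    for t in range(1, model.n_segments):
        if t not in linked:
            episodes.append((start, t))
            start = t + 1
    episodes.append((start, model.n_segments))
    return episodes


def _place_id(i: int, p: Place) -> str:
    return f"p{p.t}_{i}"


def to_dot(model: StreamModel) -> str:
    """Graphviz DOT rendering: places as nodes ranked by time, binding as
    undirected (dashed, arrowless) edges, causal arcs directed."""
    lines = ["digraph stream {", "  rankdir=LR;", '  node [shape=circle, fontsize=10];']
    for t in range(1, model.n_segments + 1):
        idxs = model.places_at(t)
        if not idxs:
            continue
        lines.append(f"  {{ rank=same; /* t={t} */")
        for i in idxs:
            p = model.places[i]
            label = f"{p.label}\\n[{p.lane}] t={p.t}"
            lines.append(f'    {_place_id(i, p)} [label="{label}"];')
        lines.append("  }")
    for group in model.bindings:
        for a, b in zip(group, group[1:]):
            pa, pb = model.places[a], model.places[b]
            lines.append(
                f"  {_place_id(a, pa)} -> {_place_id(b, pb)} "
                "[dir=none, style=dashed, constraint=false];"
            )
    for a, b in model.causal_arcs:
        src = model.places_at(a)
        dst = model.places_at(b)
        if src and dst:
            pa, pb = model.places[src[0]], model.places[dst[0]]
            lines.append(f"  {_place_id(src[0], pa)} -> {_place_id(dst[0], pb)};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_pnml(model: StreamModel) -> str:
    """PNML (place/transition net) serialization.

    The diagrammatic convention draws causality as an arrow tip at the end of
    an arc; a well-formed P/T net is bipartite, so each causal link becomes an
    explicit transition with incoming arcs from every place of the source
    segment state and outgoing arcs to every place of the target state.
    """
    NS = "http://www.pnml.org/version-2009/grammar/pnml"
    root = etree.Element("pnml", xmlns=NS)
    net = etree.SubElement(
        root,
        "net",
        id=f"stream-{model.n_segments}",
        type="http://www.pnml.org/version-2009/grammar/ptnet",
    )
    page = etree.SubElement(net, "page", id="page0")

    def add_name(el: etree._Element, text: str) -> None:
        name = etree.SubElement(el, "name")
        etree.SubElement(name, "text").text = text

    for i, p in enumerate(model.places):
        el = etree.SubElement(page, "place", id=_place_id(i, p))
        add_name(el, f"{p.label} [{p.lane}] t={p.t}")
    for a, b in model.causal_arcs:
        tid = f"t{a}_{b}"
        el = etree.SubElement(page, "transition", id=tid)
        add_name(el, f"causes {a}->{b}")
        for i in model.places_at(a):
            etree.SubElement(
                page, "arc", id=f"a_{_place_id(i, model.places[i])}_{tid}",
                source=_place_id(i, model.places[i]), target=tid,
            )
        for i in model.places_at(b):
            etree.SubElement(
                page, "arc", id=f"a_{tid}_{_place_id(i, model.places[i])}",
                source=tid, target=_place_id(i, model.places[i]),
            )
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


@dataclass
class LayoutSpec:
    """Plot geometry: per-place coordinates, binding verticals, arc polylines,
    and episode bands along the top line."""

    lanes: list[str]  # bottom-to-top is reversed scheme order; y = rank
    x: list[float]  # per segment t=1..S
    place_xy: list[tuple[float, float]]  # per place
    binding_lines: list[tuple[float, float, float]]  # (x, y_min, y_max)
    arc_segments: list[tuple[float, float, float, float]]  # (x0, y0, x1, y1)
    episode_bands: list[tuple[float, float]]  # (x_start, x_end) inclusive


def _time_positions(model: StreamModel, time_weight: str, coded: CodedStream | None) -> list[float]:
    S = model.n_segments
    if time_weight == "unit" or S == 0:
        return [float(t) for t in range(1, S + 1)]
    if coded is None:
        raise ValidationError("word/char time weighting needs the coded stream texts")
    weights = []
    for e in coded.entries:
        if e.text is None:
            raise ValidationError(f"entry {e.index} has no text for time weighting")
        weights.append(len(e.text.split()) if time_weight == "words" else len(e.text))
    # cumulative midpoint-free positions: segment t sits at the end of its span
    xs: list[float] = []
    acc = 0.0
    for w in weights:
        acc += max(w, 1)
        xs.append(acc)
    return xs


def layout(
    model: StreamModel,
    time_weight: str = "unit",
    coded: CodedStream | None = None,
) -> LayoutSpec:
    """Compute the stream-diagram geometry.

    Abscissa: one arbitrary unit per segment (optionally weighted by word or
    character count — a monotone reweighting that never reorders places).
    Ordinate: one lane per category in scheme order, top lane first.
    """
    if time_weight not in ("unit", "words", "chars"):
        raise ValueError(f"time_weight must be unit|words|chars, got {time_weight!r}")
    lanes = model.scheme.codes
    y_of = {lane: len(lanes) - 1 - i for i, lane in enumerate(lanes)}
    xs = _time_positions(model, time_weight, coded)
    place_xy = [(xs[p.t - 1], float(y_of[p.lane])) for p in model.places]
    binding_lines = []
    for group in model.bindings:
        gx = place_xy[group[0]][0]
        ys = [place_xy[i][1] for i in group]
        binding_lines.append((gx, min(ys), max(ys)))
    arc_segments = []
    for a, b in model.causal_arcs:
        src, dst = model.places_at(a), model.places_at(b)
        if src and dst:
            x0, y0 = place_xy[src[0]]
            x1, y1 = place_xy[dst[0]]
            arc_segments.append((x0, y0, x1, y1))
    episode_bands = [(xs[a - 1], xs[b - 1]) for a, b in model.episodes]
    return LayoutSpec(
        lanes=list(lanes),
        x=xs,
        place_xy=place_xy,
        binding_lines=binding_lines,
        arc_segments=arc_segments,
        episode_bands=episode_bands,
    )


def plot_stream(
    model: StreamModel,
    path: str,
    time_weight: str = "unit",
    coded: CodedStream | None = None,
) -> None:
    """Render the stream diagram to ``path`` (format from the extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = layout(model, time_weight=time_weight, coded=coded)
    n_lanes = len(spec.lanes)
    fig, ax = plt.subplots(figsize=(max(6, model.n_segments * 0.45), 3.5))
    for x0, y0, x1, y1 in spec.arc_segments:
        ax.annotate(
            "", xy=(x1, y1), xytext=(x0, y0),
            arrowprops=dict(arrowstyle="->", color="0.3", lw=0.9),
        )
    for x, ylo, yhi in spec.binding_lines:
        ax.plot([x, x], [ylo, yhi], color="0.1", lw=1.2)
    for (x, y) in spec.place_xy:
        ax.plot(x, y, "o", mfc="white", mec="black", ms=7)
    band_y = n_lanes - 0.45
    for i, (x0, x1) in enumerate(spec.episode_bands):
        ax.plot([x0, x1], [band_y, band_y], lw=3, solid_capstyle="butt")
        ax.text((x0 + x1) / 2, band_y + 0.08, f"ep{i+1}", ha="center", fontsize=8)
    ax.set_yticks(range(n_lanes))
    ax.set_yticklabels(list(reversed(spec.lanes)))
    ax.set_xlabel("time (arbitrary units, one per segment)")
    ax.set_ylim(-0.6, n_lanes)
    ax.spines[["top", "right"]].set_visible(False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
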