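"""Regenerate the packaged fixture data files under src/phenostream/data/.

The published study values transcribed here — the journal excerpt with its 16
per-boundary agreement indices, the 9 × 7 attribution table with its high/low
marks, and the 30-sentence coded monolog with its causality breaks — are the
single source from which all fixture files are derived.  Run from the
repository root:

    python scripts/build_fixtures.py
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from phenostream.corpus import (  # noqa: E402
    AttributionProtocol,
    CodedStream,
    Content,
    PhenomenologicalText,
    SegmentationProtocol,
    StreamEntry,
    joyce_scheme,
    unamuno_scheme,
    write_attribution_protocol,
    write_coded_stream,
    write_segmentation_protocol,
    write_text,
)
from phenostream.fixtures import count_discrepancies, reconstruct_count  # noqa: E402

DATA = ROOT / "src" / "phenostream" / "data"

# ---------------------------------------------------------------------------
# Unamuno journal excerpt: (Spanish line, English translation, agreement index)
# One candidate boundary after each line; the last line's boundary is the
# terminal gap (end of excerpt).

UNAMUNO_LINES = [
    ("El más insignificante suceso,", "The most insignificant occurrence", 0.375),
    ("el encuentro de cualquier frase,", "any sentence I encounter,", 0.5),
    ("la palabra más inocente que oiga,", "the most innocent word I hear,", 0.25),
    ("lo que dice mi hijo,", "whatever my son says,", 0.625),
    ("todo se me antoja aviso y símbolo", "everything seems to me a signal, a symbol", 0.125),
    ("y cosa de sentido oculto,", "and a matter of hidden meaning,", 0.813),
    ("todo lo traduzco a mi estado.", "I translate everything to my state.", 1.0),
    ("Si sigo así voy á caer en superstición.", "If I continue like this I will fall into superstition.", 1.0),
    ("No suenan una vez las campanas", "Not a single bell tolls", 0.063),
    ("que no crea que me llaman;", "that I fail to believe is calling me;", 0.934),
    (
        "se me antoja que se me ha de dirigir á preguntarme que me pasa",
        "I fancy that every man of the cloth that I pass",
        0.125,
    ),
    (
        "cualquier religioso que veo.",
        "will approach to inquire what is the matter with me.",
        1.0,
    ),
    ("Un deseo grande de declarar mi estado á todos,", "A great desire to declare my state to all,", 0.688),
    (
        "una gran felicidad de hacer confesiones a cualquiera,",
        "a great happiness to make confessions to anyone,",
        1.0,
    ),
    ("y una enorme sequedad é indiferencia", "and a great dryness and indifference", 0.125),
    (
        "si pienso en hacerla como la Iglesia manda.",
        "if I think to do it as the Church commands.",
        1.0,
    ),
]

N_JUDGES = 16

# 9 consensus segments x 7 categories (Se Pr Em Th Im Re In): recognition
# count n, published proportions, published flags (high = bold + asterisk,
# low = bold only, none = plain).
TABLE1_N = [10, 14, 16, 16, 15, 16, 11, 16, 16]
TABLE1_PROPS = [
    [0.50, 0.60, 0.30, 0.30, 0.60, 0.70, 0.20],
    [0.57, 0.21, 0.36, 0.36, 0.00, 0.14, 0.29],
    [0.13, 0.19, 0.25, 0.69, 0.00, 0.00, 0.31],
    [0.13, 0.06, 0.06, 0.81, 0.00, 0.00, 0.19],
    [0.27, 0.40, 0.13, 0.27, 0.27, 0.27, 0.27],
    [0.50, 0.25, 0.13, 0.37, 0.19, 0.13, 0.25],
    [0.27, 0.00, 0.82, 0.00, 0.00, 0.00, 0.72],
    [0.38, 0.06, 1.00, 0.06, 0.06, 0.06, 0.90],
    [0.25, 0.06, 0.69, 0.82, 0.19, 0.06, 0.25],
]
_H, _L, _N = "high", "low", "none"
TABLE1_FLAGS = [
    [_N, _H, _L, _L, _H, _H, _L],
    [_N, _L, _N, _N, _L, _L, _L],
    [_L, _L, _L, _H, _L, _L, _L],
    [_L, _L, _L, _H, _L, _L, _L],
    [_L, _N, _L, _L, _L, _L, _L],  # (5, Pr): ambiguous markup, stored as none
    [_N, _L, _L, _N, _L, _L, _L],
    [_L, _L, _H, _L, _L, _L, _H],
    [_N, _L, _H, _L, _L, _L, _H],
    [_L, _L, _H, _H, _L, _L, _L],
]
TABLE1_NOTES = {
    "alpha": "published table marks cells significant at p < 0.01, null unstated",
    "ambiguous_cells": [
        {
            "segment": 5,
            "category": "perception",
            "reason": "markup '0.40****' is ambiguous; the accompanying prose states "
            "segments 2, 5, and 6 received no significant high attribution, "
            "so the flag is stored as 'none'",
        }
    ],
}

# ---------------------------------------------------------------------------
# Joyce "Penelope" excerpt: 30 coded sentence segments.  Each tuple is
# (sentence text, linguistic gloss, [(content label, lane), ...]).
# Lanes: S sensations, E emotions, T thoughts, I mental images.

JOYCE_SENTENCES = [
    ("I bet the cat itself is better off than us", "Conjecture", [("irritation", "E")]),
    ("Have we too much blood up in us or what", "Rhetorical question", [("irritation", "E")]),
    ("O patience above is pouring out of me like the sea", "Interjection", [("despair", "E")]),
    ("Anyhow he didn't make me pregnant as big as he is", "Emphasis", [("contempt", "E")]),
    ("I don't want to ruin the clean sheets", "Reflection", [("sensation", "S"), ("wish", "T")]),
    ("The clean linen I wore brought it on too", "Reflection", [("recollection", "T"), ("image", "I")]),
    ("Damn it damn it", "Interjection", [("anger", "E")]),
    (
        "And they always want to see a stain on the bed to know youre a virgin for them",
        "Reflection",
        [("image", "I"), ("irritation", "E")],
    ),
    ("All that's troubling them", "Same reflection", [("irritation", "E")]),
    ("they're such fools too", "Same reflection", [("contempt", "E")]),
    ("You could be a widow and divorced 40 times over", "Exaggeration", [("irritation", "E")]),
    ("A daub of red ink would do or blackberry juice", "Fantasy", [("image", "I")]),
    ("No that's too purply", "Correction", [("unfolding image", "I")]),
    ("O Jamesy let me up out of this", "Interjection", [("tiredness", "E"), ("anxiety", "E")]),
    ("Pooh", "Interjection", [("same", "E")]),
    ("Sweets on sin", "Interjection", [("same", "E")]),
    (
        "Whoever suggested that business for women what between clothes and cooking and children",
        "Rhetorical question",
        [("thought", "T")],
    ),
    (
        "This damned old bed too jingling like the dickens",
        "Judgment",
        [("recollection", "T"), ("sensation", "S")],
    ),
    (
        "I suppose they could hear us away over the other side of the park till I suggested "
        "to put the quilt on the floor with the pillow under my bottom",
        "Reflection",
        [("recollection", "T"), ("image", "I")],
    ),
    ("I wonder is it nicer in the day", "Question", [("thought begins", "T")]),
    ("I think it is", "Answer", [("thought progress", "T")]),
    ("Easy", "Adjective", [("thought ends", "T")]),
    (
        "I think I'll cut all this hair off me there scalding me",
        "Plans",
        [("sensation", "S"), ("fantasy", "I")],
    ),
    ("I might look like a young girl", "Judgment", [("fantasy developing", "I")]),
    (
        "Wouldn't he get the great sucking the next time he turned up my clothes on me",
        "Rhetorical question",
        [("fantasy", "I")],
    ),
    ("I'd give anything to see his face", "Judgment", [("fantasy ends", "I"), ("wish", "T")]),
    ("where's the chamber gone", "Question", [("visual image", "I")]),
    ("Easy", "Adjective", [("reassurance", "E")]),
    (
        "I've a holy horror of its breaking under me after that old commode",
        "Judgment",
        [("fear", "E"), ("fantasy", "I")],
    ),
    (
        "I wonder was I too heavy sitting on his knee",
        "Question",
        [("fear", "E"), ("recollection", "T")],
    ),
]

# segments after which the causality flow breaks (episode boundaries
# 4|5, 13|14, 16|17, 17|18, 22|23, 26|27)
JOYCE_BREAKS = {4, 13, 16, 17, 22, 26}

# editable fine-label -> lane table; "same" refers to the continuing emotion
# of the preceding segment and is mapped to E
JOYCE_LABEL_MAP = [
    ("irritation", "E"), ("despair", "E"), ("contempt", "E"), ("anger", "E"),
    ("anxiety", "E"), ("fear", "E"), ("reassurance", "E"), ("tiredness", "E"),
    ("same", "E"),
    ("sensation", "S"),
    ("recollection", "T"), ("thought", "T"), ("conjecture", "T"), ("wish", "T"),
    ("plan", "T"), ("thought begins", "T"), ("thought progress", "T"),
    ("thought ends", "T"),
    ("image", "I"), ("unfolding image", "I"), ("visual image", "I"),
    ("fantasy", "I"), ("fantasy developing", "I"), ("fantasy ends", "I"),
]


def build_unamuno(out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    raw = " ".join(line for line, _, _ in UNAMUNO_LINES)
    # candidate boundary after each printed line, in tokens
    boundaries, acc = [], 0
    for line, _, _ in UNAMUNO_LINES:
        acc += len(line.split())
        boundaries.append(acc)
    text = PhenomenologicalText(
        text_id="unamuno_journal",
        language="es",
        raw=raw,
        candidate_boundaries=boundaries,
    )
    write_text(text, out / "text.json")

    # deterministic synthetic judges consistent with the published column sums
    indices = [idx for _, _, idx in UNAMUNO_LINES]
    marks = np.zeros((N_JUDGES, len(boundaries)), dtype=int)
    for b, idx in enumerate(indices):
        marks[: reconstruct_count(idx, N_JUDGES), b] = 1
    protocol = SegmentationProtocol(
        text_id="unamuno_journal",
        judges=[f"judge{j+1}" for j in range(N_JUDGES)],
        boundaries=boundaries,
        marks=marks,
    )
    write_segmentation_protocol(protocol, out / "segmentation.csv", format="csv")

    scheme = unamuno_scheme()
    n = np.asarray(TABLE1_N)
    props = np.asarray(TABLE1_PROPS)
    counts = np.array(
        [[reconstruct_count(props[s, k], n[s]) for k in range(props.shape[1])]
         for s in range(props.shape[0])]
    )
    attribution = AttributionProtocol(
        text_id="unamuno_journal",
        scheme=scheme,
        n_judges=N_JUDGES,
        n=n,
        counts=counts,
    )
    write_attribution_protocol(attribution, out / "attribution.json", format="json")

    printed = {
        "schema": "phenostream/fixture-printed-1",
        "agreement_indices": {str(b): idx for b, idx in zip(boundaries, indices)},
        "translations": [tr for _, tr, _ in UNAMUNO_LINES],
        "table": {
            "proportions": TABLE1_PROPS,
            "flags": TABLE1_FLAGS,
            "alpha": 0.01,
            "notes": TABLE1_NOTES,
        },
        "discrepancies": count_discrepancies(props, counts, n, scheme.codes),
    }
    (out / "printed.json").write_text(
        json.dumps(printed, ensure_ascii=False, indent=1), encoding="utf-8"
    )


def build_joyce(out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    raw = " ".join(s for s, _, _ in JOYCE_SENTENCES)
    text = PhenomenologicalText(text_id="joyce_penelope", language="en", raw=raw)
    write_text(text, out / "text.json")

    entries = []
    for i, (sentence, gloss, contents) in enumerate(JOYCE_SENTENCES, start=1):
        entries.append(
            StreamEntry(
                index=i,
                contents=[Content(label, lane) for label, lane in contents],
                causes_next=None if i == len(JOYCE_SENTENCES) else i not in JOYCE_BREAKS,
                text=sentence,
                annotation=gloss,
            )
        )
    stream = CodedStream(text_id="joyce_penelope", scheme=joyce_scheme(), entries=entries)
    write_coded_stream(stream, out / "stream.json")

    pd.DataFrame(JOYCE_LABEL_MAP, columns=["label", "lane"]).to_csv(
        out / "label_map.csv", index=False
    )


if __name__ == "__main__":
    build_unamuno(DATA / "unamuno_journal")
    build_joyce(DATA / "joyce_penelope")
    print(f"fixture data written under {DATA}")
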