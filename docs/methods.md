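# Methods

## The procedure

The package operationalizes a three-step narrative method for studying
consciousness through texts. A phenomenological text — a first-person report
expressing experience at the moment of writing — is (1) divided into
consensus segments by a panel of judges, (2) annotated with mental categories
whose panel support is tested cell by cell, and (3) transcribed, once
hand-coded, into a dynamic-system graph of the stream of consciousness.
Coding is deliberately human: the tool stores, validates, aggregates, tests,
and renders judgments; it never infers mental content or causality from raw
text.

## Consensus segmentation

Judges independently mark candidate boundaries (inter-token gaps) that
separate distinct ideas. The agreement index of a boundary is the plain
fraction of judges marking it; no chance correction (kappa-style) is applied
because the decision rule is defined directly on the raw fraction. The
consensus rule keeps boundaries whose index is **strictly** greater than a
threshold:

- `threshold="mean"` (default): the arithmetic mean of all candidate
  indices, computed at full precision. In the packaged journal panel the
  mean is 0.6014 (printed 0.60), which also exceeds one half of the judges —
  the stated rationale for treating it as the significance level. A fixed
  threshold (e.g. 0.5) can be passed instead; which generalizes better to
  new texts is an open design question, so both are exposed.
- Strict inequality was chosen so a degenerate panel whose indices all equal
  the mean yields one segment rather than many; on the packaged data strict
  and non-strict rules are indistinguishable (no index equals the mean).
- Rounding is presentation only; thresholding always uses the unrounded
  mean. On the packaged data the partition is identical under 0.60 and
  0.6014, which the tests verify.

Boundary positions are 0-based inter-token gaps; position `n_tokens` (the
end of the excerpt) is a legal candidate because panels are routinely asked
about the final line break. Its index enters the mean but a cut there adds
no segment, so `len(segments) == len(kept internal boundaries) + 1`.
Candidate boundaries of a text not covered by a protocol count as index 0
rather than erroring, so partial protocols degrade gracefully.

## Attribution statistics

For consensus segment `s`, `n_s` is the number of judges who identified and
interpreted the segment at all; attribution proportions divide by `n_s`, not
by the panel size. Segments with `n_s = 0` are excluded from the proportion
matrix with a warning.

Each cell is tested with **two one-sided exact binomial tests** at level
`alpha` (default 0.01): high if `P(X ≥ k) < alpha`, low if `P(X ≤ k) <
alpha`, with `X ~ Binomial(n_s, p0)`. Tails are computed exactly (scipy's
binomial distribution); the test suite checks them against explicit
`math.comb` summation to 1e-12 for all `n ≤ 20`. Because the binomial is
discrete the test is conservative: under a true null the high-flag rate
stays below `alpha`, which a 10,000-cell simulation verifies. No
multiple-testing correction is applied by default — the protocol tests each
cell at its own level — but a Bonferroni option exists.

The null `p0` is a modelling choice the original protocol left unstated.
The default `p0 = 0.5` treats each judge's attribution as a fair coin;
`1/K` (a judge spreading one attribution over K categories) is a documented
alternative. No single null reproduces the published significance pattern of
the journal table (e.g. 0.30 flagged while 0.50 is not in the same row, and
0.69 = 11/16 flagged high although its upper tail under `p0 = 0.5` is 0.105),
so published flags are carried as fixture metadata (`source="printed"`),
computed flags are always labelled `source="computed"`, and `flag_diff`
emits the cell-by-cell disagreement report instead of force-fitting either.

Summaries: *composite states* are segments with ≥ 2 high flags (binding of
several mental factors into one conscious occasion); *empty segments* have
none. On the published flags these are {1, 7, 8, 9} and {2, 5, 6}.

## Stream model

A coded stream maps to a Petri-net-style graph: one **place** per content at
time `t` (one arbitrary unit per segment) in the lane of its category;
a **binding** group per multi-content segment; a **causal arc** per
annotator-asserted link from a segment's state to the next. Micro-episodes
are maximal runs of consecutively linked segments — equivalently, connected
components of the chain graph — so a segment isolated by breaks on both
sides forms a singleton episode. Construction is deterministic (places
ordered by time, then lane order, then coded order), so DOT and PNML output
are byte-identical across runs.

The diagram convention draws causality as an arrow tip at the end of an arc;
a well-formed place/transition net is bipartite, so PNML export inserts an
explicit transition per causal link, with arcs from every place of the
source state and to every place of the target state. The intra-episode arc
pattern is chain-by-default (state `t` to state `t+1`); skip links are not
generated because only consecutive causality is recorded. Token-firing
simulation and reachability analysis are out of scope.

Layout puts `x = t` (optionally reweighted by word or character count — a
monotone change that never reorders places), `y` = lane rank in scheme order
(top lane first), binding as verticals, and episode bands along the top.

## Packaged datasets

`unamuno_journal` reconstructs a 16-judge panel over a 107-token Spanish
journal excerpt with 16 candidate boundaries (one per printed line, the last
being the terminal gap). Judge-level marks were never published, only
per-boundary indices, so the fixture builds a deterministic synthetic panel:
`m_b = round(index_b × 16)` judges (always judges `1..m_b`) mark boundary
`b`. Agreement indices depend on column sums only, so any assignment of
*which* judges mark is observationally equivalent; the canonical one keeps
files byte-stable. Attribution counts are reconstructed as
`round(proportion × n_s)` (half-up). Published cells that no integer count
reproduces within half of the last printed decimal (inclusive tolerance
0.005, so that 0.125 → "0.13" is not an error) are stored with the nearest
count and listed verbatim in the fixture's discrepancy report: segment 7
intention 0.72 (8/11 = 0.727), segment 8 intention 0.90 (14/16 = 0.875),
segment 9 thought 0.82 (13/16 = 0.8125). One published significance mark
("0.40" in segment 5, perception) carries ambiguous markup; it is stored as
unflagged, following the accompanying prose that segments 2, 5, 6 received
no significant attribution.

`joyce_penelope` carries the 30-sentence coded monolog: per-sentence content
labels with their lanes (S/E/T/I), a linguistic gloss, and causality breaks
after sentences 4, 13, 16, 17, 22, 26 (hence 23 causal links and seven
episodes). The fine-label → lane table ships as an editable CSV; affect
words map to E, "sensation" to S, reflective labels (recollection, thought,
conjecture, wish, plan) to T, imagery (image, fantasy, visual image) to I.
The anaphoric label "same" (sentences 15–16, continuing the emotion of 14)
maps to E.

Both datasets are regenerated from the transcribed published values by
`scripts/build_fixtures.py`; nothing in the fixtures is fitted.

## Judge-panel simulator

The simulator emulates only the statistical structure of panel marks:
independent judges, segments, and categories. Segmentation marks are
`Bernoulli(boundary_probs[b])`; attribution is two-stage (recognize segment
`s` with `recognition_probs[s]`, then attribute category `k` with
`attach_probs[s, k]` conditional on recognition). An optional per-judge
leniency multiplier (off by default) introduces judge heterogeneity; the
default models an undifferentiated assembly of judges. All randomness flows
through one `numpy` generator with a mandatory seed; identical specs give
byte-identical protocol files.

What passing simulator-based tests shows: the arithmetic of the pipeline
(index computation, exact-test calibration, power) is correct under the
independence model. What it does not show: real judges share reading
strategies and biases, violate independence, and drift across a session;
none of that is modelled, so calibration results transfer to real panels
only approximately.

Default problem sizes for calibration checks (10,000 null cells with
`n = 16` judges; panels of 400–1000 judges for recovery checks) were chosen
to make three-Monte-Carlo-standard-error bounds decisive at the default
`alpha = 0.01` while keeping each check under a second.

## Known limitations

- No chance-corrected agreement coefficients; the consensus rule is the raw
  fraction + mean threshold by construction.
- The exact test treats judges as exchangeable; correlated panels inflate
  the effective type-I error beyond what the conservativeness bound states.
- Translation text is stored but never analyzed; tokenization is
  whitespace-based and language-agnostic.
- The stream model records only consecutive causality; longer-range mental
  causation cannot be represented.
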