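# phenostream

Tools for the quantitative, narrative analysis of *phenomenological texts* —
first-person verbal reports that express conscious experience in the act of
speaking or writing (interior monologs, journals, thinking-aloud
transcriptions). The package does not code texts automatically; coding is a
human judgment. It manages and analyzes the output of human judge panels and
hand-coders in three stages:

1. **Consensus segmentation.** A panel of *J* judges marks candidate
   boundaries between distinct ideas. The agreement index of boundary *b* is
   the fraction of judges marking it, `a_b = (Σ_j m_jb) / J`. Boundaries with
   `a_b` strictly above a threshold — by default the panel mean
   `ā = (Σ_b a_b) / B` — are kept, and the kept boundaries tile the text into
   consensus segments.
2. **Attribution statistics.** Judges attribute mental categories
   (*sensation, perception, emotion, thought, image, recall, intention*) to
   each consensus segment. For segment *s* with `n_s` recognizing judges and
   `k` attributions of a category, the proportion is `k / n_s`, and the cell
   is flagged **high** when the exact binomial upper tail
   `P(X ≥ k), X ~ Bin(n_s, p0)` falls below `α`, or **low** when
   `P(X ≤ k) < α` — two one-sided exact tests, by default `p0 = 0.5`,
   `α = 0.01`. Segments high in ≥ 2 categories are *composite states*
   (binding of simultaneous contents); segments with no high flag carry no
   agreed mental content.
3. **Stream model.** A hand-coded stream (segments × content labels ×
   category lanes, with annotator-asserted causal links) becomes a
   Petri-net-style graph: contents as places on a time axis (one unit per
   segment), simultaneous contents bound into one state, causality as arcs
   between consecutive states. Breaks in the causality flow split the stream
   into *micro-episodes*. Models export to Graphviz DOT, PNML (P/T net), and
   a lane plot.

Two hand-coded reference datasets ship with the package: a Spanish
introspective journal excerpt evaluated by a 16-judge student panel
(`unamuno_journal`: 16 candidate boundaries, 9 consensus segments, a 9 × 7
attribution table with published significance marks), and a 30-sentence
English interior monolog coded into four lanes with seven micro-episodes
(`joyce_penelope`). A judge-panel simulator calibrates the agreement
threshold and the flagging test (type-I error, power) without external data.

## Worked example

```python
import phenostream as ps

bundle = ps.load_fixture("unamuno_journal")
v = ps.boundary_agreement(bundle.segmentation)
print(round(ps.mean_agreement(v), 2))          # 0.6
result = ps.consensus_segments(bundle.text, v, threshold="mean")
print(len(result.segments))                    # 9
print(result.segments[2].text)                 # todo lo traduzco a mi estado.

pm = ps.proportion_matrix(bundle.attribution)
print(pm.values[7, bundle.attribution.scheme.index("emotion")])   # 1.0
print(ps.composite_states(bundle.printed_flags))                  # [1, 7, 8, 9]
print(ps.empty_segments(bundle.printed_flags))                    # [2, 5, 6]

joyce = ps.load_fixture("joyce_penelope")
model = ps.build_stream(joyce.coded_stream)
print(model.episodes)
# [(1, 4), (5, 13), (14, 16), (17, 17), (18, 22), (23, 26), (27, 30)]
```

The mean panel agreement is 0.60, so every boundary marked by more than that
fraction of judges splits the journal excerpt — nine consensus segments. All
sixteen judges attributed *emotion* to segment 8 (proportion 1.0); segments
1, 7, 8, 9 are composite states under the published flags, while 2, 5, 6
received no significant attribution. The coded monolog breaks into seven
micro-episodes where its causality flow stops.

The same pipeline is available from a shell:

```
phenostream run --fixture unamuno_journal --out-dir out/unamuno
phenostream run --fixture joyce_penelope  --out-dir out/joyce
phenostream segment --protocol P.csv --text T.txt --out segments.json --report report.tsv
phenostream attribute --protocol A.json --p0 0.5 --alpha 0.01 --out table.tsv
phenostream stream --coded stream.json --out model.pnml --plot fig.svg
phenostream simulate power --spec spec.json --seed 1 --out power.tsv
```

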