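"""Domain types, file IO round-trips, and packaged-fixture integrity."""

import json

import numpy as np
import pytest

from phenostream import (
    AttributionProtocol,
    CategoryScheme,
    Category,
    CodedStream,
    Content,
    PhenomenologicalText,
    SegmentationProtocol,
    StreamEntry,
    ValidationError,
    joyce_scheme,
    read_attribution_protocol,
    read_coded_stream,
    read_segmentation_protocol,
    read_text,
    tokenize,
    unamuno_scheme,
    write_attribution_protocol,
    write_coded_stream,
    write_segmentation_protocol,
    write_text,
)
from phenostream.fixtures import COUNT_TOL, count_discrepancies


class TestText:
    def test_whitespace_tokenization_with_offsets(self):
        text = PhenomenologicalText("t", "es", "todo lo traduzco a mi estado.")
        assert [t.text for t in text.tokens] == ["todo", "lo", "traduzco", "a", "mi", "estado."]
        assert text.raw[text.tokens[2].start : text.tokens[2].end] == "traduzco"
        # default candidates: every internal inter-token gap
        assert text.candidate_boundaries == [1, 2, 3, 4, 5]

    def test_one_word_text_has_no_candidate_boundaries(self):
        assert PhenomenologicalText("t", "en", "Pooh").candidate_boundaries == []

    def test_empty_text_rejected(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("   \n")
        with pytest.raises(ValidationError):
            read_text(p)

    def test_invalid_utf8_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_bytes(b"\xff\xfe caf\xe9")
        with pytest.raises(ValidationError):
            read_text(p)

    def test_boundaries_must_increase_within_range(self):
        with pytest.raises(ValidationError):
            PhenomenologicalText("t", "en", "a b c", candidate_boundaries=[2, 1])
        with pytest.raises(ValidationError):
            PhenomenologicalText("t", "en", "a b c", candidate_boundaries=[4])

    def test_plain_text_roundtrip_through_json(self, tmp_path):
        src = tmp_path / "x.txt"
        src.write_text("uno dos tres cuatro", encoding="utf-8")
        t1 = read_text(src)
        write_text(t1, tmp_path / "x.json")
        t2 = read_text(tmp_path / "x.json", format="json")
        assert t1 == t2


class TestSegmentationProtocol:
    def test_rejects_empty_judges_and_nonbinary_marks(self, tmp_path):
        with pytest.raises(ValidationError):
            SegmentationProtocol("t", [], [1], np.zeros((0, 1)))
        p = tmp_path / "m.csv"
        p.write_text("judge,1,2\nj1,0,2\n")
        with pytest.raises(ValidationError):
            read_segmentation_protocol(p)

    def test_all_zero_marks_valid(self):
        prot = SegmentationProtocol("t", ["a", "b"], [1, 2, 3], np.zeros((2, 3)))
        assert prot.marks.sum() == 0

    def test_unknown_boundary_is_reference_error(self):
        text = PhenomenologicalText("t", "en", "a b c")
        prot = SegmentationProtocol("t", ["j"], [5], np.ones((1, 1)))
        with pytest.raises(ValidationError):
            prot.check_against(text)

    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_roundtrip_bit_identical(self, tmp_path, fmt):
        prot = SegmentationProtocol(
            "p1", ["j1", "j2"], [1, 3, 4], np.array([[1, 0, 1], [0, 0, 1]])
        )
        p1, p2 = tmp_path / f"a.{fmt}", tmp_path / f"b.{fmt}"
        write_segmentation_protocol(prot, p1)
        back = read_segmentation_protocol(p1)
        assert back.judges == prot.judges
        assert back.boundaries == prot.boundaries
        assert np.array_equal(back.marks, prot.marks)
        write_segmentation_protocol(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestCategoryScheme:
    def test_duplicate_codes_rejected(self):
        with pytest.raises(ValidationError):
            CategoryScheme("s", [Category("x", "X"), Category("x", "Y")])

    def test_seven_category_scheme_maps_totally_onto_four_lanes(self):
        fine, coarse = unamuno_scheme(), joyce_scheme()
        assert len(fine.codes) == 7 and len(coarse.codes) == 4
        for code in fine.codes:
            assert coarse.map_code(code) in coarse.codes

    def test_unknown_code_errors(self):
        with pytest.raises(ValidationError):
            joyce_scheme().map_code("daydream")


class TestAttributionProtocol:
    def test_counts_above_recognition_rejected(self):
        with pytest.raises(ValidationError):
            AttributionProtocol(
                "t", joyce_scheme(), n_judges=4,
                n=np.array([2]), counts=np.array([[3, 0, 0, 0]]),
            )

    def test_counts_from_indicators_judge_sum(self):
        ind = np.zeros((3, 2, 4), dtype=int)
        ind[0, 0, 1] = ind[1, 0, 1] = ind[2, 1, 0] = 1
        prot = AttributionProtocol.from_indicators("t", joyce_scheme(), ind)
        assert prot.counts[0, 1] == 2 and prot.counts[1, 0] == 1
        assert list(prot.n) == [2, 1]

    def test_unrecognized_segment_is_flagged_not_fatal(self):
        prot = AttributionProtocol(
            "t", joyce_scheme(), n_judges=4,
            n=np.array([0, 3]), counts=np.array([[0, 0, 0, 0], [1, 0, 2, 0]]),
        )
        assert prot.unrecognized_segments == [1]

    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_roundtrip_bit_identical(self, tmp_path, fmt):
        rng = np.random.default_rng(7)
        rec = rng.integers(0, 2, size=(5, 3))
        ind = rng.integers(0, 2, size=(5, 3, 4)) * rec[:, :, None]
        prot = AttributionProtocol.from_indicators(
            "t", CategoryScheme("s", [Category(c, c) for c in "SETI"]), ind, recognized=rec
        )
        p1, p2 = tmp_path / f"a.{fmt}", tmp_path / f"b.{fmt}"
        write_attribution_protocol(prot, p1)
        back = read_attribution_protocol(p1)
        assert np.array_equal(back.counts, prot.counts)
        assert np.array_equal(back.n, prot.n)
        assert np.array_equal(back.indicators, prot.indicators)
        write_attribution_protocol(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestCodedStream:
    def test_indices_must_be_consecutive(self):
        with pytest.raises(ValidationError):
            CodedStream("t", joyce_scheme(), [StreamEntry(2, [Content("x", "E")])])

    def test_category_must_belong_to_scheme(self):
        with pytest.raises(ValidationError):
            CodedStream("t", joyce_scheme(), [StreamEntry(1, [Content("x", "Z")])])

    def test_causes_next_required_except_last(self):
        with pytest.raises(ValidationError):
            CodedStream(
                "t", joyce_scheme(),
                [StreamEntry(1, [Content("x", "E")]), StreamEntry(2, [Content("y", "T")])],
            )

    def test_roundtrip(self, tmp_path, joyce):
        p1, p2 = tmp_path / "s1.json", tmp_path / "s2.json"
        write_coded_stream(joyce.coded_stream, p1)
        back = read_coded_stream(p1)
        assert back == joyce.coded_stream
        write_coded_stream(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestUnamunoFixture:
    def test_sixteen_candidate_boundaries(self, unamuno):
        assert len(unamuno.text.candidate_boundaries) == 16
        assert len(unamuno.printed_indices) == 16
        # the final printed line break is the terminal gap of the excerpt
        assert unamuno.text.candidate_boundaries[-1] == unamuno.text.n_tokens

    def test_panel_of_sixteen_judges(self, unamuno):
        assert unamuno.segmentation.n_judges == 16
        assert unamuno.segmentation.marks.shape == (16, 16)

    def test_recognition_vector_matches_published_table(self, unamuno):
        assert list(unamuno.attribution.n) == [10, 14, 16, 16, 15, 16, 11, 16, 16]
        assert unamuno.attribution.scheme.codes == [
            "sensation", "perception", "emotion", "thought", "image", "recall", "intention",
        ]

    def test_boundary_after_lo_que_dice_mi_hijo_marked_by_ten_judges(self, unamuno):
        b = unamuno.text.candidate_boundaries[3]
        assert unamuno.text.span_text(0, b).endswith("lo que dice mi hijo,")
        col = unamuno.segmentation.boundaries.index(b)
        assert unamuno.segmentation.marks[:, col].sum() == 10
        assert unamuno.printed_indices[b] == 0.625

    def test_mark_counts_consistent_with_published_indices(self, unamuno):
        """Every reconstructed column sum sits within rounding slack of its
        published agreement index; anything farther lands in the report."""
        for b, idx in unamuno.printed_indices.items():
            col = unamuno.segmentation.boundaries.index(b)
            count = unamuno.segmentation.marks[:, col].sum()
            assert abs(count / 16 - idx) <= 0.5 / 16 + 0.005

    def test_discrepancy_report_lists_irreproducible_cells(self, unamuno):
        cells = {(d["segment"], d["category"]) for d in unamuno.discrepancies}
        assert cells == {(7, "intention"), (8, "intention"), (9, "thought")}
        # the report is recomputable from the stored counts and published table
        recomputed = count_discrepancies(
            unamuno.printed_proportions,
            unamuno.attribution.counts,
            unamuno.attribution.n,
            unamuno.attribution.scheme.codes,
        )
        assert recomputed == unamuno.discrepancies

    def test_all_other_cells_reproduce_printed_proportions(self, unamuno):
        flagged = {(d["segment"], d["category"]) for d in unamuno.discrepancies}
        counts, n = unamuno.attribution.counts, unamuno.attribution.n
        codes = unamuno.attribution.scheme.codes
        for s in range(9):
            for k, code in enumerate(codes):
                if (s + 1, code) not in flagged:
                    assert abs(counts[s, k] / n[s] - unamuno.printed_proportions[s, k]) <= COUNT_TOL


class TestJoyceFixture:
    def test_thirty_entries_six_causality_breaks(self, joyce):
        assert len(joyce.coded_stream) == 30
        assert joyce.coded_stream.causal_breaks == [4, 13, 16, 17, 22, 26]

    def test_entry_seven_is_a_single_anger_emotion(self, joyce):
        e = joyce.coded_stream.entries[6]
        assert e.contents == [Content("anger", "E")]
        assert e.annotation == "Interjection"

    def test_entry_five_binds_a_sensation_and_a_wish(self, joyce):
        e = joyce.coded_stream.entries[4]
        assert [(c.label, c.category) for c in e.contents] == [
            ("sensation", "S"), ("wish", "T"),
        ]

    def test_label_map_covers_every_coded_label(self, joyce):
        for e in joyce.coded_stream.entries:
            for c in e.contents:
                assert joyce.label_map[c.label] == c.category
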