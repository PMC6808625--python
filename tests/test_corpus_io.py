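"""Tokenization, BRAT/CoNLL round-trips and tag<->span conversion."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pharmaconer as ph
from pharmaconer.corpus_io import repair_tags
from pharmaconer.types import AlignmentError, FormatError


class TestTokenize:
    def test_empty_text_yields_no_tokens(self):
        assert ph.tokenize("") == []

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("receptores de progesterona", [(0, 10), (11, 13), (14, 26)]),
            ("triglicéridos altos", [(0, 13), (14, 19)]),
        ],
    )
    def test_whitespace_offsets(self, text, expected):
        assert [(t.start, t.end) for t in ph.tokenize(text)] == expected

    @pytest.mark.parametrize(
        "text,surfaces",
        [
            ("lidocaína (2%)", ["lidocaína", "(", "2", "%", ")"]),
            ("anti-TNF, 0,5 mg.", ["anti-TNF", ",", "0,5", "mg", "."]),
            ("dosis [v.o.]", ["dosis", "[", "v", ".", "o", ".", "]"]),
        ],
    )
    def test_punctuation_isolated_but_hyphens_and_decimals_kept(
        self, text, surfaces
    ):
        assert [t.surface for t in ph.tokenize(text)] == surfaces

    @given(st.text(max_size=120))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_offsets_always_slice_back_to_surface(self, text):
        for tok in ph.tokenize(text):
            assert text[tok.start:tok.end] == tok.surface


class TestBrat:
    def test_read_annotated_drug_mention(self, tmp_path):
        (tmp_path / "d.txt").write_text("triglicéridos altos", encoding="utf-8")
        (tmp_path / "d.ann").write_text(
            "T1\tNormalizables 0 13\ttriglicéridos\n", encoding="utf-8")
        doc = ph.read_brat(tmp_path / "d.txt", tmp_path / "d.ann")
        assert doc.entities == [
            ph.Entity("Normalizables", 0, 13, "triglicéridos")]

    def test_empty_ann_file(self, tmp_path):
        (tmp_path / "d.txt").write_text("sin menciones", encoding="utf-8")
        (tmp_path / "d.ann").write_text("", encoding="utf-8")
        assert ph.read_brat(tmp_path / "d.txt", tmp_path / "d.ann").entities == []

    def test_offset_beyond_text_is_format_error(self, tmp_path):
        (tmp_path / "d.txt").write_text("corto", encoding="utf-8")
        (tmp_path / "d.ann").write_text("T1\tX 0 99\tcorto\n", encoding="utf-8")
        with pytest.raises(FormatError, match="T1"):
            ph.read_brat(tmp_path / "d.txt", tmp_path / "d.ann")

    def test_surface_mismatch_strict_vs_lenient(self, tmp_path):
        (tmp_path / "d.txt").write_text("abcdef", encoding="utf-8")
        (tmp_path / "d.ann").write_text("T1\tX 0 3\txyz\n", encoding="utf-8")
        with pytest.raises(FormatError):
            ph.read_brat(tmp_path / "d.txt", tmp_path / "d.ann")
        doc = ph.read_brat(tmp_path / "d.txt", tmp_path / "d.ann", lenient=True)
        assert doc.entities[0].surface == "abc"

    def test_discontinuous_span_rejected(self, tmp_path):
        (tmp_path / "d.txt").write_text("a b c d e f", encoding="utf-8")
        (tmp_path / "d.ann").write_text("T1\tX 0 1;4 5\ta c\n", encoding="utf-8")
        with pytest.raises(FormatError, match="discontinuous"):
            ph.read_brat(tmp_path / "d.txt", tmp_path / "d.ann")

    def test_non_text_bound_lines_ignored(self, tmp_path):
        (tmp_path / "d.txt").write_text("abc", encoding="utf-8")
        (tmp_path / "d.ann").write_text(
            "T1\tX 0 3\tabc\n#1\tAnnotatorNotes T1\tnota\nR1\tRel Arg1:T1\n",
            encoding="utf-8")
        doc = ph.read_brat(tmp_path / "d.txt", tmp_path / "d.ann")
        assert len(doc.entities) == 1

    def test_write_is_byte_stable(self, tiny_doc, tmp_path):
        for i in (1, 2):
            ph.write_brat(tiny_doc, tmp_path / f"{i}.txt", tmp_path / f"{i}.ann")
        assert (tmp_path / "1.ann").read_bytes() == (tmp_path / "2.ann").read_bytes()
        assert (tmp_path / "1.txt").read_bytes() == (tmp_path / "2.txt").read_bytes()

    def test_doc_without_entities_writes_empty_ann(self, tmp_path):
        doc = ph.Document("d", "hola", ph.tokenize("hola"), [])
        ph.write_brat(doc, tmp_path / "d.txt", tmp_path / "d.ann")
        assert (tmp_path / "d.ann").read_text() == ""


class TestTagConversion:
    def make_doc(self, n_tokens=3, spans=((0, 2, "X"),)):
        text = " ".join(f"w{i}" for i in range(n_tokens))
        tokens = ph.tokenize(text)
        entities = [
            ph.Entity(lab, tokens[a].start, tokens[b - 1].end,
                      text[tokens[a].start:tokens[b - 1].end])
            for a, b, lab in spans
        ]
        return ph.Document("d", text, tokens, entities)

    def test_bio_definition(self):
        doc = self.make_doc()
        assert ph.entities_to_tags(doc, "BIO").tags == ["B-X", "I-X", "O"]

    def test_bioes_two_token_entity(self):
        doc = self.make_doc()
        assert ph.entities_to_tags(doc, "BIOES").tags == ["B-X", "E-X", "O"]

    def test_bioes_single_token_entity(self):
        doc = self.make_doc(spans=((0, 1, "X"),))
        assert ph.entities_to_tags(doc, "BIOES").tags == ["S-X", "O", "O"]

    def test_misaligned_boundary_raises_unless_expanded(self):
        doc = self.make_doc()
        doc.entities = [ph.Entity("X", 0, 1, "w")]  # splits token "w0"
        with pytest.raises(AlignmentError):
            ph.entities_to_tags(doc, "BIO")
        tags = ph.entities_to_tags(doc, "BIO", expand_boundaries=True)
        assert tags.tags == ["B-X", "O", "O"]

    def test_overlapping_entities_rejected(self):
        doc = self.make_doc(spans=((0, 2, "X"), (1, 3, "Y")))
        with pytest.raises(AlignmentError, match="overlap"):
            ph.entities_to_tags(doc, "BIO")

    def test_all_outside_decodes_to_no_entities(self):
        doc = self.make_doc(spans=())
        seq = ph.TagSequence("BIO", ["O", "O", "O"])
        assert ph.bio_to_entities(doc.tokens, seq, doc.text) == []

    def test_stray_inside_repaired_as_begin(self):
        doc = self.make_doc(spans=())
        seq = ph.TagSequence("BIO", ["I-X", "I-X", "O"])
        ents = ph.bio_to_entities(doc.tokens, seq, doc.text)
        assert len(ents) == 1
        assert (ents[0].start, ents[0].end) == (0, 5)  # tokens 0-1

    @pytest.mark.parametrize("scheme", ["BIO", "BIOES"])
    def test_roundtrip_identity(self, small_corpus, scheme):
        for doc in small_corpus.docs[:20]:
            tags = ph.entities_to_tags(doc, scheme)
            assert tags.is_valid()
            back = ph.bio_to_entities(doc.tokens, tags, doc.text)
            assert back == sorted(doc.entities, key=lambda e: e.start)

    def test_repair_makes_any_tag_sequence_valid(self):
        ugly = ["I-X", "E-Y", "B-X", "O", "E-X", "I-Z"]
        for scheme in ("BIO", "BIOES"):
            fixed = repair_tags(ugly, scheme)
            seq = ph.TagSequence(scheme, ph.entities_to_tags(
                ph.Document("d", "", [], []), scheme).tags)
            # decoding the repaired tags never raises
            toks = ph.tokenize(" ".join("w" * 1 for _ in ugly))


class TestConll:
    @pytest.mark.parametrize("scheme", ["BIO", "BIOES"])
    def test_roundtrip_reproduces_tokens_offsets_entities(
        self, small_corpus, tmp_path, scheme
    ):
        path = tmp_path / "c.conll"
        ph.write_conll(small_corpus.docs, path, scheme)
        back = ph.read_conll(path)
        assert len(back) == len(small_corpus.docs)
        for orig, new in zip(small_corpus.docs, back):
            assert [(t.surface, t.start, t.end, t.pos) for t in orig.tokens] \
                == [(t.surface, t.start, t.end, t.pos) for t in new.tokens]
            assert sorted(orig.entities, key=lambda e: e.start) == new.entities

    def test_three_line_file_decodes_one_entity(self, tmp_path):
        path = tmp_path / "c.conll"
        path.write_text(
            "triglicéridos d1 0 13 NOUN B-Normalizables\n"
            "altos d1 14 19 ADJ O\n"
            "hoy d1 20 23 ADV O\n\n",
            encoding="utf-8")
        docs = ph.read_conll(path)
        assert len(docs) == 1
        assert docs[0].entities == [
            ph.Entity("Normalizables", 0, 13, "triglicéridos")]

    def test_blank_only_file_gives_no_documents(self, tmp_path):
        path = tmp_path / "c.conll"
        path.write_text("\n\n\n", encoding="utf-8")
        assert ph.read_conll(path) == []

    def test_stray_inside_at_sentence_start_is_repaired_not_fatal(
        self, tmp_path
    ):
        path = tmp_path / "c.conll"
        path.write_text("w d1 0 1 _ I-X\n\n", encoding="utf-8")
        docs = ph.read_conll(path)
        assert docs[0].entities[0].label == "X"

    def test_ragged_columns_reported_with_line_number(self, tmp_path):
        path = tmp_path / "c.conll"
        path.write_text("a d1 0 1 _ O\nb d1\n", encoding="utf-8")
        with pytest.raises(FormatError, match="2"):
            ph.read_conll(path)

    def test_docstart_lines_ignored(self, tmp_path):
        path = tmp_path / "c.conll"
        path.write_text("-DOCSTART- -X- O\nw d1 0 1 _ O\n\n", encoding="utf-8")
        assert len(ph.read_conll(path)) == 1

    def test_write_is_byte_stable(self, small_corpus, tmp_path):
        for i in (1, 2):
            ph.write_conll(small_corpus.docs[:5], tmp_path / f"{i}.conll")
        assert (tmp_path / "1.conll").read_bytes() \
            == (tmp_path / "2.conll").read_bytes()


def test_brat_dir_roundtrip(small_corpus, tmp_path):
    ph.write_brat_dir(small_corpus.docs[:10], tmp_path / "brat")
    back = ph.read_brat_dir(tmp_path / "brat")
    for orig, new in zip(small_corpus.docs[:10], back):
        assert new.text == orig.text
        assert new.entities == sorted(orig.entities, key=lambda e: (e.start, e.end))
        assert [(t.surface, t.start, t.end) for t in new.tokens] \
            == [(t.surface, t.start, t.end) for t in orig.tokens]


def test_sentence_spans_break_on_terminator_plus_capital():
    text = "Una frase corta. Otra frase más."
    doc = ph.Document("d", text, ph.tokenize(text), [])
    spans = ph.sentence_spans(doc)
    assert len(spans) == 2
    lo, hi = spans[0]
    assert doc.tokens[hi - 1].surface == "."
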