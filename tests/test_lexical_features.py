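"""Gazetteer, affix and POS feature channels against brute-force oracles."""
import numpy as np
import pytest

import pharmaconer as ph
from pharmaconer.lexical_features import normalize
from pharmaconer.types import FormatError


def tok(surface):
    return ph.Token(surface, 0, len(surface))


class TestGazetteer:
    def test_listed_active_ingredient_is_member(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("indometacina\n", encoding="utf-8")
        g = ph.load_gazetteer(path)
        assert ph.gazetteer_feature(tok("indometacina"), g) == 1
        assert ph.gazetteer_feature(tok("Indometacina"), g) == 1  # lowercased

    def test_multiword_entry_exploded_into_words(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("ácido acetilsalicílico\n", encoding="utf-8")
        g = ph.load_gazetteer(path)
        assert ph.gazetteer_feature(tok("ácido"), g) == 1
        assert ph.gazetteer_feature(tok("acetilsalicílico"), g) == 1

    def test_short_fragments_not_exploded(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("vitamina de contraste\n", encoding="utf-8")
        g = ph.load_gazetteer(path)
        assert ph.gazetteer_feature(tok("de"), g) == 0

    def test_empty_file_degenerates_to_constant_zero(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("# solo comentarios\n\n", encoding="utf-8")
        g = ph.load_gazetteer(path)
        assert ph.gazetteer_feature(tok("cualquiera"), g) == 0

    def test_non_members_and_punctuation_score_zero(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("indometacina\n", encoding="utf-8")
        g = ph.load_gazetteer(path)
        assert ph.gazetteer_feature(tok("paciente"), g) == 0
        assert ph.gazetteer_feature(tok("("), g) == 0

    def test_accent_stripping_flag(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("lidocaína\n", encoding="utf-8")
        strict = ph.load_gazetteer(path)
        loose = ph.load_gazetteer(path, strip_accents=True)
        assert ph.gazetteer_feature(tok("lidocaina"), strict) == 0
        assert ph.gazetteer_feature(tok("lidocaina"), loose) == 1

    def test_hash_lookup_matches_linear_scan_oracle(
        self, corpus_dir, small_corpus
    ):
        g = ph.load_gazetteer(corpus_dir / "gazetteer.txt")
        raw_terms = [
            normalize(line) for line in
            (corpus_dir / "gazetteer.txt").read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]

        def brute(surface):
            s = normalize(surface)
            for term in raw_terms:
                if s == term:
                    return 1
                for w in term.split():
                    if len(w) >= 3 and s == w:
                        return 1
            return 0

        rng = np.random.default_rng(1)
        all_tokens = [t for d in small_corpus.docs for t in d.tokens]
        picks = rng.choice(len(all_tokens), size=1000)
        for i in picks:
            t = all_tokens[int(i)]
            assert ph.gazetteer_feature(t, g) == brute(t.surface), t.surface


class TestAffixes:
    def test_tsv_row_parsing(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text(
            "type\taffix_en\taffix_es\texample_en\tdrug_class\n"
            "suffix\t-caine\t-caína\tlidocaine\tlocal anesthetic\n"
            "prefix\tcef-\tcef-\tcefazolin\tcephalosporin\n",
            encoding="utf-8")
        entries = ph.load_affixes(path)
        assert [(e.kind, e.affix_es) for e in entries] == [
            ("suffix", "caína"), ("prefix", "cef")]

    def test_missing_columns_reported_with_line(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text("suffix\t-caine\t-caína\n", encoding="utf-8")
        with pytest.raises(FormatError, match="1"):
            ph.load_affixes(path)

    def test_unknown_kind_lists_accepted(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text("header\ta\tb\tc\td\nwrong\ta\tb\tc\td\n",
                        encoding="utf-8")
        with pytest.raises(FormatError, match="prefix"):
            ph.load_affixes(path)

    def test_empty_file_yields_no_entries(self, tmp_path):
        path = tmp_path / "a.tsv"
        path.write_text("", encoding="utf-8")
        assert ph.load_affixes(path) == []

    def test_suffix_anchored_at_end(self):
        entries = [ph.AffixEntry("suffix", "caína")]
        assert ph.affix_match(tok("lidocaína"), entries) == 1
        assert ph.affix_match(tok("Lidocaína"), entries) == 1
        assert ph.affix_match(tok("caínalido"), entries) == 0
        assert ph.affix_match(tok("caína"), entries) == 1  # bare affix matches

    def test_prefix_and_root_anchoring(self):
        prefix = [ph.AffixEntry("prefix", "cef")]
        root = [ph.AffixEntry("root", "tiaz")]
        assert ph.affix_match(tok("cefazolina"), prefix) == 1
        assert ph.affix_match(tok("acefalo"), prefix) == 0
        assert ph.affix_match(tok("hidroclorotiazida"), root) == 1
        assert ph.affix_match(tok("ti"), root) == 0  # too short for roots

    def test_empty_entry_list_never_matches(self):
        assert ph.affix_match(tok("lidocaína"), []) == 0

    def test_matches_brute_force_anchoring_oracle(
        self, resources, small_corpus
    ):
        entries = resources["affixes"]

        def brute(surface):
            s = normalize(surface)
            for e in entries:
                if e.kind == "prefix" and s.startswith(e.affix_es):
                    return 1
                if e.kind == "suffix" and s.endswith(e.affix_es):
                    return 1
                if e.kind == "root" and len(s) >= 3 and e.affix_es in s:
                    return 1
            return 0

        rng = np.random.default_rng(2)
        all_tokens = [t for d in small_corpus.docs for t in d.tokens]
        for i in rng.choice(len(all_tokens), size=1000):
            t = all_tokens[int(i)]
            assert ph.affix_match(t, entries) == brute(t.surface), t.surface


class TestPosOnehot:
    def test_unit_vector_at_tag_index(self):
        v = ph.PosVocabulary(["ADJ", "ADP", "NOUN", "VERB"])
        vec = ph.pos_onehot("NOUN", v)
        assert vec.tolist() == [0, 0, 1, 0, 0]

    def test_unseen_tag_maps_to_unk_slot(self):
        v = ph.PosVocabulary(["NOUN"])
        assert ph.pos_onehot("XYZ", v).tolist() == [0, 1]
        assert ph.pos_onehot(None, v).tolist() == [0, 1]

    def test_vocab_dimension_counts_distinct_tags_plus_unk(self, small_corpus):
        v = ph.PosVocabulary.from_corpus(small_corpus.docs[:3])
        distinct = {t.pos for d in small_corpus.docs[:3] for t in d.tokens
                    if t.pos is not None}
        assert v.dim == len(distinct) + 1


class TestFeatureExtractor:
    def test_bundle_invariants_and_determinism(self, resources, small_corpus):
        ex = ph.FeatureExtractor(
            pos_vocab=ph.PosVocabulary.from_corpus(small_corpus.docs),
            gazetteer=resources["gazetteer"],
            affixes=resources["affixes"])
        seen = {}
        for doc in small_corpus.docs[:10]:
            for t in doc.tokens:
                b = ex.bundle(t)
                assert b.pos_onehot.sum() == 1.0
                assert b.gazetteer_flag in (0, 1)
                assert b.affix_flag in (0, 1)
                key = (t.surface, t.pos)
                vec = tuple(ex.vector(t))
                assert seen.setdefault(key, vec) == vec  # position-independent

    def test_disabled_channels_contribute_zero_width(self):
        assert ph.FeatureExtractor().dim == 0
        gaz_only = ph.FeatureExtractor(gazetteer=ph.Gazetteer({"x"}))
        assert gaz_only.dim == 1
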