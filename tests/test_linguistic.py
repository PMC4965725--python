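"""Tokenizer, Porter stemmer, lexicon, keyword choice and parse trees."""

import pytest
from hypothesis import given, settings, strategies as st

import ppi_groupsel as pg
from ppi_groupsel.linguistic import (AlignmentError, ParseError, Tokenization,
                                     detokenize, stub_parse)

LLL_TEXT = ("GerE binds to a site on one of these promoters, cotX, that "
            "overlaps its -35 region")


class TestTokenize:
    def test_word_indices_skip_punctuation(self):
        tk = pg.tokenize(LLL_TEXT)
        surfaces = tk.surfaces()
        assert surfaces[0] == "GerE"
        assert surfaces.index("cotX") + 1 == 11      # 1-based word index
        assert tk.words[10].surface == "cotX" and tk.words[10].index == 11
        assert [p.surface for p in tk.punct] == [",", ","]

    def test_hyphenated_forms_stay_single_words(self):
        tk = pg.tokenize("inhibited in dose-dependent fashion at -35 region")
        assert "dose-dependent" in tk.surfaces()
        assert "-35" in tk.surfaces()

    @pytest.mark.parametrize("text,n_words,n_punct", [
        ("", 0, 0), ("A, B", 2, 1), ("(A) and B.", 3, 3)])
    def test_counts(self, text, n_words, n_punct):
        tk = pg.tokenize(text)
        assert (len(tk.words), len(tk.punct)) == (n_words, n_punct)

    def test_entity_boundaries_force_splits(self):
        text = "the sigX-ypuN region"
        spans = [(4, 8), (9, 13)]       # sigX, ypuN
        tk = pg.tokenize(text, boundaries=spans)
        assert tk.surfaces() == ["the", "sigX", "ypuN", "region"]
        assert [p.surface for p in tk.punct] == ["-"]

    @given(st.text(alphabet="abcZ-,.()/ ", max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_idempotent_on_detokenized_output(self, text):
        tk = pg.tokenize(text)
        again = pg.tokenize(detokenize(tk))
        assert again.surfaces() == tk.surfaces()
        assert [p.surface for p in again.punct] == \
            [p.surface for p in tk.punct]


class TestStem:
    @pytest.mark.parametrize("a,b", [
        ("binds", "bind"), ("binding", "bind"), ("stimulates", "stimulate"),
        ("stimulation", "stimulate"), ("association", "associate"),
        ("regulates", "regulate"), ("induced", "induce"),
        ("interacts", "interact"), ("activation", "activate"),
        ("inhibits", "inhibit"), ("phosphorylated", "phosphorylate"),
    ])
    def test_equivalence_classes(self, a, b):
        assert pg.stem(a) == pg.stem(b)

    def test_protein_name_lowercased_only(self):
        assert pg.stem("GerE") == "gere"

    @given(st.text(alphabet=st.characters(min_codepoint=97,
                                          max_codepoint=122),
                   min_size=1, max_size=15))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_idempotent(self, word):
        assert pg.stem(pg.stem(word)) == pg.stem(word)


class TestLexicon:
    def test_second_keywords_folded_into_keywords(self, lexicon):
        assert set(lexicon.second_keywords) <= lexicon.keywords
        assert len(lexicon.second_keywords) == 7

    def test_entries_are_stems(self, lexicon):
        assert all(w == pg.stem(w) or not w.isalpha()
                   for w in lexicon.keywords)

    def test_load_sections(self, tmp_path):
        path = tmp_path / "lex.txt"
        path.write_text("[keywords]\ncleaves\n[iverb]\ncleaves\n"
                        "[inoun]\ncleavage\n")
        lex = pg.Lexicon.load(path)
        assert pg.stem("cleaved") in lex.keywords
        assert pg.stem("cleaves") in lex.iverb


class TestFindKeyword:
    def test_single_hit(self, lexicon, blinded_factory):
        b = blinded_factory(["PROT1", "binds", "PROT2"], 1, 3)
        kw = pg.find_keyword(b, lexicon)
        assert kw.stem == pg.stem("bind")
        assert kw.token_index == 2 and kw.all_matches == (2,)

    def test_no_hit_returns_none(self, lexicon, blinded_factory):
        b = blinded_factory(["PROT1", "near", "PROT2"], 1, 3)
        assert pg.find_keyword(b, lexicon) is None

    def test_two_hits_recorded(self, lexicon, blinded_factory):
        b = blinded_factory(
            ["PROT1", "binds", "and", "regulates", "PROT2"], 1, 5)
        kw = pg.find_keyword(b, lexicon)
        assert len(kw.all_matches) == 2
        assert kw.stem == pg.stem("bind")       # nearest P1 among infix hits

    def test_infix_hit_preferred_over_outside(self, lexicon, blinded_factory):
        b = blinded_factory(
            ["binding", "of", "PROT1", "regulates", "PROT2"], 3, 5)
        assert pg.find_keyword(b, lexicon).stem == pg.stem("regulate")

    def test_placeholders_never_match(self, lexicon, blinded_factory):
        b = blinded_factory(["PROT1", "with", "PROT0", "and", "PROT2"], 1, 5)
        assert pg.find_keyword(b, lexicon) is None


class TestParseTree:
    TREE = ("(S (NP (NNP Oxytocin)) (VP (VBZ stimulates) "
            "(NP (NN production))))")

    def test_bracketed_round_trip(self):
        tree = pg.ParseTree.from_string(self.TREE)
        assert pg.ParseTree.from_string(tree.to_string()).to_string() \
            == tree.to_string()
        assert tree.leaves() == ["Oxytocin", "stimulates", "production"]

    def test_pos_path_and_height(self):
        tree = pg.ParseTree.from_string(self.TREE)
        assert tree.pos_path(0) == ["NP", "NNP"]
        assert tree.height(0) == 2
        assert tree.pos_path(2) == ["VP", "NP", "NN"]

    def test_degenerate_single_level_tree(self):
        tree = pg.ParseTree.from_string("(ROOT word)")
        assert tree.pos_path(0) == []
        assert tree.height(0) == 1

    def test_unbalanced_brackets_rejected(self):
        with pytest.raises(ParseError):
            pg.ParseTree.from_string("(S (NP word)")

    def test_stub_is_deterministic_and_aligned(self, lexicon):
        words = ["PROT1", "binds", "to", "PROT2"]
        t1, t2 = stub_parse(words, lexicon), stub_parse(words, lexicon)
        assert t1.to_string() == t2.to_string()
        assert t1.leaves() == words

    def test_empty_sentence_rejected(self):
        with pytest.raises(ParseError):
            stub_parse([])

    def test_misaligned_backend_raises(self):
        with pytest.raises(AlignmentError, match="s9"):
            pg.parse(["a", "b"], backend="(S (NN a))", sent_id="s9")

    @given(st.lists(st.sampled_from(
        ["PROT1", "PROT2", "binds", "the", "cell", "of", "and", "-35"]),
        min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_leaf_count_equals_token_count(self, words):
        assert stub_parse(words).leaves() == words
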