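"""Feature families, syntax-pattern matching and vector assembly."""

import random

import pytest
from hypothesis import given, settings, strategies as st

import ppi_groupsel as pg
from ppi_groupsel.features import (GROUPS, PATTERNS, MISSING_NUMERIC,
                                   NONE_CATEGORY, assemble_vector,
                                   extract_lexical, extract_pattern_features,
                                   extract_syntactic, extract_word_context,
                                   match_pattern)
from ppi_groupsel.linguistic import stem, stub_parse

from conftest import make_blinded


def _features(sentence, lexicon, index=0):
    inst = pg.enumerate_instances(sentence)[index]
    blinded = pg.blind_instance(inst)
    keyword = pg.find_keyword(blinded, lexicon)
    return blinded, keyword


class TestLexicalFeatures:
    def test_oxytocin_example(self, worked_sentences, lexicon):
        blinded, kw = _features(worked_sentences["IEPA.d0.s0"], lexicon)
        out = extract_lexical(blinded, kw, lexicon)
        assert out["keyword"] == stem("stimulate")
        # the chosen keyword itself and the six absent words are all false
        assert all(out[f"second_kw_{w}"] is False
                   for w in lexicon.second_keywords)
        assert out["condition_word"] is False

    def test_negation_between_proteins(self, worked_sentences, lexicon):
        sent = worked_sentences["HPRD50.d21.s1"]
        blinded, kw = _features(sent, lexicon, index=2)   # (CB1, OX1R)
        out = extract_lexical(blinded, kw, lexicon)
        assert out["negative_word"] is True

    def test_preposition_of_keyword(self, worked_sentences, lexicon):
        blinded, kw = _features(worked_sentences["AIMed.d55.s487"], lexicon)
        out = extract_lexical(blinded, kw, lexicon)
        assert out["keyword"] == stem("bind")
        assert out["preposition_of_keyword"] == "of"

    def test_but_and_which(self, worked_sentences, lexicon):
        b485, k485 = _features(worked_sentences["AIMed.d55.s485"], lexicon)
        assert extract_lexical(b485, k485, lexicon)["but"] is True
        b13, k13 = _features(worked_sentences["LLL.d13.s0"], lexicon)
        assert extract_lexical(b13, k13, lexicon)["which"] is True

    def test_second_keyword_true_when_not_chosen(self, lexicon):
        b = make_blinded(
            ["PROT1", "binds", "and", "interacts", "with", "PROT2"], 1, 6)
        kw = pg.find_keyword(b, lexicon)
        out = extract_lexical(b, kw, lexicon)
        assert kw.stem == stem("bind")
        assert out[f"second_kw_{stem('interact')}"] is True
        assert out[f"second_kw_{stem('bind')}"] is False   # chosen as K


class TestWordContext:
    def test_lll_table_values(self, worked_sentences, lexicon):
        blinded, kw = _features(worked_sentences["LLL.d33.s1"], lexicon)
        out = extract_word_context(blinded, kw)
        assert out["Distance_KP1"] == 0
        assert out["Distance_KP2"] == 8
        assert out["Distance_P1P2"] == 9
        assert out["Position_P1"] == 1
        assert out["Position_P2"] == 11
        assert out["position_of_keyword"] == "infix"
        assert out["comma_pattern"] == "ft"
        assert out["multiple_keywords"] is False

    def test_adjacent_triple(self, lexicon):
        b = make_blinded(["a", "PROT1", "binds", "PROT2"], 2, 4)
        out = extract_word_context(b, pg.find_keyword(b, lexicon))
        # the keyword itself lies between the proteins, so Distance_P1P2
        # counts it (consistent with the printed example: 9 = keyword + 8)
        assert (out["Distance_KP1"], out["Distance_KP2"],
                out["Distance_P1P2"]) == (0, 0, 1)
        assert (out["Position_P1"], out["Position_P2"]) == (2, 4)

    def test_parallel_expression_pairs(self, worked_sentences, lexicon):
        sent = worked_sentences["LLL.d30.s0"]
        flags = {}
        for inst in pg.enumerate_instances(sent):
            blinded = pg.blind_instance(inst)
            kw = pg.find_keyword(blinded, lexicon)
            flags[(inst.p1.text, inst.p2.text)] = \
                extract_word_context(blinded, kw)["parallel_expression"]
        assert flags[("sigma(A)", "sigma(X)")] is True
        assert flags[("sigX", "ypuN")] is True
        assert sum(flags.values()) == 2

    def test_missing_keyword_sentinels(self):
        b = make_blinded(["PROT1", "near", "PROT2"], 1, 3)
        out = extract_word_context(b, None)
        assert out["Distance_KP1"] == MISSING_NUMERIC
        assert out["position_of_keyword"] == NONE_CATEGORY
        assert out["multiple_keywords"] is False
        assert out["Distance_P1P2"] == 1

    @given(st.integers(1, 8), st.integers(0, 8), st.integers(0, 8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_order_invariants(self, p1, gap_a, gap_b):
        words = (["w"] * (p1 - 1) + ["PROT1"] + ["w"] * gap_a + ["binds"]
                 + ["w"] * gap_b + ["PROT2"])
        b = make_blinded(words, p1, len(words))
        kw = pg.KeywordMatch(stem("bind"), p1 + gap_a + 1,
                             (p1 + gap_a + 1,))
        out = extract_word_context(b, kw)
        assert out["Position_P2"] > out["Position_P1"]
        assert out["Distance_P1P2"] >= 0
        assert (out["position_of_keyword"] == "infix") == \
            (out["Position_P1"] < kw.token_index < out["Position_P2"])
        if out["parallel_expression"]:
            assert out["Distance_P1P2"] <= 1


class TestSyntacticFeatures:
    def test_fig_tree_values(self, worked_sentences, lexicon):
        sent = worked_sentences["IEPA.d0.s0"]
        blinded, kw = _features(sent, lexicon)
        tree = pg.ParseTree.from_string(sent.parse)
        out = extract_syntactic(blinded, kw, tree)
        assert (out["Height_P1"], out["POS_P1"]) == (2, "NP, NNP")
        assert (out["Height_P2"], out["POS_P2"]) == (4, "VP, NP, NP, CD")
        assert (out["Height_K"], out["POS_K"]) == (2, "VP, VBZ")

    def test_misaligned_tree_rejected(self, lexicon):
        b = make_blinded(["PROT1", "binds", "PROT2"], 1, 3)
        with pytest.raises(Exception, match="align|leaves"):
            extract_syntactic(b, None, pg.ParseTree.from_string("(S (NN x))"))

    def test_missing_keyword_sentinels(self):
        b = make_blinded(["PROT1", "near", "PROT2"], 1, 3)
        out = extract_syntactic(b, None, stub_parse(b.words))
        assert out["Height_K"] == MISSING_NUMERIC
        assert out["POS_K"] == NONE_CATEGORY


# ---------------------------------------------------------------------------
# Syntax patterns
# ---------------------------------------------------------------------------

def oracle_match(pattern, blinded, lexicon, limit=5):
    """Independent brute-force oracle: explicitly enumerate every wildcard
    expansion 0..limit at every start position."""
    words = blinded.words
    stems = [stem(w) for w in words]
    placeholders = {"PROT0", "PROT1", "PROT2"}
    n = len(words)

    def ok(element, i):
        kind = element[0]
        if kind == "P1":
            return words[i] == "PROT1"
        if kind == "P2":
            return words[i] == "PROT2"
        if words[i] in placeholders:
            return False
        if kind == "lit":
            return stems[i] == element[1]
        if kind == "alt":
            return stems[i] in element[1]
        if kind == "IVERB":
            return stems[i] in lexicon.iverb
        if kind == "INOUN":
            return stems[i] in lexicon.inoun
        raise AssertionError(element)

    def rec(ei, pos):
        if ei == len(pattern.elements):
            return True
        element = pattern.elements[ei]
        if element[0] == "wild":
            return any(pos + used <= n and rec(ei + 1, pos + used)
                       for used in range(limit + 1))
        return pos < n and ok(element, pos) and rec(ei + 1, pos + 1)

    return any(rec(0, s) for s in range(n))


PATTERN_BY_ID = {p.pattern_id: p for p in PATTERNS}


class TestMatchPattern:
    def test_pattern13_direct_literal(self, lexicon):
        b = make_blinded(
            ["interaction", "between", "PROT1", "and", "PROT2"], 3, 5)
        assert match_pattern(PATTERN_BY_ID[13], b, lexicon) is True
        assert match_pattern(PATTERN_BY_ID[7], b, lexicon) is True

    def test_pattern1_on_oxytocin(self, worked_sentences, lexicon):
        blinded, _ = _features(worked_sentences["IEPA.d0.s0"], lexicon)
        assert stem("stimulate") in lexicon.iverb
        assert match_pattern(PATTERN_BY_ID[1], blinded, lexicon) is True
        assert oracle_match(PATTERN_BY_ID[1], blinded, lexicon) is True

    def test_wildcard_limit_five(self, lexicon):
        words = ["PROT1"] + ["w"] * 6 + ["binds", "PROT2"]
        b = make_blinded(words, 1, 9)
        assert match_pattern(PATTERN_BY_ID[1], b, lexicon) is False
        words = ["PROT1"] + ["w"] * 5 + ["binds", "PROT2"]
        b = make_blinded(words, 1, 8)
        assert match_pattern(PATTERN_BY_ID[1], b, lexicon) is True

    def test_pattern12_matches_on_stems(self, lexicon):
        b = make_blinded(["PROT1", "depends", "of", "PROT2"], 1, 4)
        assert match_pattern(PATTERN_BY_ID[12], b, lexicon) is True

    def test_oracle_agreement_random(self, lexicon):
        rng = random.Random(42)
        vocab = ["the", "complex", "of", "by", "and", "between", "interact",
                 "bind", "interaction", "activation", "cell", "form",
                 "depend", "with", "to", "on", "through", "PROT0", "a"]
        for _ in range(150):
            n = 15
            words = [rng.choice(vocab) for _ in range(n)]
            i, j = sorted(rng.sample(range(n), 2))
            words[i], words[j] = "PROT1", "PROT2"
            b = make_blinded(words, i + 1, j + 1)
            for p in PATTERNS:
                assert match_pattern(p, b, lexicon) == \
                    oracle_match(p, b, lexicon), (p.pattern_id, words)


class TestPatternFeatures:
    def test_subset_pruning_removes_ids(self, lexicon):
        from ppi_groupsel.partitioning import prune_patterns
        b = make_blinded(["PROT1", "binds", "PROT2"], 1, 3)
        feats_a = extract_pattern_features(b, lexicon, prune_patterns("A"))
        assert set(feats_a) == {f"pattern_{i}" for i in range(1, 14)
                                if i not in (7, 8, 9, 13)}
        feats_c = extract_pattern_features(b, lexicon, prune_patterns("C"))
        assert len(feats_c) == 13

    def test_no_match_all_false(self, lexicon):
        b = make_blinded(["PROT1", "near", "PROT2"], 1, 3)
        assert not any(extract_pattern_features(b, lexicon).values())


class TestAssembleVector:
    def test_group_tagging(self, worked_sentences, lexicon):
        sent = worked_sentences["IEPA.d0.s0"]
        blinded, kw = _features(sent, lexicon)
        vec = pg.extract_all(blinded, lexicon, kw,
                             tree=pg.ParseTree.from_string(sent.parse))
        by_group = {}
        for name, group in vec.groups.items():
            by_group.setdefault(group, set()).add(name)
        assert len(by_group["G1"]) == 3
        assert len(by_group["G2"]) == 2
        assert len(by_group["G3"]) == 3
        assert len(by_group["G4"]) == 3
        assert all(vec.kinds[n] == "numeric"
                   for n in GROUPS["G1"] + GROUPS["G2"] + GROUPS["G3"])

    def test_empty_and_collision(self):
        assert assemble_vector().values == {}
        with pytest.raises(ValueError, match="duplicate"):
            assemble_vector({"x": 1}, {"x": 2})
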