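"""Fold plans, in-group search, EvalCon cascade and the three strategies."""

import itertools

import pytest

import ppi_groupsel as pg
from ppi_groupsel.cl_selection import (CLSelector, GroupContribution,
                                       eval_con4, make_folds, resolve_ties)
from ppi_groupsel.evaluation import f_score, prepare_records, \
    vectors_for_subset
from ppi_groupsel.features import GROUPS
from ppi_groupsel.knn import KnnModel


class TestMakeFolds:
    def test_nine_documents_nine_folds(self):
        plan = make_folds([f"d{i}" for i in range(9)], 9, seed=1)
        assert sorted(len(p) for p in plan.partitions) == [1] * 9

    def test_ten_documents_nine_folds(self):
        plan = make_folds([f"d{i}" for i in range(10)], 9, seed=1)
        assert sorted(len(p) for p in plan.partitions) == [1] * 8 + [2]

    def test_deterministic_in_seed(self):
        docs = [f"d{i}" for i in range(17)]
        assert make_folds(docs, 9, 5) == make_folds(docs, 9, 5)
        assert make_folds(docs, 9, 5) != make_folds(docs, 9, 6)

    def test_partition_covers_without_overlap(self):
        docs = [f"d{i}" for i in range(23)]
        plan = make_folds(docs, 9, 3)
        flat = [d for p in plan.partitions for d in p]
        assert sorted(flat) == sorted(docs)

    def test_too_few_documents_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["d0", "d1"], 9, 0)


@pytest.fixture(scope="module")
def selector(lexicon_module):
    corpus = pg.generate_corpus(pg.SimConfig(
        n_documents=24, informative_groups=frozenset({"G1"}), seed=5))
    records = prepare_records(corpus.documents, lexicon_module)
    vectors = vectors_for_subset(records, "C", lexicon_module)
    return CLSelector(vectors, [r.label for r in records],
                      [r.doc_id for r in records], S=9, seed=5)


@pytest.fixture(scope="module")
def lexicon_module():
    return pg.default_lexicon()


class TestBestComboForGroup:
    def test_three_feature_group_evaluates_eight_subsets(self, selector):
        _, _, trace = selector.best_combo_for_group(0, "G1")
        assert len(trace) == 8
        assert {len(c) for c, _ in trace} == {0, 1, 2, 3}

    def test_two_feature_group_evaluates_four_subsets(self, selector):
        _, _, trace = selector.best_combo_for_group(0, "G2")
        assert len(trace) == 4

    def test_max_agrees_with_brute_force(self, selector):
        best_f, best_combo, trace = selector.best_combo_for_group(1, "G3")
        assert best_f == max(f for _, f in trace)
        # tie-break: among argmax combos, the largest then lexicographic
        arg = [c for c, f in trace if f == best_f]
        assert best_combo == arg[0]
        assert all(len(best_combo) >= len(c) or trace.index(
            (best_combo, best_f)) < trace.index((c, best_f)) for c in arg)


class TestEvalCon4:
    def test_strict_winner_takes_all_folds(self):
        fcon = {"G1": [0.9, 0.8, 0.7], "G2": [0.1, 0.2, 0.3],
                "G3": [0.2, 0.1, 0.2], "G4": [0.0, 0.0, 0.0]}
        contribution = eval_con4(fcon)
        assert contribution.counters == {"G1": 3, "G2": 0, "G3": 0, "G4": 0}

    def test_fold_tie_awards_both(self):
        fcon = {"G1": [0.9, 0.5], "G2": [0.9, 0.4],
                "G3": [0.1, 0.6], "G4": [0.0, 0.0]}
        counters = eval_con4(fcon).counters
        assert counters == {"G1": 1, "G2": 1, "G3": 1, "G4": 0}

    def test_counters_sum_at_least_folds(self):
        fcon = {"G1": [0.5, 0.5], "G2": [0.5, 0.5],
                "G3": [0.5, 0.5], "G4": [0.5, 0.5]}
        assert sum(eval_con4(fcon).counters.values()) >= 2


class TestResolveTies:
    def test_no_tie_ranking_by_counters(self):
        fcon = {"G1": [0.2, 0.2], "G2": [0.9, 0.9],
                "G3": [0.5, 0.1], "G4": [0.1, 0.5]}
        ranking = resolve_ties(eval_con4(fcon))
        assert ranking[0] == "G2"

    def test_three_way_tie_resolved_by_a_max(self):
        # G2, G3, G4 each win one fold; A_j differ
        fcon = {"G1": [0.0, 0.0, 0.0],
                "G2": [0.9, 0.1, 0.1],
                "G3": [0.1, 0.8, 0.1],
                "G4": [0.1, 0.1, 0.7]}
        ranking = resolve_ties(eval_con4(fcon))
        assert ranking == ["G2", "G3", "G4", "G1"]

    def test_tie_on_a_max_falls_to_second_max(self):
        fcon = {"G1": [0.9, 0.5, 0.0],
                "G2": [0.0, 0.9, 0.6],
                "G3": [0.0, 0.0, 0.9],
                "G4": [0.9, 0.0, 0.1]}
        # all win exactly one fold (4-way tie), A_j all 0.9 -> A'_j decides
        contribution = eval_con4(fcon)
        assert len(set(contribution.counters.values())) == 1
        ranking = resolve_ties(contribution)
        assert ranking[0] == "G2"       # A' = 0.6 beats 0.5, 0.1, 0.0

    def test_full_tie_falls_back_to_group_index(self):
        fcon = {g: [0.5, 0.5] for g in ("G1", "G2", "G3", "G4")}
        assert resolve_ties(eval_con4(fcon)) == ["G1", "G2", "G3", "G4"]


class TestStrategies:
    def test_best1g_mask_changes_only_top_group(self, selector):
        result = selector.run("best1g")
        contribution = selector.compute_contribution()
        ranking = resolve_ties(contribution)
        top = ranking[0]
        outside = set(selector.all_names) - set(GROUPS[top])
        assert outside <= set(result.mask)
        dropped = set(selector.all_names) - set(result.mask)
        assert dropped <= set(GROUPS[top])

    def test_u3g_stops_at_first_improvement(self, selector):
        result = selector.run("u3g")
        for fold in result.per_fold:
            assert fold["score"] >= fold["baseline"]
            if fold["score"] > fold["baseline"]:
                # hard stop: the last removed feature triggered improvement
                assert len(fold["removed"]) >= 1

    def test_o2g_dominates_baseline_per_fold(self, selector):
        result = selector.run("o2g")
        for fold in result.per_fold:
            assert fold["score"] >= fold["baseline"]

    def test_o2g_dominates_best1g_when_top_group_merged(self, selector):
        contribution = selector.compute_contribution()
        ranking = resolve_ties(contribution)
        o2g = selector.select_o2g(contribution, ranking)
        top = ranking[0]
        for i, fo in enumerate(f["score"] for f in o2g.per_fold):
            assert fo >= contribution.fcon[top][i] - 1e-12

    def test_selection_reproducible(self, lexicon_module):
        corpus = pg.generate_corpus(pg.SimConfig(
            n_documents=20, informative_groups=frozenset({"G1"}), seed=9))
        records = prepare_records(corpus.documents, lexicon_module)
        vectors = vectors_for_subset(records, "C", lexicon_module)
        args = (vectors, [r.label for r in records],
                [r.doc_id for r in records])
        r1 = CLSelector(*args, S=9, seed=4).run("o2g")
        r2 = CLSelector(*args, S=9, seed=4).run("o2g")
        assert r1.mask == r2.mask and r1.winning_fold == r2.winning_fold

    def test_non_group_features_always_retained(self, selector):
        group_features = {f for fs in GROUPS.values() for f in fs}
        for strategy in ("best1g", "u3g", "o2g"):
            result = selector.run(strategy)
            non_group = set(selector.all_names) - group_features
            assert non_group <= set(result.mask)
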