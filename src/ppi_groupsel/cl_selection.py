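"""Contribution-level (CL) evaluation and grouped feature selection.

S-fold document-level cross-validation (default S = 9) runs on a training
collection. For every fold i and every group G_j of related features the
in-group search tries all 2^|G_j| feature combinations (features of other
groups held fixed), trains the k-NN classifier on Train_i and records the
best validation F-score Fcon_ji. The CL of a group counts the folds whose
maximum (over groups) is attained by that group; ties among 3 or 2 groups
are re-scored restricted to the tied groups (EvalCon3 / EvalCon2), then by
the fold maximum A_j, then by the second maximum A'_j, finally by group
index.

Three selection strategies consume the CL ranking:

* BEST1G — adopt the best in-group combination of the top-CL group,
  taken from the fold with the highest Fcon;
* U3G    — per fold, gradually (cumulatively) remove the features of the
  top three groups in CL-major order, stopping at the first strict
  improvement of the validation F-score; adopt the best fold's mask;
* O2G    — per fold, exhaustively search all subsets of the merged top two
  groups; adopt the best fold's mask.

Selection never touches features outside G1..G4.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field

from .evaluation import f_score
from .features import GROUPS, FeatureVector
from .knn import KnnModel

logger = logging.getLogger(__name__)


class DegenerateFoldsError(RuntimeError):
    """Too few usable folds for CL evaluation."""


@dataclass(frozen=True)
class FoldPlan:
    """Document-level partition of a training collection into S folds."""

    S: int
    partitions: tuple[tuple[str, ...], ...]

    def fold_of(self) -> dict[str, int]:
        return {d: i for i, part in enumerate(self.partitions) for d in part}


def make_folds(doc_ids, S: int, seed: int) -> FoldPlan:
    """Shuffle documents by ``seed`` and deal them round-robin into S
    near-equal partitions. Reproducible; no document is split."""
    docs = list(dict.fromkeys(doc_ids))     # unique, order-preserving
    if len(docs) < S:
        raise ValueError(f"need at least {S} documents, have {len(docs)}")
    rng = random.Random(seed)
    rng.shuffle(docs)
    partitions: list[list[str]] = [[] for _ in range(S)]
    for i, doc in enumerate(docs):
        partitions[i % S].append(doc)
    return FoldPlan(S=S, partitions=tuple(tuple(p) for p in partitions))


def _subset_orders(members: tuple[str, ...]):
    """All subsets of a group, largest first, then lexicographic — so the
    first strict maximum realises the more-features / lexicographic
    tie-break."""
    subsets = []
    for r in range(len(members), -1, -1):
        subsets.extend(itertools.combinations(members, r))
    return subsets


@dataclass
class GroupContribution:
    """Per-group CL counters plus the fold traces behind them."""

    fcon: dict[str, list[float]]                 # group -> per-fold Fcon
    combos: dict[str, list[tuple[str, ...]]]     # group -> per-fold best combo
    counters: dict[str, int] = field(default_factory=dict)

    def a_max(self, group: str) -> float:
        return max(self.fcon[group])

    def a_second(self, group: str) -> float:
        scores = sorted(self.fcon[group], reverse=True)
        return scores[1] if len(scores) > 1 else scores[0]


def _win_counts(groups, fcon) -> dict[str, int]:
    counts = {g: 0 for g in groups}
    n_folds = len(fcon[groups[0]])
    for i in range(n_folds):
        best = max(fcon[g][i] for g in groups)
        for g in groups:
            if fcon[g][i] == best:
                counts[g] += 1
    return counts


def eval_con4(fcon: dict[str, list[float]],
              combos: dict[str, list[tuple[str, ...]]] | None = None
              ) -> GroupContribution:
    """Count, per fold, every group attaining the fold maximum of Fcon."""
    groups = list(fcon)
    contribution = GroupContribution(
        fcon=fcon, combos=combos or {g: [] for g in groups})
    contribution.counters = _win_counts(groups, fcon)
    return contribution


def resolve_ties(contribution: GroupContribution) -> list[str]:
    """A strict ranking of the groups from the CL counters.

    Blocks of 3 or 2 groups sharing a CL are re-scored restricted to the
    tied groups (EvalCon3 / EvalCon2); persisting ties fall back to the
    fold maximum A_j, then the second maximum A'_j, then group index (with
    a warning — the procedure does not define this case).
    """
    groups = list(contribution.fcon)
    index = {g: n for n, g in enumerate(groups)}
    C = contribution.counters

    def rank_block(block: list[str]) -> list[str]:
        if len(block) == 1:
            return block
        if len(block) in (2, 3):
            sub = _win_counts(block, contribution.fcon)
        else:
            logger.warning("%d-way CL tie: falling back to fold maxima",
                           len(block))
            sub = {g: 0 for g in block}
        ordered = sorted(block, key=lambda g: (
            -sub[g], -contribution.a_max(g), -contribution.a_second(g),
            index[g]))
        for g1, g2 in zip(ordered, ordered[1:]):
            if (sub[g1], contribution.a_max(g1), contribution.a_second(g1)) \
                    == (sub[g2], contribution.a_max(g2),
                        contribution.a_second(g2)):
                logger.warning("residual CL tie %s/%s broken by group index",
                               g1, g2)
        return ordered

    ranking: list[str] = []
    for cl in sorted(set(C.values()), reverse=True):
        block = [g for g in groups if C[g] == cl]
        ranking.extend(rank_block(block))
    return ranking


@dataclass
class SelectionResult:
    """Outcome of one selection strategy on one training collection."""

    strategy: str
    mask: frozenset[str]
    winning_fold: int
    achieved_f: float
    per_fold: list[dict]


class CLSelector:
    """Runs the CL machinery on one training collection (typically one of
    the subsets A/B/C inside an outer CV fold).

    Parameters
    ----------
    vectors, labels, doc_ids : aligned lists
        The training instances with their document of origin.
    S : int
        Inner fold count (9-fold document-level CV by default).
    k, k_mode, seed : k-NN configuration; ``k=None`` applies the
        square-root rule per inner training fold.
    """

    def __init__(self, vectors: list[FeatureVector], labels, doc_ids,
                 *, S: int = 9, seed: int = 0, k: int | None = None,
                 k_mode: str = "sqrt_rule"):
        self.vectors = list(vectors)
        self.labels = [bool(l) for l in labels]
        self.doc_ids = list(doc_ids)
        self.k, self.k_mode, self.seed = k, k_mode, seed
        self.all_names = tuple(self.vectors[0].values)
        self.group_members = {
            g: tuple(n for n in members if n in self.vectors[0].values)
            for g, members in GROUPS.items()}
        self.plan = make_folds(self.doc_ids, S, seed)
        fold_of = self.plan.fold_of()
        self.folds: list[tuple[list[int], list[int]]] = []
        for i in range(S):
            train = [j for j, d in enumerate(self.doc_ids) if fold_of[d] != i]
            val = [j for j, d in enumerate(self.doc_ids) if fold_of[d] == i]
            if train and val:
                self.folds.append((train, val))
            else:
                logger.warning("skipping inner fold %d: empty side", i)
        if len(self.folds) < 2:
            raise DegenerateFoldsError(
                f"only {len(self.folds)} usable inner folds")
        self._cache: dict[tuple[int, frozenset[str]], float] = {}
        self.n_evaluations = 0

    # -- elementary evaluation ----------------------------------------------

    def fold_f(self, fold_index: int, mask) -> float:
        """Validation F-score of a k-NN trained on the fold with ``mask``."""
        key = (fold_index, frozenset(mask))
        if key not in self._cache:
            train, val = self.folds[fold_index]
            if not val:
                raise ValueError(f"empty validation fold {fold_index}")
            model = KnnModel.fit(
                [self.vectors[j] for j in train],
                [self.labels[j] for j in train],
                mask=mask, k=self.k, k_mode=self.k_mode, seed=self.seed)
            preds = model.predict([self.vectors[j] for j in val])
            truth = [self.labels[j] for j in val]
            self._cache[key] = f_score(truth, preds)
            self.n_evaluations += 1
        return self._cache[key]

    def best_combo_for_group(self, fold_index: int, group: str,
                             base_mask=None):
        """Exhaustive in-group subset search on one fold.

        Returns (best F, best combo, trace of every (combo, F) evaluated).
        Score ties resolve toward the larger, lexicographically earlier
        combination.
        """
        members = self.group_members[group]
        base = set(base_mask if base_mask is not None else self.all_names)
        best_f, best_combo, trace = -1.0, None, []
        for combo in _subset_orders(members):
            mask = (base - set(members)) | set(combo)
            f = self.fold_f(fold_index, mask)
            trace.append((combo, f))
            if f > best_f:
                best_f, best_combo = f, combo
        return best_f, best_combo, trace

    # -- contribution levels -------------------------------------------------

    def compute_contribution(self) -> GroupContribution:
        fcon: dict[str, list[float]] = {g: [] for g in self.group_members}
        combos: dict[str, list[tuple[str, ...]]] = {
            g: [] for g in self.group_members}
        for i in range(len(self.folds)):
            for g in self.group_members:
                f, combo, _ = self.best_combo_for_group(i, g)
                fcon[g].append(f)
                combos[g].append(combo)
        return eval_con4(fcon, combos)

    # -- strategies ----------------------------------------------------------

    def select_best1g(self, contribution: GroupContribution,
                      ranking: list[str]) -> SelectionResult:
        top = ranking[0]
        scores = contribution.fcon[top]
        i_star = max(range(len(scores)), key=lambda i: (scores[i], -i))
        combo = contribution.combos[top][i_star]
        mask = frozenset(set(self.all_names)
                         - set(self.group_members[top]) | set(combo))
        per_fold = [{"fold": i, "score": s,
                     "combo": contribution.combos[top][i]}
                    for i, s in enumerate(scores)]
        return SelectionResult("best1g", mask, i_star, scores[i_star],
                               per_fold)

    def select_u3g(self, contribution: GroupContribution,
                   ranking: list[str]) -> SelectionResult:
        top3 = ranking[:3]
        removal_order = [f for g in top3 for f in self.group_members[g]]
        per_fold, fu, masks = [], [], []
        for i in range(len(self.folds)):
            baseline = self.fold_f(i, self.all_names)
            current = set(self.all_names)
            chosen, score = frozenset(self.all_names), baseline
            removed = []
            for feat in removal_order:
                current = current - {feat}
                f = self.fold_f(i, current)
                removed.append(feat)
                if f > baseline:        # improved even slightly: stop
                    chosen, score = frozenset(current), f
                    break
            else:
                removed = []
            fu.append(score)
            masks.append(chosen)
            per_fold.append({"fold": i, "baseline": baseline, "score": score,
                             "removed": removed})
        i_star = max(range(len(fu)), key=lambda i: (fu[i], -i))
        return SelectionResult("u3g", masks[i_star], i_star, fu[i_star],
                               per_fold)

    def select_o2g(self, contribution: GroupContribution,
                   ranking: list[str]) -> SelectionResult:
        top2 = ranking[:2]
        merged = tuple(f for g in top2 for f in self.group_members[g])
        fixed = set(self.all_names) - set(merged)
        per_fold, fo, masks = [], [], []
        for i in range(len(self.folds)):
            baseline = self.fold_f(i, self.all_names)
            best_f, best_mask = -1.0, None
            for combo in _subset_orders(merged):
                mask = fixed | set(combo)
                f = self.fold_f(i, mask)
                if f > best_f:
                    best_f, best_mask = f, frozenset(mask)
            fo.append(best_f)
            masks.append(best_mask)
            per_fold.append({"fold": i, "baseline": baseline,
                             "score": best_f})
        i_star = max(range(len(fo)), key=lambda i: (fo[i], -i))
        return SelectionResult("o2g", masks[i_star], i_star, fo[i_star],
                               per_fold)

    def run(self, strategy: str) -> SelectionResult:
        """CL evaluation, tie resolution and the named strategy."""
        if strategy == "none":
            return SelectionResult("none", frozenset(self.all_names), -1,
                                   float("nan"), [])
        contribution = self.compute_contribution()
        ranking = resolve_ties(contribution)
        if strategy == "best1g":
            return self.select_best1g(contribution, ranking)
        if strategy == "u3g":
            return self.select_u3g(contribution, ranking)
        if strategy == "o2g":
            return self.select_o2g(contribution, ranking)
        raise ValueError(f"unknown strategy {strategy!r}")
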