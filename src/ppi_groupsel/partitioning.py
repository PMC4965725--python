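"""Significant keywords and division of the training set into subsets.

A keyword K is *significant* (SK) when the classes of training instances
containing it are strongly imbalanced: with N_P positive and N_N negative
instances whose designated keyword is K, the imbalance degree is

    ID(K) = N_P / N_N          (infinite when N_N = 0),

and K is an SK when min(ID, 1/ID) < T (default T = 0.18). Training
instances are then routed into three subsets:

    A: designated keyword is an SK and sits between the proteins (infix);
    B: designated keyword is an SK, prefix or postfix;
    C: no SK (including instances without any keyword).

Each subset trains its own classifier, and syntax patterns incompatible
with the subset's sentence structure are pruned beforehand: subset A drops
patterns 7, 8, 9 and 13 (keyword-first phrases), subset B drops patterns
1, 2, 10 and 12 (subject-verb-object shapes), subset C keeps all 13.

SK statistics must be computed from training data only; unseen test-time
keywords route to C.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .features import PATTERNS, SyntaxPattern

logger = logging.getLogger(__name__)

#: Default imbalance threshold.
DEFAULT_T = 0.18

#: Pattern ids removed per training subset.
REMOVED_PATTERNS: dict[str, frozenset[int]] = {
    "A": frozenset({7, 8, 9, 13}),
    "B": frozenset({1, 2, 10, 12}),
    "C": frozenset(),
}


@dataclass(frozen=True)
class KeywordStats:
    """Class counts and imbalance degree of one keyword stem."""

    stem: str
    n_pos: int
    n_neg: int

    @property
    def id_value(self) -> float:
        """ID(K) = N_P / N_N; infinity when N_N = 0; NaN when unseen."""
        if self.n_neg == 0:
            return math.inf if self.n_pos > 0 else math.nan
        return self.n_pos / self.n_neg


def imbalance_degree(keyword_stem: str, instances) -> KeywordStats:
    """Count labeled training instances whose designated keyword is the stem.

    ``instances`` is an iterable of (keyword_stem_or_None, label) pairs or of
    objects with ``.keyword_stem`` and ``.label`` attributes.
    """
    n_pos = n_neg = 0
    for item in instances:
        if isinstance(item, tuple):
            k, label = item
        else:
            k, label = item.keyword_stem, item.label
        if k != keyword_stem:
            continue
        if label:
            n_pos += 1
        else:
            n_neg += 1
    stats = KeywordStats(stem=keyword_stem, n_pos=n_pos, n_neg=n_neg)
    if n_pos == 0 and n_neg == 0:
        logger.warning("keyword %r absent from the training set: ID undefined",
                       keyword_stem)
    return stats


def is_significant(stats: KeywordStats, T: float = DEFAULT_T) -> bool:
    """True iff min(ID, 1/ID) < T, i.e. K is strongly class-imbalanced."""
    if not 0 < T < 1:
        raise ValueError(f"threshold T must lie in (0, 1), got {T}")
    idv = stats.id_value
    if math.isnan(idv):
        logger.warning("ID(%r) undefined; treating as not significant",
                       stats.stem)
        return False
    if math.isinf(idv):
        return True     # 1/inf = 0 < T: completely imbalanced
    if idv == 0:
        return True
    return min(idv, 1.0 / idv) < T


def significant_keywords(instances, T: float = DEFAULT_T) -> set[str]:
    """The SK set of a labeled training collection.

    ``instances`` as in :func:`imbalance_degree`; keyword-less instances
    (stem None) are ignored.
    """
    pairs = []
    for item in instances:
        if isinstance(item, tuple):
            pairs.append(item)
        else:
            pairs.append((item.keyword_stem, item.label))
    stems = {k for k, _ in pairs if k is not None}
    return {k for k in stems
            if is_significant(imbalance_degree(k, pairs), T)}


def assign_subset(keyword_stem: str | None, position_of_keyword: str,
                  sk_set: set[str]) -> str:
    """Route an instance to subset A, B or C.

    A: SK present and infix; B: SK present, prefix/postfix; C: otherwise
    (no keyword, or keyword not significant / unseen in training).
    """
    if keyword_stem is None or keyword_stem not in sk_set:
        return "C"
    return "A" if position_of_keyword == "infix" else "B"


def prune_patterns(label: str,
                   all_patterns=PATTERNS) -> tuple[SyntaxPattern, ...]:
    """The active syntax patterns of a subset (A: 9, B: 9, C: all 13)."""
    if label not in REMOVED_PATTERNS:
        raise ValueError(f"unknown subset label {label!r}")
    removed = REMOVED_PATTERNS[label]
    return tuple(p for p in all_patterns if p.pattern_id not in removed)
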