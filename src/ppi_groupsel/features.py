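"""The four feature families of the PPI extractor and their assembly.

An instance (ordered protein pair P1, P2 in a blinded sentence, with
designated interaction keyword K where one exists) is described by:

* lexical features read straight off the sentence (keyword identity,
  negation, conjunctions, the preposition following K, the seven "second
  keyword" indicator bits);
* word-context features (word distances between K, P1 and P2; 1-based word
  positions; infix/prefix/postfix keyword order; comma placement within the
  K/P1/P2 triple; multiple keyword occurrence; parallel protein expression);
* syntactic features from a constituency tree (leaf heights and
  root-to-leaf POS paths of P1, P2 and K);
* boolean matches against 13 interaction syntax patterns with bounded
  ("at most five words") wildcards.

Four groups of related features — G1 distances, G2 positions, G3 heights,
G4 POS paths — are tagged on the assembled vector; the contribution-level
selection machinery operates on exactly these groups.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus_io import PROT0, PROT1, PROT2, BlindedInstance
from .linguistic import (CONDITION_WORDS, PREPOSITIONS, KeywordMatch, Lexicon,
                         ParseTree, AlignmentError, stem)

#: Sentinel for numeric features undefined without a keyword; the scaler maps
#: it to the top of the training range.
MISSING_NUMERIC = -1
#: Sentinel category for undefined categorical features.
NONE_CATEGORY = "NONE"

#: The four groups of related features.
GROUPS: dict[str, tuple[str, ...]] = {
    "G1": ("Distance_KP1", "Distance_KP2", "Distance_P1P2"),
    "G2": ("Position_P1", "Position_P2"),
    "G3": ("Height_P1", "Height_P2", "Height_K"),
    "G4": ("POS_P1", "POS_P2", "POS_K"),
}

NUMERIC_FEATURES = frozenset(GROUPS["G1"] + GROUPS["G2"] + GROUPS["G3"])

_PLACEHOLDERS = {PROT0, PROT1, PROT2}


def feature_kind(name: str) -> str:
    return "numeric" if name in NUMERIC_FEATURES else "categorical"


def feature_group(name: str) -> str:
    for group, members in GROUPS.items():
        if name in members:
            return group
    return "none"


@dataclass
class FeatureVector:
    """Named mixed-type features with group tags."""

    values: dict[str, object]
    kinds: dict[str, str]
    groups: dict[str, str]

    def names(self) -> list[str]:
        return list(self.values)


def assemble_vector(*parts: dict[str, object]) -> FeatureVector:
    """Merge disjoint partial feature maps into one group-tagged vector."""
    values: dict[str, object] = {}
    for part in parts:
        for name, value in part.items():
            if name in values:
                raise ValueError(f"duplicate feature name {name!r}")
            values[name] = value
    return FeatureVector(
        values=values,
        kinds={n: feature_kind(n) for n in values},
        groups={n: feature_group(n) for n in values},
    )


# ---------------------------------------------------------------------------
# Lexical features (sentence surface)
# ---------------------------------------------------------------------------

def _between(lo: int, hi: int) -> range:
    """1-based word indices strictly between positions lo and hi."""
    lo, hi = min(lo, hi), max(lo, hi)
    return range(lo + 1, hi)


def _windows(blinded: BlindedInstance, keyword: KeywordMatch | None):
    """The K<->P1, K<->P2 and P1<->P2 windows (word indices, strict)."""
    wins = [_between(blinded.p1_index, blinded.p2_index)]
    if keyword is not None:
        wins.append(_between(keyword.token_index, blinded.p1_index))
        wins.append(_between(keyword.token_index, blinded.p2_index))
    return wins


def extract_lexical(blinded: BlindedInstance,
                    keyword: KeywordMatch | None,
                    lexicon: Lexicon) -> dict[str, object]:
    words = blinded.words
    lower = [w.lower() for w in words]

    def in_windows(test) -> bool:
        return any(test(lower[i - 1]) for win in _windows(blinded, keyword)
                   for i in win)

    out: dict[str, object] = {
        "keyword": keyword.stem if keyword else NONE_CATEGORY,
        "negative_word": in_windows(lambda w: w in lexicon.negative_words),
        "conjunctive_word": any(w in lexicon.conjunctive_words for w in lower),
        "which": "which" in lower,
        "but": "but" in lower,
        "condition_word": in_windows(lambda w: w in CONDITION_WORDS),
    }

    prep = NONE_CATEGORY
    if keyword is not None:
        for j in range(keyword.token_index + 1,
                       min(keyword.token_index + 3, len(words)) + 1):
            if lower[j - 1] in PREPOSITIONS:
                prep = lower[j - 1]
                break
    out["preposition_of_keyword"] = prep

    pair_window = _between(blinded.p1_index, blinded.p2_index)
    between_stems = {stem(words[i - 1]) for i in pair_window
                     if words[i - 1] not in _PLACEHOLDERS}
    for second in lexicon.second_keywords:
        taken_as_k = keyword is not None and keyword.stem == second
        out[f"second_kw_{second}"] = (not taken_as_k
                                      and second in between_stems)
    return out


# ---------------------------------------------------------------------------
# Word-context features
# ---------------------------------------------------------------------------

def _word_distance(a: int, b: int) -> int:
    """Count of words strictly between two 1-based word positions."""
    return max(abs(a - b) - 1, 0)


def extract_word_context(blinded: BlindedInstance,
                         keyword: KeywordMatch | None) -> dict[str, object]:
    p1, p2 = blinded.p1_index, blinded.p2_index
    out: dict[str, object] = {
        "Distance_P1P2": _word_distance(p1, p2),
        "Position_P1": p1,
        "Position_P2": p2,
    }
    if keyword is None:
        out.update({
            "Distance_KP1": MISSING_NUMERIC,
            "Distance_KP2": MISSING_NUMERIC,
            "position_of_keyword": NONE_CATEGORY,
            "comma_pattern": NONE_CATEGORY,
            "multiple_keywords": False,
        })
    else:
        k = keyword.token_index
        out["Distance_KP1"] = _word_distance(k, p1)
        out["Distance_KP2"] = _word_distance(k, p2)
        if p1 < k < p2:
            pos = "infix"
        elif k < p1:
            pos = "prefix"
        else:
            pos = "postfix"
        out["position_of_keyword"] = pos
        a, b, c = sorted((k, p1, p2))
        x1 = any(a <= cw < b for cw in blinded.comma_after)
        x2 = any(b <= cw < c for cw in blinded.comma_after)
        out["comma_pattern"] = ("t" if x1 else "f") + ("t" if x2 else "f")
        out["multiple_keywords"] = len(keyword.all_matches) > 1

    gap = _word_distance(p1, p2)
    parallel = gap == 0 or (
        gap == 1 and blinded.words[min(p1, p2)].lower() in ("and", "or"))
    out["parallel_expression"] = parallel
    return out


# ---------------------------------------------------------------------------
# Syntactic features
# ---------------------------------------------------------------------------

def extract_syntactic(blinded: BlindedInstance,
                      keyword: KeywordMatch | None,
                      tree: ParseTree) -> dict[str, object]:
    """Heights and POS root-paths of P1, P2 and K from a constituency tree.

    The tree's leaves must align one-to-one with the blinded word sequence.
    """
    leaves = tree.leaves()
    if len(leaves) != len(blinded.words):
        raise AlignmentError(
            f"tree has {len(leaves)} leaves but the blinded sentence has "
            f"{len(blinded.words)} words")

    def leaf_features(prefix: str, word_index: int) -> dict[str, object]:
        i = word_index - 1
        return {
            f"Height_{prefix}": tree.height(i),
            f"POS_{prefix}": ", ".join(tree.pos_path(i)),
        }

    out: dict[str, object] = {}
    out.update(leaf_features("P1", blinded.p1_index))
    out.update(leaf_features("P2", blinded.p2_index))
    if keyword is not None:
        out.update(leaf_features("K", keyword.token_index))
    else:
        out["Height_K"] = MISSING_NUMERIC
        out["POS_K"] = NONE_CATEGORY
    return out


# ---------------------------------------------------------------------------
# Syntax patterns
# ---------------------------------------------------------------------------

#: Maximum number of words one wildcard may stand for.
WILDCARD_LIMIT = 5

# element kinds
LIT, ALT, WILD, P1_EL, P2_EL, IVERB, INOUN = (
    "lit", "alt", "wild", "P1", "P2", "IVERB", "INOUN")


@dataclass(frozen=True)
class SyntaxPattern:
    """One interaction syntax pattern: an ordered element sequence."""

    pattern_id: int
    elements: tuple[tuple, ...]

    @property
    def name(self) -> str:
        return f"pattern_{self.pattern_id}"


def _lit(word: str) -> tuple:
    return (LIT, stem(word))


def _alt(*words: str) -> tuple:
    return (ALT, tuple(stem(w) for w in words))


#: The 13 interaction syntax patterns ('*' is a bounded wildcard).
PATTERNS: tuple[SyntaxPattern, ...] = (
    SyntaxPattern(1, ((P1_EL,), (WILD,), (IVERB,), (WILD,), (P2_EL,))),
    SyntaxPattern(2, ((P1_EL,), (WILD,), (IVERB,), (WILD,), _lit("by"),
                      (WILD,), (P2_EL,))),
    SyntaxPattern(3, ((IVERB,), _lit("of"), (WILD,), (P1_EL,), (WILD,),
                      _lit("by"), (WILD,), (P2_EL,))),
    SyntaxPattern(4, ((IVERB,), _lit("of"), (WILD,), (P1_EL,), (WILD,),
                      _lit("to"), (WILD,), (P2_EL,))),
    SyntaxPattern(5, ((INOUN,), _lit("of"), (WILD,), (P1_EL,), (WILD,),
                      _alt("by", "through"), (WILD,), (P2_EL,))),
    SyntaxPattern(6, ((INOUN,), _lit("of"), (WILD,), (P1_EL,), (WILD,),
                      _alt("with", "to", "on"), (WILD,), (P2_EL,))),
    SyntaxPattern(7, ((INOUN,), _lit("between"), (WILD,), (P1_EL,), (WILD,),
                      _lit("and"), (WILD,), (P2_EL,))),
    SyntaxPattern(8, (_lit("complex"), _lit("between"), (WILD,), (P1_EL,),
                      (WILD,), _lit("and"), (WILD,), (P2_EL,))),
    SyntaxPattern(9, (_lit("complex"), _lit("of"), (WILD,), (P1_EL,),
                      (WILD,), _lit("and"), (WILD,), (P2_EL,))),
    SyntaxPattern(10, ((P1_EL,), (WILD,), _lit("form"), (WILD,),
                       _lit("complex"), _lit("with"), (WILD,), (IVERB,),
                       (WILD,), (P2_EL,))),
    SyntaxPattern(11, ((P1_EL,), (WILD,), (P2_EL,), (WILD,), (INOUN,))),
    SyntaxPattern(12, ((P1_EL,), _lit("depend"), _lit("of"), (P2_EL,))),
    SyntaxPattern(13, (_lit("between"), (P1_EL,), _lit("and"), (P2_EL,))),
)


def _element_matches(element: tuple, word: str, word_stem: str,
                     lexicon: Lexicon) -> bool:
    kind = element[0]
    if kind == P1_EL:
        return word == PROT1
    if kind == P2_EL:
        return word == PROT2
    if word in _PLACEHOLDERS:
        return False
    if kind == LIT:
        return word_stem == element[1]
    if kind == ALT:
        return word_stem in element[1]
    if kind == IVERB:
        return word_stem in lexicon.iverb
    if kind == INOUN:
        return word_stem in lexicon.inoun
    raise ValueError(f"unknown pattern element {element!r}")


def match_pattern(pattern: SyntaxPattern, blinded: BlindedInstance,
                  lexicon: Lexicon) -> bool:
    """True iff the pattern matches a contiguous subsequence of the blinded
    sentence with every wildcard consuming 0..5 words.

    Literal elements compare on stems; P1/P2 match only the instance's own
    placeholder tokens; wildcards may consume any word.
    """
    words = blinded.words
    stems = [stem(w) for w in words]
    n = len(words)
    for start in range(n):
        positions = {start}
        for element in pattern.elements:
            nxt: set[int] = set()
            if element[0] == WILD:
                for p in positions:
                    nxt.update(range(p, min(p + WILDCARD_LIMIT, n) + 1))
            else:
                for p in positions:
                    if p < n and _element_matches(element, words[p], stems[p],
                                                 lexicon):
                        nxt.add(p + 1)
            positions = nxt
            if not positions:
                break
        if positions:
            return True
    return False


def extract_pattern_features(blinded: BlindedInstance, lexicon: Lexicon,
                             active_patterns=PATTERNS) -> dict[str, object]:
    """One boolean per active pattern; pruned pattern ids are absent."""
    return {p.name: match_pattern(p, blinded, lexicon)
            for p in active_patterns}


# ---------------------------------------------------------------------------
# Full extraction for one instance
# ---------------------------------------------------------------------------

def extract_all(blinded: BlindedInstance, lexicon: Lexicon,
                keyword: KeywordMatch | None,
                tree: ParseTree | None = None,
                active_patterns=PATTERNS) -> FeatureVector:
    """Assemble the complete feature vector of a blinded instance.

    With ``tree`` None a deterministic stub parse of the blinded words is
    used, so syntactic features never require a parser binary.
    """
    from .linguistic import stub_parse

    if tree is None:
        tree = stub_parse(blinded.words, lexicon)
    return assemble_vector(
        extract_lexical(blinded, keyword, lexicon),
        extract_word_context(blinded, keyword),
        extract_syntactic(blinded, keyword, tree),
        extract_pattern_features(blinded, lexicon, active_patterns),
    )
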