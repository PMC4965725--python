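"""Tokenization, stemming, lexicons, keyword identification and parse trees.

Word-distance features count *words*: standalone punctuation (commas,
periods, parentheses...) is recorded separately and excluded from word-index
numbering, while hyphenated forms such as "dose-dependent" or "-35" remain
single words. The stemmer is the classic Porter suffix-stripping algorithm;
all lexicon comparisons happen on stems, so only stem-equivalence classes
matter, never literal stem strings.

The interaction-keyword lexicon shipped with the package
(``data/default_lexicon.txt``) is a curated stand-in for the unpublished
642-word list behind the original system: it seeds the printed examples
('bind', 'link', 'stimulate', 'interact', 'induce', 'regulate', 'mediate',
'inhibit', ...) with common interaction verbs and nouns, and is fully
editable (plain text, one entry per line, ``[section]`` headers).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

logger = logging.getLogger(__name__)

# Characters treated as standalone punctuation when they flank a token.
_EDGE_PUNCT = ",.;:!?()[]{}\"`"
_CONNECTOR_PUNCT = {"-", "/", "("}


@dataclass(frozen=True)
class Token:
    """A word token: surface form, character span, 1-based word index."""

    surface: str
    start: int
    end: int
    index: int = 0      # 1-based for words; 0 for punctuation records


@dataclass
class Tokenization:
    words: list[Token]
    punct: list[Token]

    def surfaces(self) -> list[str]:
        return [t.surface for t in self.words]


def _split_raw(text: str, boundaries) -> list[tuple[int, int]]:
    """Whitespace chunks further cut at entity-span edges."""
    cuts = sorted({b for span in (boundaries or []) for b in span})
    chunks = []
    for m in re.finditer(r"\S+", text):
        start, end = m.start(), m.end()
        inner = [c for c in cuts if start < c < end]
        for a, b in zip([start] + inner, inner + [end]):
            if a < b:
                chunks.append((a, b))
    return chunks


def tokenize(text: str, boundaries=None) -> Tokenization:
    """Tokenize ``text`` into word tokens plus punctuation records.

    Parameters
    ----------
    text : str
        Raw sentence text.
    boundaries : iterable of (start, end), optional
        Character spans (e.g. entity mentions) at whose edges token
        boundaries are forced, so "sigX-ypuN" with two annotated names
        splits into two words and a connector hyphen.

    Word indices are 1-based and count words only; each punctuation record
    keeps its character span so features can locate commas relative to words.
    """
    words: list[Token] = []
    punct: list[Token] = []
    for start, end in _split_raw(text, boundaries):
        chunk = text[start:end]
        # lone connector or punctuation chunk
        if chunk in _CONNECTOR_PUNCT or all(c in _EDGE_PUNCT for c in chunk):
            for i, ch in enumerate(chunk):
                punct.append(Token(ch, start + i, start + i + 1))
            continue
        # strip punctuation from the edges
        left, right = 0, len(chunk)
        while left < right and chunk[left] in _EDGE_PUNCT:
            punct.append(Token(chunk[left], start + left, start + left + 1))
            left += 1
        tail: list[Token] = []
        while right > left and chunk[right - 1] in _EDGE_PUNCT:
            tail.append(Token(chunk[right - 1], start + right - 1, start + right))
            right -= 1
        core = chunk[left:right]
        if core and not any(ch.isalnum() for ch in core):
            # residual pure-punctuation core (e.g. "/." -> "/"): never a word
            for i, ch in enumerate(core):
                punct.append(Token(ch, start + left + i, start + left + i + 1))
        elif core:
            words.append(Token(core, start + left, start + right))
        punct.extend(reversed(tail))
    words = [Token(t.surface, t.start, t.end, i + 1) for i, t in enumerate(words)]
    punct.sort(key=lambda t: t.start)
    return Tokenization(words=words, punct=punct)


def detokenize(tk: Tokenization) -> str:
    """Space-join words and punctuation in character order (lossy but
    re-tokenizes to the same word/punct sequences)."""
    pieces = sorted(tk.words + tk.punct, key=lambda t: t.start)
    return " ".join(t.surface for t in pieces)


# ---------------------------------------------------------------------------
# Porter stemmer
# ---------------------------------------------------------------------------

class PorterStemmer:
    """The Porter (1980) suffix-stripping stemmer.

    Implemented in-package; only stem-equivalence classes are relied upon
    (e.g. stem('binds') == stem('bind')), never literal stem strings.
    """

    _VOWELS = "aeiou"

    def _cons(self, word: str, i: int) -> bool:
        ch = word[i]
        if ch in self._VOWELS:
            return False
        if ch == "y":
            return i == 0 or not self._cons(word, i - 1)
        return True

    def _measure(self, stem: str) -> int:
        m, prev_vowel = 0, False
        for i in range(len(stem)):
            if self._cons(stem, i):
                if prev_vowel:
                    m += 1
                prev_vowel = False
            else:
                prev_vowel = True
        return m

    def _has_vowel(self, stem: str) -> bool:
        return any(not self._cons(stem, i) for i in range(len(stem)))

    def _ends_double_cons(self, word: str) -> bool:
        return (len(word) >= 2 and word[-1] == word[-2]
                and self._cons(word, len(word) - 1))

    def _cvc(self, word: str) -> bool:
        if len(word) < 3:
            return False
        if (self._cons(word, len(word) - 3)
                and not self._cons(word, len(word) - 2)
                and self._cons(word, len(word) - 1)):
            return word[-1] not in "wxy"
        return False

    def _replace(self, word, suffix, repl, m_min):
        stem = word[: len(word) - len(suffix)]
        if self._measure(stem) > m_min:
            return stem + repl
        return word

    def stem(self, word: str) -> str:
        w = word.lower()
        if len(w) <= 2 or not w.isalpha():
            return w
        # step 1a
        if w.endswith("sses"):
            w = w[:-2]
        elif w.endswith("ies"):
            w = w[:-2]
        elif not w.endswith("ss") and w.endswith("s"):
            w = w[:-1]
        # step 1b
        if w.endswith("eed"):
            if self._measure(w[:-3]) > 0:
                w = w[:-1]
        else:
            flag = False
            if w.endswith("ed") and self._has_vowel(w[:-2]):
                w, flag = w[:-2], True
            elif w.endswith("ing") and self._has_vowel(w[:-3]):
                w, flag = w[:-3], True
            if flag:
                if w.endswith(("at", "bl", "iz")):
                    w += "e"
                elif self._ends_double_cons(w) and w[-1] not in "lsz":
                    w = w[:-1]
                elif self._measure(w) == 1 and self._cvc(w):
                    w += "e"
        # step 1c
        if w.endswith("y") and self._has_vowel(w[:-1]):
            w = w[:-1] + "i"
        # step 2
        for suffix, repl in (("ational", "ate"), ("tional", "tion"),
                             ("enci", "ence"), ("anci", "ance"),
                             ("izer", "ize"), ("abli", "able"),
                             ("alli", "al"), ("entli", "ent"), ("eli", "e"),
                             ("ousli", "ous"), ("ization", "ize"),
                             ("ation", "ate"), ("ator", "ate"),
                             ("alism", "al"), ("iveness", "ive"),
                             ("fulness", "ful"), ("ousness", "ous"),
                             ("aliti", "al"), ("iviti", "ive"),
                             ("biliti", "ble")):
            if w.endswith(suffix):
                w = self._replace(w, suffix, repl, 0)
                break
        # step 3
        for suffix, repl in (("icate", "ic"), ("ative", ""), ("alize", "al"),
                             ("iciti", "ic"), ("ical", "ic"), ("ful", ""),
                             ("ness", "")):
            if w.endswith(suffix):
                w = self._replace(w, suffix, repl, 0)
                break
        # step 4
        for suffix in ("al", "ance", "ence", "er", "ic", "able", "ible",
                       "ant", "ement", "ment", "ent", "ou", "ism", "ate",
                       "iti", "ous", "ive", "ize"):
            if w.endswith(suffix):
                stem = w[: len(w) - len(suffix)]
                if self._measure(stem) > 1:
                    w = stem
                break
        else:
            if w.endswith("ion") and len(w) > 3 and w[-4] in "st":
                if self._measure(w[:-3]) > 1:
                    w = w[:-3]
        # step 5a
        if w.endswith("e"):
            stem = w[:-1]
            m = self._measure(stem)
            if m > 1 or (m == 1 and not self._cvc(stem)):
                w = stem
        # step 5b
        if self._ends_double_cons(w) and w.endswith("l") and self._measure(w) > 1:
            w = w[:-1]
        return w


_STEMMER = PorterStemmer()


def stem(word: str) -> str:
    """Deterministic, idempotent lower-cased stem of ``word``.

    Porter's algorithm is applied to a fixed point (a single pass is not
    idempotent: dropping a final 'e' can expose an 's' that the plural rule
    would strip on a second pass). Iteration only merges equivalence
    classes, never splits them, so lexicon matching is unaffected.
    """
    w = word.lower()
    for _ in range(5):
        nxt = _STEMMER.stem(w)
        if nxt == w:
            return w
        w = nxt
    return w


# ---------------------------------------------------------------------------
# Lexicons
# ---------------------------------------------------------------------------

#: The seven especially significant interaction words checked between the
#: protein pair when not already chosen as the keyword.
SECOND_KEYWORDS = ("bind", "interact", "stimulate", "associate",
                   "regulate", "induce", "known")

NEGATIVE_WORDS = frozenset({"not", "incapable", "unable"})

CONJUNCTIVE_WORDS = frozenset({
    "although", "though", "because", "as", "therefore", "hence", "since",
    "so", "where", "when", "what", "why", "how", "wherein", "whereas",
    "whereby"})

CONDITION_WORDS = frozenset({"if", "whether"})

PREPOSITIONS = frozenset({
    "of", "in", "to", "by", "with", "on", "for", "at", "from", "into",
    "between", "through", "against", "under", "over", "within", "via",
    "upon", "during", "among", "onto", "toward", "towards", "without"})


@dataclass
class Lexicon:
    """Stemmed word lists driving lexical features and syntax patterns.

    All entries are lower-case stems. ``second_keywords`` is always folded
    into ``keywords``.
    """

    keywords: set[str] = field(default_factory=set)
    iverb: set[str] = field(default_factory=set)
    inoun: set[str] = field(default_factory=set)
    negative_words: frozenset[str] = NEGATIVE_WORDS
    conjunctive_words: frozenset[str] = CONJUNCTIVE_WORDS
    condition_words: frozenset[str] = CONDITION_WORDS
    second_keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.keywords = {stem(w) for w in self.keywords}
        self.iverb = {stem(w) for w in self.iverb}
        self.inoun = {stem(w) for w in self.inoun}
        if not self.second_keywords:
            self.second_keywords = tuple(stem(w) for w in SECOND_KEYWORDS)
        else:
            self.second_keywords = tuple(stem(w) for w in self.second_keywords)
        self.keywords |= set(self.second_keywords)

    @classmethod
    def load(cls, path) -> "Lexicon":
        """Read a plain-text lexicon with [keywords]/[iverb]/[inoun]/
        [negative]/[conjunctive] sections, one entry per line."""
        sections: dict[str, list[str]] = {}
        current = "keywords"
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if line.startswith("[") and line.endswith("]"):
                    current = line[1:-1].lower()
                    continue
                sections.setdefault(current, []).append(line.lower())
        kwargs = dict(
            keywords=set(sections.get("keywords", ())),
            iverb=set(sections.get("iverb", ())),
            inoun=set(sections.get("inoun", ())),
        )
        if "negative" in sections:
            kwargs["negative_words"] = frozenset(sections["negative"])
        if "conjunctive" in sections:
            kwargs["conjunctive_words"] = frozenset(sections["conjunctive"])
        return cls(**kwargs)


def default_lexicon() -> Lexicon:
    """The packaged stand-in lexicon (see module docstring)."""
    ref = resources.files("ppi_groupsel").joinpath("data/default_lexicon.txt")
    with resources.as_file(ref) as path:
        return Lexicon.load(path)


# ---------------------------------------------------------------------------
# Keyword identification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeywordMatch:
    """The designated keyword K of an instance plus all lexicon hits."""

    stem: str
    token_index: int            # 1-based word position of K
    all_matches: tuple[int, ...]


def find_keyword(blinded, lexicon: Lexicon) -> KeywordMatch | None:
    """Locate all keyword-lexicon hits in a blinded instance and pick K.

    When several hits exist the designated K is the hit between P1 and P2
    nearest P1; with no infix hit, the hit nearest either protein (ties to
    the leftmost). Placeholder tokens never match.
    """
    from .corpus_io import PROT0, PROT1, PROT2  # local: avoid import cycle

    placeholders = {PROT0, PROT1, PROT2}
    hits = [i + 1 for i, w in enumerate(blinded.words)
            if w not in placeholders and stem(w) in lexicon.keywords]
    if not hits:
        return None
    p1, p2 = blinded.p1_index, blinded.p2_index
    infix = [i for i in hits if p1 < i < p2]
    if infix:
        k = min(infix, key=lambda i: (i - p1, i))
    else:
        k = min(hits, key=lambda i: (min(abs(i - p1), abs(i - p2)), i))
    return KeywordMatch(stem=stem(blinded.words[k - 1]), token_index=k,
                        all_matches=tuple(hits))


# ---------------------------------------------------------------------------
# Constituency parse trees
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class ParseTree:
    """A rooted ordered constituency tree importable from bracketed
    Penn-Treebank-style strings, e.g. ``(S (NP (NNP Oxytocin)) ...)``.

    Leaves align one-to-one with the (blinded) word sequence of a sentence.
    """

    def __init__(self, label: str, children: list["ParseTree"] | None = None,
                 leaf: str | None = None):
        self.label = label
        self.children = children or []
        self.leaf = leaf            # surface word, set on preterminal nodes

    # -- construction -------------------------------------------------------

    @classmethod
    def from_string(cls, text: str) -> "ParseTree":
        tokens = re.findall(r"\(|\)|[^\s()]+", text)
        pos = 0

        def parse_node() -> "ParseTree":
            nonlocal pos
            if pos >= len(tokens) or tokens[pos] != "(":
                raise ParseError(f"expected '(' at token {pos} in {text!r}")
            pos += 1
            if pos >= len(tokens):
                raise ParseError("truncated tree")
            label = tokens[pos]
            pos += 1
            node = cls(label)
            while pos < len(tokens) and tokens[pos] != ")":
                if tokens[pos] == "(":
                    node.children.append(parse_node())
                else:
                    node.leaf = tokens[pos]
                    pos += 1
            if pos >= len(tokens):
                raise ParseError("unbalanced brackets")
            pos += 1  # consume ')'
            return node

        root = parse_node()
        if pos != len(tokens):
            raise ParseError(f"trailing material in {text!r}")
        return root

    def to_string(self) -> str:
        if self.leaf is not None and not self.children:
            return f"({self.label} {self.leaf})"
        inner = " ".join(c.to_string() for c in self.children)
        return f"({self.label} {inner})"

    # -- queries -------------------------------------------------------------

    def leaves(self) -> list[str]:
        if self.leaf is not None and not self.children:
            return [self.leaf]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def _paths(self):
        """Yield (leaf_surface, [labels root..preterminal]) in leaf order."""
        if self.leaf is not None and not self.children:
            yield (self.leaf, [self.label])
            return
        for child in self.children:
            for leaf, path in child._paths():
                yield (leaf, [self.label] + path)

    def pos_path(self, leaf_index: int) -> list[str]:
        """Node labels on the root-to-leaf path, root excluded, POS included.

        For the degenerate single-level tree (root is itself the
        preterminal) the path is empty.
        """
        paths = list(self._paths())
        if not 0 <= leaf_index < len(paths):
            raise IndexError(leaf_index)
        return paths[leaf_index][1][1:]

    def height(self, leaf_index: int) -> int:
        """Height of a leaf: the length of its POS path (at least 1).

        This convention reproduces the worked constituency-tree example:
        a leaf under root -> NP -> NNP has height 2.
        """
        return max(1, len(self.pos_path(leaf_index)))


# -- stub parser backend -----------------------------------------------------

_STUB_TAGS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "its": "PRP$",
    "and": "CC", "or": "CC", "but": "CC",
    "is": "VBZ", "was": "VBD", "are": "VBP", "were": "VBD",
}


def _stub_tag(word: str, lexicon: Lexicon | None) -> str:
    from .corpus_io import PROT0, PROT1, PROT2

    if word in (PROT0, PROT1, PROT2):
        return "NNP"
    low = word.lower()
    if low in _STUB_TAGS:
        return _STUB_TAGS[low]
    if low in PREPOSITIONS:
        return "IN"
    if re.fullmatch(r"-?\d+(\.\d+)?", low):
        return "CD"
    s = stem(word)
    if lexicon is not None and (s in lexicon.iverb or s in lexicon.keywords):
        return "VBZ" if low.endswith("s") else "VB"
    return "NN"


def stub_parse(words: list[str], lexicon: Lexicon | None = None) -> ParseTree:
    """Deterministic right-branching stand-in parser.

    Each word is wrapped in a dictionary POS tag; the spine is a chain of S
    nodes, so later words sit deeper. Same input, identical tree — used so
    syntactic features never require a parser binary.
    """
    if not words:
        raise ParseError("cannot parse an empty sentence")
    pre = [ParseTree(_stub_tag(w, lexicon), leaf=w) for w in words]
    node = ParseTree("S", [pre[-1]])
    for p in reversed(pre[:-1]):
        node = ParseTree("S", [p, node])
    return node


def parse(words: list[str], backend="stub",
          lexicon: Lexicon | None = None,
          sent_id: str = "?") -> ParseTree:
    """Produce a ParseTree aligned to ``words`` via the given backend.

    ``backend`` is "stub", a bracketed tree string, or a callable
    ``f(words) -> ParseTree``. Leaf/token misalignment raises
    :class:`AlignmentError` carrying the sentence id.
    """
    if backend == "stub":
        tree = stub_parse(words, lexicon)
    elif callable(backend):
        try:
            tree = backend(words)
        except Exception as exc:
            raise ParseError(f"parser backend failed on {sent_id}: {exc}") from exc
    elif isinstance(backend, str):
        tree = ParseTree.from_string(backend)
    else:
        raise TypeError(f"bad parser backend {backend!r}")
    if tree.leaves() != list(words):
        raise AlignmentError(
            f"parse leaves do not align with tokens of sentence {sent_id}: "
            f"{tree.leaves()!r} vs {list(words)!r}")
    return tree
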