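"""Unified-XML PPI corpus I/O, candidate-pair enumeration and entity blinding.

The benchmark PPI corpora (LLL, HPRD50, IEPA, AIMed) circulate in a common
"unified" XML dialect: a ``<corpus>`` holds ``<document>`` elements, each
document holds ``<sentence>`` elements carrying the sentence text, entity
annotations with character offsets, and pairwise interaction annotations.
This module materialises that structure, generates the n-choose-2 candidate
protein pairs of each sentence, and blinds entity surface forms to the
placeholders PROT1 / PROT2 / PROT0 so the learner cannot memorise names.

Character offsets are 0-based and end-exclusive internally; the reader
converts from the dialect's inclusive offsets at the boundary.
"""

from __future__ import annotations

import itertools
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .linguistic import Token, tokenize

logger = logging.getLogger(__name__)

#: Placeholder tokens substituted for entity mentions.
PROT1 = "PROT1"
PROT2 = "PROT2"
PROT0 = "PROT0"

#: Attributes the reader understands on each element of the unified dialect.
_KNOWN_ATTRS = {
    "corpus": {"id", "source"},
    "document": {"id", "origId", "origID"},
    "sentence": {"id", "origId", "origID", "text", "seqId"},
    "entity": {"id", "origId", "origID", "charOffset", "text", "type", "seqId"},
    "interaction": {"id", "origId", "origID", "e1", "e2", "type", "directed",
                    "interaction", "seqId"},
    "pair": {"id", "origId", "origID", "e1", "e2", "type", "directed",
             "interaction", "seqId"},
}


class CorpusFormatError(ValueError):
    """Malformed or invariant-violating unified-XML input."""


@dataclass(frozen=True)
class EntityMention:
    """A contiguous annotated entity (protein/gene/chemical) in a sentence."""

    ent_id: str
    start: int          # 0-based, inclusive
    end: int            # 0-based, exclusive
    text: str
    ent_type: str = "protein"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class AnnotatedSentence:
    """A sentence with tokens, entity mentions and gold interaction pairs.

    ``parse`` optionally carries a bracketed constituency tree string whose
    leaves align one-to-one with the *blinded* word sequence of the sentence
    (entities collapsed to single placeholder tokens).
    """

    sent_id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    gold_pairs: set[frozenset[str]] = field(default_factory=set)
    parse: str | None = None
    tokens: list[Token] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tokens:
            self.tokens = tokenize(
                self.text, boundaries=[e.span for e in self.entities]
            ).words
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for ent in self.entities:
            if ent.ent_id in seen:
                raise CorpusFormatError(
                    f"duplicate entity id {ent.ent_id!r} in sentence {self.sent_id!r}")
            seen.add(ent.ent_id)
            if not (0 <= ent.start < ent.end <= len(self.text)):
                raise CorpusFormatError(
                    f"entity {ent.ent_id!r} span {ent.span} outside sentence "
                    f"{self.sent_id!r} text of length {len(self.text)}")
            if self.text[ent.start:ent.end] != ent.text and ent.text:
                raise CorpusFormatError(
                    f"entity {ent.ent_id!r} text {ent.text!r} does not match "
                    f"span {self.span_text(ent)!r} in sentence {self.sent_id!r}")
        for pair in self.gold_pairs:
            for eid in pair:
                if eid not in seen:
                    raise CorpusFormatError(
                        f"interaction references unknown entity {eid!r} "
                        f"in sentence {self.sent_id!r}")

    def span_text(self, ent: EntityMention) -> str:
        return self.text[ent.start:ent.end]

    def entity_by_id(self, ent_id: str) -> EntityMention:
        for ent in self.entities:
            if ent.ent_id == ent_id:
                return ent
        raise KeyError(ent_id)


@dataclass
class Document:
    doc_id: str
    sentences: list[AnnotatedSentence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sent_id for s in self.sentences]
        if len(ids) != len(set(ids)):
            raise CorpusFormatError(f"duplicate sentence id in document {self.doc_id!r}")


@dataclass
class Corpus:
    corpus_id: str
    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise CorpusFormatError(f"duplicate document id in corpus {self.corpus_id!r}")

    def sentences(self):
        for doc in self.documents:
            yield from doc.sentences


@dataclass
class CandidateInstance:
    """An ordered candidate pair (p1 before p2) with the remaining entities P0.

    ``label`` is True (interacting), False (not interacting) or None when no
    gold annotation is available.
    """

    sentence: AnnotatedSentence
    p1: EntityMention
    p2: EntityMention
    others: list[EntityMention]
    label: bool | None
    doc_id: str = ""

    @property
    def pair_id(self) -> tuple[str, str]:
        return (self.p1.ent_id, self.p2.ent_id)


# ---------------------------------------------------------------------------
# Reading and writing the unified XML dialect
# ---------------------------------------------------------------------------

def _warn_unknown_attrs(elem: ET.Element) -> None:
    known = _KNOWN_ATTRS.get(elem.tag, set())
    for attr in elem.attrib:
        if attr not in known:
            warnings.warn(
                f"ignoring unknown attribute {attr!r} on <{elem.tag}>",
                stacklevel=3,
            )


def _parse_char_offset(raw: str, where: str) -> tuple[int, int]:
    # Dialect offsets are "start-end" inclusive; possibly comma-separated for
    # non-contiguous names, which this implementation rejects (BioInfer-style
    # discontinuous entities are out of scope).
    if "," in raw:
        raise CorpusFormatError(
            f"non-contiguous entity charOffset {raw!r} at {where}: unsupported")
    try:
        start_s, end_s = raw.split("-", 1) if not raw.startswith("-") else ("", "")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise CorpusFormatError(f"bad charOffset {raw!r} at {where}") from exc
    return start, end + 1  # to end-exclusive


def read_corpus(path, dialect: str = "unified") -> Corpus:
    """Read a unified-XML PPI corpus file into a :class:`Corpus`.

    Parameters
    ----------
    path : str or file-like
        XML file in the unified dialect.
    dialect : str
        Only ``"unified"`` is recognised.

    Raises
    ------
    CorpusFormatError
        On malformed XML, bad offsets, spans outside the sentence text,
        duplicate ids, or overlapping entity mentions.
    """
    if dialect != "unified":
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise CorpusFormatError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "corpus":
        raise CorpusFormatError(f"expected <corpus> root, found <{root.tag}>")
    _warn_unknown_attrs(root)

    documents = []
    for doc_el in root.findall("document"):
        _warn_unknown_attrs(doc_el)
        sentences = []
        for sent_el in doc_el.findall("sentence"):
            _warn_unknown_attrs(sent_el)
            sid = sent_el.get("id", "")
            text = sent_el.get("text", "")
            entities = []
            for ent_el in sent_el.findall("entity"):
                _warn_unknown_attrs(ent_el)
                start, end = _parse_char_offset(
                    ent_el.get("charOffset", ""), f"entity in {sid}")
                entities.append(EntityMention(
                    ent_id=ent_el.get("id", ""),
                    start=start, end=end,
                    text=ent_el.get("text", text[start:end]),
                    ent_type=ent_el.get("type", "protein"),
                ))
            gold = set()
            for int_el in itertools.chain(sent_el.findall("interaction"),
                                          sent_el.findall("pair")):
                _warn_unknown_attrs(int_el)
                flag = int_el.get("interaction", "true").lower()
                if flag in ("true", "1", "yes"):
                    gold.add(frozenset((int_el.get("e1"), int_el.get("e2"))))
            parse_el = sent_el.find("parse")
            parse = parse_el.text.strip() if parse_el is not None and parse_el.text else None
            _check_no_overlap(entities, sid)
            sentences.append(AnnotatedSentence(
                sent_id=sid, text=text, entities=entities,
                gold_pairs=gold, parse=parse))
        documents.append(Document(doc_id=doc_el.get("id", ""), sentences=sentences))
    return Corpus(corpus_id=root.get("id", ""), documents=documents)


def _check_no_overlap(entities: list[EntityMention], sid: str) -> None:
    spans = sorted((e.start, e.end, e.ent_id) for e in entities)
    for (s1, e1, id1), (s2, e2, id2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise CorpusFormatError(
                f"overlapping entity mentions {id1!r}/{id2!r} in sentence "
                f"{sid!r}: blinding of nested mentions is undefined")


def write_corpus(corpus: Corpus, path) -> None:
    """Write a :class:`Corpus` back to unified XML (offsets made inclusive)."""
    root = ET.Element("corpus", id=corpus.corpus_id)
    for doc in corpus.documents:
        doc_el = ET.SubElement(root, "document", id=doc.doc_id)
        for sent in doc.sentences:
            sent_el = ET.SubElement(doc_el, "sentence", id=sent.sent_id,
                                    text=sent.text)
            for ent in sent.entities:
                ET.SubElement(sent_el, "entity", id=ent.ent_id,
                              charOffset=f"{ent.start}-{ent.end - 1}",
                              text=ent.text, type=ent.ent_type)
            for n, pair in enumerate(sorted(sent.gold_pairs, key=sorted)):
                e1, e2 = sorted(pair)
                ET.SubElement(sent_el, "interaction",
                              id=f"{sent.sent_id}.i{n}", e1=e1, e2=e2)
            if sent.parse:
                ET.SubElement(sent_el, "parse").text = sent.parse
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# Candidate instances and blinding
# ---------------------------------------------------------------------------

def enumerate_instances(sentence: AnnotatedSentence,
                        doc_id: str = "",
                        labeled: bool = True) -> list[CandidateInstance]:
    """Generate the n-choose-2 candidate pairs of a sentence.

    Each unordered entity pair yields exactly one instance with p1 the mention
    appearing first (by character offset; ties by entity id). Self-interactions
    (the same protein annotated twice) are kept, matching the evaluation
    convention used on AIMed.
    """
    ordered = sorted(sentence.entities, key=lambda e: (e.start, e.ent_id))
    out = []
    for p1, p2 in itertools.combinations(ordered, 2):
        others = [e for e in ordered if e is not p1 and e is not p2]
        label = None
        if labeled:
            label = frozenset((p1.ent_id, p2.ent_id)) in sentence.gold_pairs
        out.append(CandidateInstance(sentence=sentence, p1=p1, p2=p2,
                                     others=others, label=label,
                                     doc_id=doc_id))
    return out


@dataclass
class BlindedInstance:
    """Token view of an instance after entity blinding.

    Every entity mention collapses to ONE placeholder word, so word indices
    (1-based) are recomputed; word-distance features count protein names as
    single words. Punctuation records keep the count of words preceding each
    punctuation mark so comma features survive blinding.
    """

    words: list[str]
    p1_index: int                       # 1-based word index of PROT1
    p2_index: int                       # 1-based word index of PROT2
    comma_after: list[int]              # word counts preceding each comma
    connectors_between: list[str]       # lone '-'/'/'/'(' between p1 and p2
    label: bool | None
    instance: CandidateInstance


def blind_instance(instance: CandidateInstance) -> BlindedInstance:
    """Replace p1/p2/other entity tokens with PROT1/PROT2/PROT0 placeholders."""
    sent = instance.sentence
    spans = {instance.p1.span: PROT1, instance.p2.span: PROT2}
    for other in instance.others:
        spans[other.span] = PROT0

    tk = tokenize(sent.text, boundaries=[e.span for e in sent.entities])
    words: list[str] = []
    comma_after: list[int] = []
    covered: set[tuple[int, int]] = set()
    positions: dict[str, int] = {}
    # replay words and punctuation in character order
    events = [("w", t) for t in tk.words] + [("p", p) for p in tk.punct]
    events.sort(key=lambda ev: ev[1].start)
    for kind, tok in events:
        owner = None
        for (s, e), placeholder in spans.items():
            if s <= tok.start and tok.end <= e:
                owner = ((s, e), placeholder)
                break
        if kind == "p":
            if tok.surface == "," and owner is None:
                comma_after.append(len(words))
            continue
        if owner is None:
            words.append(tok.surface)
        elif owner[0] not in covered:
            covered.add(owner[0])
            words.append(owner[1])
            if owner[1] in (PROT1, PROT2):
                positions[owner[1]] = len(words)
        # subsequent tokens of a multi-token entity are dropped

    if PROT1 not in positions or PROT2 not in positions:
        raise CorpusFormatError(
            f"entity tokens not found in sentence {sent.sent_id!r}")

    p1_idx, p2_idx = positions[PROT1], positions[PROT2]
    connectors = [p.surface for p in tk.punct
                  if p.surface in ("-", "/", "(")
                  and instance.p1.end <= p.start and p.end <= instance.p2.start]
    return BlindedInstance(words=words, p1_index=p1_idx, p2_index=p2_idx,
                           comma_after=comma_after,
                           connectors_between=connectors,
                           label=instance.label, instance=instance)


def write_predictions(rows, path) -> None:
    """Write prediction rows as TSV: corpus, doc, sentence, pair ids, label."""
    header = "corpus\tdoc_id\tsent_id\tp1_id\tp2_id\tpredicted_label\n"
    with open(path, "w") as fh:
        fh.write(header)
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
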