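"""Synthetic unified-XML PPI corpora with controllable statistical structure.

The generator emulates the properties the pipeline feeds on — sentences
with two blinded protein mentions, a controllable positive-pair fraction,
keywords with controllable class imbalance ID(K), infix/prefix/postfix
keyword placement, sentences built to match specific syntax patterns, and
embedded bracketed parse trees so the syntactic features (G3 heights, G4
POS paths) never depend on a parser binary.

Informative groups. ``informative_groups`` names the feature groups whose
values are generated with class-separated distributions (e.g. interacting
pairs get short keyword/protein distances, non-interacting long). Because
the contribution-level machinery evaluates a group while holding every
other group's features fixed, a group in which *all* members are perfectly
informative can never strictly beat the shared full-feature baseline —
in-group selection only pays off when the group mixes signal with a
distractor. An "informative" group here therefore carries strong class
separation on its members except one designated distractor member drawn
label-independently with high variance (G1: Distance_KP2, G3: Height_P2,
G4: POS_P2; G2's two members are positionally coupled and share the
signal), while uninformative groups take label-independent, near-constant
values (tree anchors of constant shape), keeping them nearly harmless to
the k-NN distance: were uninformative groups noisy, the CL machinery would
reward *their* removal rather than the informative group's selection
payoff. See the methods note for the full rationale.

The generator does not attempt to mimic real biomedical token
distributions beyond these controlled properties.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus_io import AnnotatedSentence, Corpus, Document, EntityMention

#: Filler vocabulary; chosen so no filler stem collides with the default
#: interaction lexicon or any syntax-pattern literal.
FILLERS = ("the", "a", "this", "these", "small", "large", "new", "early",
           "late", "several", "various", "distinct", "common", "rare",
           "simple", "cell", "sample", "tissue", "culture", "assay",
           "buffer", "study", "result", "figure", "panel", "lane", "step",
           "phase", "stage")

_LABEL_POOL = ("NP", "VP", "PP", "ADJP", "ADVP", "SBAR", "WHNP", "QP")
_POS_POOL = ("NN", "NNP", "NNS")


@dataclass
class SimConfig:
    """Stated world of one synthetic corpus.

    keyword_profiles maps a keyword (base word, stemmed at use) to its
    target imbalance degree ID(K) = N_P/N_N among instances containing it;
    a sentence carrying that keyword is drawn positive with probability
    ID/(1+ID). structure_mix gives the infix/prefix/postfix sentence
    proportions. pattern_quota forces that many sentences to be built from
    the template of the given syntax-pattern id. noise is the label-flip
    probability applied after the class draw.
    """

    n_documents: int = 40
    sentences_per_document: int = 3
    p_positive: float = 0.4
    keyword_profiles: tuple[tuple[str, float], ...] = (
        ("bind", 9.0), ("interact", 1.0), ("regulate", 0.11))
    structure_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)
    pattern_quota: dict[int, int] = field(default_factory=dict)
    informative_groups: frozenset[str] = frozenset()
    noise: float = 0.05
    p_no_keyword: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.informative_groups = frozenset(self.informative_groups)
        if not 0 <= self.p_positive <= 1 or not 0 <= self.noise <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.structure_mix) - 1.0) > 1e-9:
            raise ValueError("structure_mix must sum to 1")
        if sum(self.pattern_quota.values()) > \
                self.n_documents * self.sentences_per_document:
            raise ValueError("pattern_quota exceeds the number of sentences")


# ---------------------------------------------------------------------------
# Sentence assembly
# ---------------------------------------------------------------------------

def _fillers(rng: random.Random, n: int) -> list[str]:
    return [rng.choice(FILLERS) for _ in range(n)]


def _rand_chain(rng: random.Random, height: int) -> list[str]:
    return [rng.choice(_LABEL_POOL) for _ in range(height - 1)] + \
        [rng.choice(_POS_POOL)]


def _chain_labels(rng: random.Random, g3: str, g4: str,
                  label: bool) -> list[str]:
    """Labels (phrase chain + POS tag) above one anchor leaf.

    The list length is the leaf's height, the joined list its POS path.
    ``g3``/``g4`` are "signal", "distractor" or "off". Random label chains
    keep a G3 signal from leaking into G4 (high-cardinality categories);
    constant-height canonical chains keep a G4 signal out of G3.
    """
    if g4 == "signal" and g3 == "signal":
        return ["NP", "NNP"] if label else ["VP", "PP", "SBAR", "NNP"]
    if g4 == "signal":
        return ["NP", "NP", "NNP"] if label else ["VP", "PP", "NNP"]
    if g4 == "distractor":
        return _rand_chain(rng, 3)
    if g3 == "signal":
        return _rand_chain(rng, rng.randint(2, 3) if label
                           else rng.randint(5, 7))
    if g3 == "distractor":
        return _rand_chain(rng, rng.randint(2, 7))
    # uninformative: constant shape, so the group is label-independent AND
    # nearly harmless to the distance (see module docstring)
    return ["NP", "NN"]


def _build_parse(words: list[str], anchors: dict[int, list[str]]) -> str:
    """Bracketed tree over ``words``: anchor indices get their label
    chains, every other word a flat NN preterminal."""
    parts = []
    for i, w in enumerate(words):
        chain = anchors.get(i, ["NN"])
        node = f"({chain[-1]} {w})"
        for lab in reversed(chain[:-1]):
            node = f"({lab} {node})"
        parts.append(node)
    return "(S " + " ".join(parts) + ")"


_PATTERN_TEMPLATES: dict[int, list[str]] = {
    # {1}/{2} mark the entity slots; other tokens are literals.
    1: ["{1}", "interact", "{2}"],
    2: ["{1}", "interact", "by", "{2}"],
    3: ["activate", "of", "{1}", "by", "{2}"],
    4: ["activate", "of", "{1}", "to", "{2}"],
    5: ["interaction", "of", "{1}", "through", "{2}"],
    6: ["interaction", "of", "{1}", "with", "{2}"],
    7: ["interaction", "between", "{1}", "and", "{2}"],
    8: ["complex", "between", "{1}", "and", "{2}"],
    9: ["complex", "of", "{1}", "and", "{2}"],
    10: ["{1}", "form", "a", "complex", "with", "bind", "{2}"],
    11: ["{1}", "the", "{2}", "interaction"],
    12: ["{1}", "depend", "of", "{2}"],
    13: ["the", "data", "between", "{1}", "and", "{2}"],
}


def _compose(rng, config: SimConfig, name1: str, name2: str,
             keyword: str | None, label: bool) -> list[str]:
    """One templated sentence honoring the structure mix and G1/G2 signals."""
    g1 = "G1" in config.informative_groups
    g2 = "G2" in config.informative_groups
    if g1:
        # overlapping class-separated signal: real corpora are far from
        # perfectly separable, and saturated validation folds would make
        # in-group selection a no-op
        g_sig = rng.randint(0, 2) if label else rng.randint(3, 8)
        g_noise = rng.randint(0, 9)      # distractor gap, label-independent
    else:
        g_sig = rng.randint(1, 4)
        g_noise = rng.randint(1, 4)
    pre = _fillers(rng, rng.randint(5, 8)) if g2 and not label else []

    if keyword is None:
        return pre + [name1] + _fillers(rng, g_sig) + [name2]
    u = rng.random()
    infix_p, prefix_p, _ = config.structure_mix
    if u < infix_p:          # P1 [g_sig] K [g_noise] P2
        return pre + [name1] + _fillers(rng, g_sig) + [keyword] + \
            _fillers(rng, g_noise) + [name2]
    if u < infix_p + prefix_p:   # K [g_sig] P1 [g_noise] P2
        return pre + [keyword] + _fillers(rng, g_sig) + [name1] + \
            _fillers(rng, g_noise) + [name2]
    # P1 [g_noise] P2 [g_sig] K
    return pre + [name1] + _fillers(rng, g_noise) + [name2] + \
        _fillers(rng, g_sig) + [keyword]


def generate_corpus(config: SimConfig) -> Corpus:
    """Generate a labeled corpus per ``config``, byte-deterministic in the
    seed, with an embedded bracketed parse on every sentence."""
    rng = random.Random(config.seed)
    quota = [pid for pid, count in sorted(config.pattern_quota.items())
             for _ in range(count)]
    quota_i = 0
    ent_counter = 0
    documents = []
    for d in range(config.n_documents):
        doc_id = f"SYN.d{d}"
        sentences = []
        for s in range(config.sentences_per_document):
            sent_id = f"{doc_id}.s{s}"
            ent_counter += 1
            name1, name2 = f"ProtA{ent_counter}", f"ProtB{ent_counter}"

            keyword = None
            if config.keyword_profiles and \
                    rng.random() >= config.p_no_keyword:
                keyword, target_id = rng.choice(config.keyword_profiles)
                p_pos = target_id / (1.0 + target_id)
            else:
                p_pos = config.p_positive
            label = rng.random() < p_pos
            if rng.random() < config.noise:
                label = not label

            if quota_i < len(quota):
                template = _PATTERN_TEMPLATES[quota[quota_i]]
                quota_i += 1
                words = [name1 if w == "{1}" else name2 if w == "{2}" else w
                         for w in template]
            else:
                words = _compose(rng, config, name1, name2, keyword, label)
            words = words + _fillers(rng, rng.randint(1, 3))

            anchors = {}
            for i, w in enumerate(words):
                if w == name1 or (keyword is not None and w == keyword):
                    role = "signal"
                elif w == name2:
                    role = "distractor"
                else:
                    continue
                g3 = g4 = "off"
                if "G3" in config.informative_groups:
                    g3 = role
                if "G4" in config.informative_groups:
                    g4 = role
                anchors[i] = _chain_labels(rng, g3, g4, label)
            parse = _build_parse(words, anchors)

            rendered = list(words)
            if len(words) > 3 and rng.random() < 0.2:
                j = rng.randrange(1, len(words) - 1)
                rendered[j] = rendered[j] + ","
            text = " ".join(rendered) + " ."

            entities = []
            for name, tag in ((name1, "e1"), (name2, "e2")):
                start = text.index(name)
                entities.append(EntityMention(
                    ent_id=f"{sent_id}.{tag}", start=start,
                    end=start + len(name), text=name))
            gold = set()
            if label:
                gold.add(frozenset((f"{sent_id}.e1", f"{sent_id}.e2")))
            sentences.append(AnnotatedSentence(
                sent_id=sent_id, text=text, entities=entities,
                gold_pairs=gold, parse=parse))
        documents.append(Document(doc_id=doc_id, sentences=sentences))
    return Corpus(corpus_id="SYN", documents=documents)


# ---------------------------------------------------------------------------
# Worked-example fixtures
# ---------------------------------------------------------------------------

#: Hand-encoded constituency tree of the oxytocin example sentence.
_IEPA_TREE = ("(S (NP (NNP Oxytocin)) (VP (VBZ stimulates) "
              "(NP (NP (CD IP3) (NN production)) "
              "(PP (IN in) (NP (JJ dose-dependent) (NN fashion)))) "
              "(ADVP (RB as) (RB well))))")


def worked_example_fixtures() -> Corpus:
    """The printed example sentences, packaged as a valid corpus.

    Entity spans are located programmatically in the sentence text; the
    oxytocin sentence carries its hand-encoded constituency tree so the
    syntactic features can be checked against the published values.
    """
    def sent(sent_id, text, entity_names, gold_index_pairs, parse=None):
        entities = []
        cursor: dict[str, int] = {}
        for n, name in enumerate(entity_names):
            start = text.index(name, cursor.get(name, 0))
            cursor[name] = start + len(name)
            entities.append(EntityMention(
                ent_id=f"{sent_id}.e{n}", start=start,
                end=start + len(name), text=name))
        gold = {frozenset((f"{sent_id}.e{i}", f"{sent_id}.e{j}"))
                for i, j in gold_index_pairs}
        return AnnotatedSentence(sent_id=sent_id, text=text,
                                 entities=entities, gold_pairs=gold,
                                 parse=parse)

    docs = [
        Document("IEPA.d0", [sent(
            "IEPA.d0.s0",
            "Oxytocin stimulates IP3 production in dose-dependent fashion "
            "as well",
            ["Oxytocin", "IP3"], [(0, 1)], parse=_IEPA_TREE)]),
        Document("LLL.d33", [sent(
            "LLL.d33.s1",
            "GerE binds to a site on one of these promoters, cotX, that "
            "overlaps its -35 region",
            ["GerE", "cotX"], [(0, 1)])]),
        Document("LLL.d30", [sent(
            "LLL.d30.s0",
            "In vitro, both sigma(A) and sigma(X) holoenzymes recognize "
            "promoter elements within the sigX-ypuN control region",
            ["sigma(A)", "sigma(X)", "sigX", "ypuN"],
            [(0, 2), (0, 3), (1, 2), (1, 3)])]),
        Document("LLL.d13", [sent(
            "LLL.d13.s0",
            "Production of sigmaK about 1h earlier than normal does affect "
            "Spo0A, which when phosphorylated is an activator of sigE "
            "transcription",
            ["sigmaK", "Spo0A", "sigE"], [(0, 1), (1, 2)])]),
        Document("HPRD50.d21", [sent(
            "HPRD50.d21.s1",
            "In contrast to OX1R, the potency of direct activation of CB1 "
            "was not affected by co-expression with OX1R",
            ["OX1R", "CB1", "OX1R"], [])]),
        Document("AIMed.d55", [
            sent("AIMed.d55.s485",
                 "LEC also induced calcium mobilization, but marginal "
                 "chemotaxis via CCR5",
                 ["LEC", "CCR5"], []),
            sent("AIMed.d55.s487",
                 "The binding of LEC to CCR8 was much less significant",
                 ["LEC", "CCR8"], [(0, 1)])]),
    ]
    return Corpus(corpus_id="worked-examples", documents=docs)
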