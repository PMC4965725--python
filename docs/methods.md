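# Methods

This note records the modeling conventions, numerical choices and design
decisions behind ppi-groupsel, and what the synthetic-corpus tests do and
do not establish.

## Instances, blinding, tokenization

A sentence with n annotated entity mentions yields exactly n·(n−1)/2
candidate instances. Self-interactions (the same protein annotated twice)
are kept. P1 is the mention appearing first by character offset (ties by
entity id). Blinding replaces each mention by a single placeholder token
(PROT1/PROT2/PROT0), so a multi-token name collapses to one word and all
word-distance features count protein names as single words.

The tokenizer counts words only: standalone punctuation (`, . ; : ! ? ( )
[ ] { } "` and lone `-` `/`) is recorded separately with its position and
excluded from word numbering, while hyphenated forms ("dose-dependent",
"-35") remain single words. Token boundaries are forced at entity-span
edges so constructions like "sigX-ypuN" with two annotated names split
correctly. Character offsets are 0-based end-exclusive internally; the
unified-XML dialect's inclusive offsets are converted at the reader
boundary. Overlapping or nested entity mentions are rejected by the
reader: their blinding is undefined and guessing silently would corrupt
distances.

Word distance between two word positions a, b is `max(|a−b|−1, 0)` — the
count of words strictly between them. Note the protein–protein distance
therefore includes an infix keyword (adjacent P1-K-P2 gives distances
0, 0, 1), consistent with the published worked example where
Distance_P1P2 = 9 spans the keyword plus eight other words.

## Stemming and lexicons

`stem()` is the Porter (1980) suffix-stripping algorithm iterated to a
fixed point. A single Porter pass is not idempotent (removing a final
"e" can expose an "s" the plural rule would strip next); iterating makes
the map idempotent and can only merge equivalence classes, never split
them. All lexicon matching is on stems, and only stem-equivalence is
relied upon anywhere (never literal stem strings).

The interaction keyword list is configurable because the original
642-word list was never published. The packaged default (~90 stems) seeds
the published examples plus common interaction verbs/nouns; `known` and
the other six "second keywords" are always folded in. Function-word cues
(negation, conjunctions, `which`, `but`, `if`/`whether`, prepositions)
are matched on lower-cased surfaces, not stems. `which`, `but` and the
conjunctive words are checked over the whole sentence; negation and
condition words only between K and a protein or between the proteins, per
their definitions.

Keyword designation when several lexicon words occur: prefer a hit
strictly between P1 and P2 (nearest P1); otherwise the hit nearest either
protein, ties to the leftmost. This maximizes infix assignment, matching
the emphasis of the subset division. The preposition-of-keyword feature
scans the three words after K and takes the first preposition found.

## Parse trees and syntactic features

Trees are constituency trees in bracketed Penn style whose leaves align
one-to-one with the blinded word sequence. The height of a leaf is the
length of its POS path — the node labels from the root (exclusive) down
to and including the preterminal — with a floor of 1 for the degenerate
root→leaf tree. This convention reproduces the published example values
(heights 2/4/2 and paths "NP, NNP" / "VP, NP, NP, CD" / "VP, VBZ" for the
oxytocin sentence). POS paths are compared as whole strings (0/1) in the
classifier, since no finer categorical rule is defined.

A deterministic right-branching stub parser with a dictionary tagger
ships for tests and as the fallback when a sentence carries no embedded
parse; real parser backends plug in as callables returning aligned trees.
Misalignment raises rather than silently shifting features.

## Syntax patterns

The 13 interaction patterns are element sequences over literals (compared
on stems), alternations (`by|through`, `with|to|on`), the iVerb/iNoun
lexicons, the instance's own P1/P2 placeholders, and wildcards consuming
0–5 words. Matching is a small reachability scan (sets of token
positions per element); the test suite checks it against an independent
brute-force oracle that enumerates every wildcard expansion. Patterns are
matched on the blinded token sequence (the patterns are written in terms
of P1/P2). Placeholders never match literals or lexicon elements, but
wildcards may consume them.

## Significant keywords and subsets

ID(K) counts *instances* (not sentences) whose designated keyword is K.
N_N = 0 gives ID = ∞ (significant); a keyword with no occurrences has
undefined ID and is not significant. SK statistics are recomputed inside
every outer CV fold from that fold's training portion only; a test-time
keyword unseen in training routes to subset C. The three subsets
partition the data: A (SK, infix), B (SK, prefix/postfix), C (otherwise,
including keyword-less instances).

## k-NN

Numeric features are min–max scaled on the training matrix; test values
clip to [0, 1]; constant features map to 0. Features undefined without a
keyword carry the sentinel −1 and scale to 1.0 (the top of the training
range), keeping keyword-less instances maximally distant from keyword-
bearing ones on those dimensions; categorical sentinels are the category
`NONE`. Distance is Euclidean with 0/1 categorical contributions. k is
odd, so binary majority votes never tie; distance ties at the k-th
neighbor resolve by stable training order, making reruns bit-exact. The
square-root rule takes the odd integer nearest √n (ties toward the
larger, clamped to the training size); the alternative `cv_rmse` mode
scans the odd grid {5, 7, …, 31} by inner-CV root-mean-square 0/1 error,
ties toward the smaller k — the grid and loss are conventions chosen
here, as none are published.

## Contribution levels and selection

Per inner fold and group, the in-group search evaluates all 2^|G| subsets
with every other feature fixed; F-score ties prefer the larger, then
lexicographically earlier subset (removal should require evidence). A
fold with an empty validation side is skipped; a subset with fewer
documents than S or fewer than 2S instances falls back to the full
feature mask with a warning. F on a validation fold with no predicted
positives is 0.

The CL of a group counts fold wins, with ties awarding every attaining
group. Blocks of 3 or 2 groups with equal CLs are re-scored restricted to
the block; persisting ties fall to the fold maximum A_j, then the second
maximum A'_j, then group index with a logged warning (the last case, and
4-way ties, are undefined in the source procedure and are reconstructed
here).

U3G removes features cumulatively in CL-major order (within a group, the
published table order) and stops at the first strict improvement of the
fold baseline; the published description ("gradually removing … conclude
immediately") admits either a cumulative or a one-at-a-time reading, and
the cumulative one is implemented. Selection never touches features
outside G1–G4. Each strategy finally adopts the mask of the fold with the
best score (ties to the lower fold index).

## Evaluation

Outer evaluation is 10-fold document-level CV: documents are shuffled by
the run seed and dealt round-robin, so no article contributes to both
sides of a fold. Scoring is One Answer per Occurrence — every candidate
occurrence counts independently. Reported P/R/F pool confusion counts
across folds (micro-averaging); per-fold counts and the macro mean are
also emitted because the published tables do not state which convention
they use. A test subset with no trained counterpart (empty in training)
falls back to the training majority label.

## Synthetic corpora: what they establish

The generator emits unified XML with embedded bracketed parses, two
single-token entities per sentence, keyword profiles targeting chosen
ID(K) ratios (a keyword with target ratio r labels its sentence positive
with probability r/(1+r)), a controllable infix/prefix/postfix mix,
per-pattern sentence quotas, and a label-flip noise rate. Defaults: 40
documents × 3 sentences, p_positive 0.4 for keyword-less sentences,
profiles bind:9.0 / interact:1.0 / regulate:0.11, mix (0.6, 0.2, 0.2),
noise 0.05.

"Informative" groups need care. The CL search evaluates a group holding
all other features fixed, so a group whose members are all perfectly
predictive can never strictly beat the shared full-feature baseline: the
fold maximum over its subsets is attained at the full subset. The payoff
the CL detects is *in-group selection* — which exists only when a group
mixes signal with a distractor. An informative group therefore gets
class-separated members plus one designated high-variance,
label-independent distractor member (G1: Distance_KP2; G3: Height_P2;
G4: POS_P2; G2's two members are positionally coupled and share the
signal). Conversely, uninformative groups are generated label-independent
and nearly constant: were they noisy, the CL machinery would reward
*their* removal and rank the noisiest group first — the mirror image of
recovery. The class-separated gaps overlap (positives 0–2 filler words,
negatives 3–8, distractor 0–9) because real corpora sit far from
saturation (published F-scores 42–77%); perfectly separable gaps drive
every inner validation fold to F = 1, where selection is a no-op.

Coupling is controlled where the features force it: a G3 height signal
uses random node labels so no usable POS category leaks into G4, and a
G4 signal uses constant-height canonical label chains so nothing leaks
into G3. Position features cannot be decoupled from distances
(Position_P2 sits downstream of both gaps), which is why the
G1-versus-G2 sanity check explicitly permutes G2's values across
instances.

A green synthetic suite establishes that the machinery recovers a planted
informative group, that the selection strategies dominate their fold
baselines by construction, and that on the packaged demonstration corpus
(60 documents × 5 sentences, noise 0.08, seed 7) all three strategies
improve pooled F over the plain k-NN baseline. It does not establish
real-corpus F-scores: synthetic sentences have none of the lexical
diversity, parse ambiguity or annotation idiosyncrasy of the benchmark
corpora, and strategy improvements are seed-dependent (on some seeds the
single-best-fold mask adoption generalizes worse than the baseline —
visible in this package's own experiments and inherent to adopting one
fold's mask).

## Known limitations

* Non-contiguous entity names (BioInfer-style) are rejected, not
  modeled.
* The default lexicon is a stand-in; benchmark F-scores depend on the
  unpublished original and on the parser, and are out of scope.
* No dependency parsing or deep-parser predicate-argument structures —
  deliberately absent from the method.
* `which`/`but`/conjunctive cues are scoped to the whole sentence; the
  source definitions imply but do not state this.
* EvalCon2 and residual tie handling are reconstructions of elided
  pseudo-code, flagged in-line.
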