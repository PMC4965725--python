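# ppi-groupsel

Feature-based extraction of protein–protein interactions (PPIs) from
sentences, with automatic feature selection driven by the *contribution
levels* of groups of related features around a k-nearest-neighbor
classifier.

## The problem

Biomedical articles describe far more protein interactions than curated
databases hold. Given a sentence with annotated protein mentions, every
pair of mentions is a candidate *instance*: the task is binary
classification — does the sentence assert an interaction between the pair?
This package implements a complete feature-based pipeline for the
benchmark PPI corpora distributed in the unified XML format (LLL, HPRD50,
IEPA, AIMed style): documents → sentences → entities with character
offsets → pairwise interaction annotations.

## The method

For a candidate pair (P1, P2 in order of appearance) with designated
interaction keyword K, the pipeline computes four feature families:

* **lexical** — keyword identity, negation/conjunction/condition cues,
  the preposition following K, seven "second keyword" indicator bits;
* **word context** — word distances `Distance_KP1`, `Distance_KP2`,
  `Distance_P1P2` (standalone punctuation never counts as a word),
  1-based positions `Position_P1`/`Position_P2`, infix/prefix/postfix
  keyword order, comma placement, multiple-keyword and
  parallel-expression flags;
* **syntactic** — leaf heights and root-to-leaf POS paths of P1, P2, K
  in a constituency parse;
* **patterns** — boolean matches against 13 interaction syntax patterns
  with bounded wildcards (a `*` stands for at most five words).

Training instances are partitioned by *significant keywords* (SK): with
`N_P`/`N_N` the positive/negative training instances containing keyword
K, the imbalance degree is `ID(K) = N_P / N_N`, and K is an SK when
`min(ID, 1/ID) < T` (default `T = 0.18`). Subset A holds SK-infix
instances, B SK-prefix/postfix, C the rest; incompatible syntax patterns
are pruned per subset (A drops 7, 8, 9, 13; B drops 1, 2, 10, 12) and one
classifier is trained per subset.

Related features form four groups — G1 distances, G2 positions, G3
heights, G4 POS paths. Inside 9-fold document-level cross-validation, the
best in-group feature combination of each group is found per fold
(`2^|G|` exhaustive search, other groups fixed) and the *contribution
level* (CL) of a group counts the folds it wins; ties cascade through
restricted re-scoring, fold maxima `A_j` and second maxima `A'_j`. Three
strategies consume the ranking: **BEST1G** (adopt the top group's best
combination), **U3G** (greedy cumulative removal over the top three
groups, stopping at the first improvement), **O2G** (exhaustive search
over the merged top two groups).

Classification is k-NN with min–max normalized numeric features,
0/1 categorical contributions, odd k (square-root rule or inner-CV RMSE
scan), and evaluation is 10-fold *document-level* cross-validation scored
One Answer per Occurrence with `P = TP/(TP+FP)`, `R = TP/(TP+FN)`,
`F = 2PR/(P+R)`.

## Worked example

The printed benchmark sentence
`"GerE binds to a site on one of these promoters, cotX, that overlaps its
-35 region"` (P1 = GerE, P2 = cotX):

```python
>>> import ppi_groupsel as pg
>>> from ppi_groupsel.features import extract_word_context
>>> lex = pg.default_lexicon()
>>> sent = next(s for s in pg.worked_example_fixtures().sentences()
...             if s.sent_id == "LLL.d33.s1")
>>> b = pg.blind_instance(pg.enumerate_instances(sent)[0])
>>> kw = pg.find_keyword(b, lex)
>>> kw.stem
'bind'
>>> extract_word_context(b, kw)
{'Distance_P1P2': 9, 'Position_P1': 1, 'Position_P2': 11,
 'Distance_KP1': 0, 'Distance_KP2': 8, 'position_of_keyword': 'infix',
 'comma_pattern': 'ft', 'multiple_keywords': False,
 'parallel_expression': False}
```

`Distance_KP1 = 0`: no word separates "binds" from GerE. `Position_P2 =
11`: cotX is the 11th word because the commas are not counted.
`comma_pattern = 'ft'`: no comma between GerE and "binds", one between
"binds" and cotX.

End-to-end on a synthetic corpus (the package generates its own unified
XML; no downloads):

```console
$ ppi-groupsel simulate --seed 5 --out syn.xml
synthetic corpus written to syn.xml
$ ppi-groupsel evaluate --corpus syn.xml --strategy none --seed 5 --out rep.json
P=66.7% R=62.5% F=64.5% (pooled over 120 scored instances)
```

The JSON report carries per-fold and per-subset confusion counts, the
configuration snapshot and the per-fold selection traces.
`ppi-groupsel extract --train ... --input ... --out preds.tsv` labels an
unannotated corpus.

## Lexicons

The original system's 642-word interaction keyword list was never
published. The packaged lexicon (`src/ppi_groupsel/data/default_lexicon.txt`)
is a curated, clearly-marked stand-in seeded with the published example
words; swap in your own with `Lexicon.load(path)` or `--lexicon`.
Absolute F-scores on the benchmark corpora therefore depend on your
lexicon and parser and are not reproduced bit-exactly here.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch through the full tokenize→blind→keyword→extract
pipeline, the five published word-context quantities of the worked
example sentence above (the two keyword–protein distances, the
protein–protein distance, and the two protein positions) and writes them
as JSON; it also smoke-runs the full cross-validation pipeline on a
seeded synthetic corpus.

## Layout

```
src/ppi_groupsel/
  corpus_io.py         unified-XML I/O, instance enumeration, blinding
  linguistic.py        tokenizer, Porter stemmer, lexicons, parse trees
  features.py          the four feature families, 13 syntax patterns
  partitioning.py      ID(K), significant keywords, subsets A/B/C
  knn.py               normalized mixed-type k-NN
  cl_selection.py      contribution levels, BEST1G / U3G / O2G
  evaluation.py        P/R/F, 10-fold document-level CV, inference
  synthetic_corpus.py  corpus generator + worked-example fixtures
  cli.py               ppi-groupsel evaluate / extract / simulate
```

See `docs/methods.md` for modeling assumptions, numerical conventions and
known limitations.
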