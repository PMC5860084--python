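# Methods

## Problem and model

`hocmine` classifies biomedical-literature sentences into a two-level,
37-node Hallmarks-of-Cancer taxonomy (ten hallmarks such as *Resisting cell
death* or *Inducing angiogenesis*, plus 27 process subclasses such as
*Apoptosis* or *Glycolysis/Warburg effect*), and computes query-association
statistics over a classified collection. Classification is one-vs-rest: one
binary linear max-margin classifier per node, trained on the entire corpus,
predicting independently, with predictions integrated into a
hierarchy-consistent label set afterwards. Multi-label output is therefore
native — a sentence can bear any subset of nodes whose ancestors are also
present.

Three modelling rules shape training:

* **Hypernym closure.** A sentence annotated with a subclass counts as a
  positive example for every ancestor ("apoptosis" evidence is "resisting
  cell death" evidence). Gold annotations are stored exactly as annotated;
  closure is applied explicitly at training and scoring time, so annotation
  semantics and training semantics stay separable.
* **Inverse-proportional class weighting.** Fewer than a quarter of
  sentences carry any label, so per-node positives are rare. Each class's
  error weight is w_c = N / (2 n_c), the balanced scheme; any global factor
  is absorbed by the SVM's C.
* **Parent-favoring post-processing.** The 37 binary decisions are resolved
  top-down: a child predicted positive under a (resolved-)negative parent is
  suppressed. Parent classifiers see more positives and are on average
  stronger, so the parent's verdict wins; the pass is idempotent and its
  output always satisfies hierarchy consistency. Parent-positive with
  child-negative is *not* treated as disagreement — subclasses are not
  exhaustive. Multi-level chains are resolved top-down rather than pairwise.

## Features

Sentences are represented in sparse binary form (a feature is 1 iff present).
Seven typed extractors contribute: lemmatized bag of words (LBOW, stopwords
removed), token bi-/trigrams (NGRAM), verb classes from a clustering lexicon
(VC), named-entity types and type:surface pairs (NE), and abstract-inherited
MeSH descriptors (MESH) and chemical names (CHEM). The seventh, semantic
distance (SD), discretizes the maximum cosine similarity between the
sentence's lemmas and the class label in a jointly trained word-label
embedding into B = 10 equal-width bins over [-1, 1]; B is configurable, and
the binning is the simplest scheme compatible with a binary feature format.
NE features emit both the bare type and type:surface pairs because the bare
type alone is nearly information-free; this is an interpretation, recorded
here.

Feature selection is per class: candidate keys must occur in at least one
abstract annotated with the class after closure, and their corpus-wide
sentence document frequency must lie in [min_count, max_count]. Defaults are
min_count = 5 and max_count = 500 per kind, both overridable per class and
kind; occurrence counting is sentence-level document frequency (once per
sentence), matching the binary presence semantics. LBOW excludes stopwords
(toggleable) for sparsity.

External NLP resources are pluggable. The default sentence segmenter is a
regex splitter with an abbreviation guard; the default lemmatizer is the
identity (lowercasing) lemmatizer; the default entity tagger is a gazetteer
over shipped term lists, and the default verb-class lexicon is a small
hand-written stand-in — both labelled synthetic in their filenames, present
so the pipeline and tests run self-contained. A production deployment would
substitute a trained biomedical tagger and the full induced verb clustering
through the same interfaces; every model artifact records the identities of
the components that built it.

## Joint word-label embedding

The SD feature requires words and class labels in one vector space. A
shallow skip-gram model with negative sampling is trained on the corpus with
each sentence's (closed) labels injected as pseudo-tokens whose context is
the whole sentence; word-word pairs use a sliding window (default 5).
Defaults: d = 100 dimensions, 20 epochs, 5 negative samples from the
unigram^0.75 distribution, linearly decaying learning rate from 0.025; all
configurable and stamped into the artifact; training is deterministic given
the seed. Three numerical choices matter: logits are clipped to ±6
(the classical sigmoid-table range) to avoid overflow; the minibatch is
capped at one eighth of the pair count so that tiny corpora train
near-sequentially (large batches full of duplicate indices against stale
weights destabilize training); and the final representation is the sum of
input and output vectors, which carries the first-order word-label
co-occurrence signal the SD feature measures — input vectors alone encode
only second-order (shared-context) similarity. Cosine similarity to an
out-of-vocabulary word or label is undefined and returned as such, never
coerced to a number.

## Evaluation protocol

Nested cross-validation: 4 outer folds (train 75% / test 25%, rotated) with
5-fold inner cross-validation inside each outer training split selecting the
SVM regularization constant per node from a geometric grid
{0.01, 0.1, 1, 10, 100} by pooled inner F1 (ties to the smaller C). Folds
are grouped by abstract so sentences of one abstract never straddle a
train/test boundary (a sentence-level toggle exists for fidelity
experiments). Feature selection and embedding training happen inside each
outer training split; the inner loop reuses the outer split's feature space,
a deliberate economy — the outer estimate remains leakage-free because
selection never sees outer test data. Embedding seeds are derived per fold
from the run seed.

Metrics: precision, recall, F1 and accuracy in percent, per node; macro
averages are unweighted means over nodes, micro averages are metrics of the
pooled per-node confusion counts (the pooling is over nodes; whether a
published "micro" pools over nodes or sentences is ambiguous, and node
pooling is the choice here). Ratios with zero denominators are reported as 0
and flagged rather than raised. Reports round to one decimal place.

Leave-one-out feature ablation reruns nested CV once per feature kind with
that kind removed, under identical fold assignments; the macro-F1 delta
measures the kind's contribution.

Inter-annotator agreement is Cohen's κ = (p_o − p_e)/(1 − p_e) per node
(binary), averaged unweighted over the node subset; nodes on which both
annotators are constant are excluded as degenerate. A multi-label κ has no
single canonical reduction; mean-of-binary-κ is the simplest and is used
here, with subset-agreement κ implementable on top of the same counts.

## Analytics layer

A query is matched as a case-insensitive contiguous token phrase (no
stemming or synonym expansion — predictable and testable; extension hooks
are the tokenizer/lemmatizer interfaces). For hallmark h and query q over N
sentences, with n_q, n_h, n_hq the matched / hallmark-positive / joint
sentence counts:

* CPROB: P(h|q) = n_hq / n_q (undefined when n_q = 0);
* PMI = log[(n_hq/N) / ((n_h/N)(n_q/N))] in natural log (nats; NPMI is
  base-invariant);
* NPMI = PMI / (−log(n_hq/N)) ∈ [−1, 1], undefined additionally when
  P(h,q) = 1.

Undefined values are first-class (`None`/`NA`), never zero-filled.
Probabilities are estimated over the whole supplied collection, not
query-restricted subsets.

Two-query comparison builds a per-node 2×2 table whose rows are the two
queries' matched sets (a sentence matching both queries is counted in both
rows and the overlap is reported) and whose columns split by hallmark
presence. The expected-frequency rule routes the table: Fisher's exact test
when any of the four expected counts (row total × column total / N) is
below five, Pearson's χ² (1 df, no continuity correction) otherwise; a zero
marginal short-circuits to Fisher with p = 1 and a degenerate flag. The
two-sided Fisher p uses the point-probability method, computed in exact
integer arithmetic (binomial coefficients) so ties between table
probabilities are resolved exactly — the single float division happens at
the end, giving agreement with an exhaustive rational-arithmetic enumeration
to better than 1e-12. Bonferroni correction uses m = number of nodes in the
comparison (37 for the full taxonomy): p_corr = min(1, m·p_raw).

## Synthetic corpora

The generator reproduces the statistical structure that drives the pipeline,
not English. Defaults mirror the annotated corpus: 75% of sentences
unlabeled; labelled mass concentrated on two-label sentences (16.8% of all
sentences, the hypernym subclass-plus-parent pattern) with scarce exact
singletons (0.9%) and the remainder over three-plus-label counts. Label sets
are composed of whole ancestor chains with distinct roots, so closure holds
by construction. Each class owns `vocab_per_class` = 10 keyword types
emitted with probability 0.6 per positive sentence over a background
vocabulary of 500 types; abstract metadata (`MH-`/`CH-` terms) is attached
per contained label with probability 0.3. Abstracts hold 4-8 sentences.
Everything is reproducible from the seed.

A second generator emits a *separable* corpus: each node owns a disjoint
signature vocabulary and every positive sentence contains at least two
(three in practice) signature words per carried label, guaranteeing linear
separability per node. It is the parameter-recovery fixture: a correct
pipeline must score near-perfect nested-CV macro-F1 on it.

What passing on synthetic data does **not** show: robustness to real
lexical ambiguity, annotation noise, negation/speculation, or genuine
English syntax. The synthetic corpora validate the machinery (closure,
weighting, selection, hierarchy handling, statistics), not the attainable
accuracy on the released annotated corpus, which additionally depends on
the external tagger and lemmatizer of record.

## Problem sizes used in the shipped checks

Chosen as the smallest sizes at which the checked properties are stable:
parameter recovery runs nested CV on the separable corpus at n = 2000
sentences with a reduced embedding (d = 50, 5 epochs); the ablation check
uses the realistic generator at 150 abstracts (~900 sentences), a 3-value C
grid and 3 inner folds; distribution recovery uses ~10,000 sentences; the
Fisher oracle sweep is exhaustive for N ≤ 12 plus 1,000 random tables at
N ≤ 50; PMI/NPMI and post-processing fuzzing use 10,000 random cases each.

## Known limitations

* The default segmenter/lemmatizer are deliberately simple; lemma quality
  on real text is lower than with a trained biomedical pipeline, which
  affects LBOW/VC/SD feature quality.
* The gazetteer tagger and stand-in verb lexicon cover only the shipped
  term lists; NE and VC features on real text are skeletal until real
  resources are plugged in.
* Scores are raw margins; no probability calibration is attempted, and the
  decision threshold is fixed at 0.
* The taxonomy machinery assumes dotted-code forests; no ontology formats.
* Fisher's exact test enumerates the hypergeometric support, which is ample
  for sentence-scale 2×2 tables but not tuned for counts in the millions
  (the χ² branch covers those by the expected-frequency rule).
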