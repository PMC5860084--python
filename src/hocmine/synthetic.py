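"""Seeded synthetic corpora with the statistical shape of the annotated data.

The generator emulates the structure that matters to the pipeline rather
than realistic English: about 75% of sentences carry no hallmark label; most
labelled sentences carry two labels coupled through hypernymy (a subclass
plus its parent) and almost none carry exactly one; each class has its own
small keyword vocabulary embedded in background noise; abstract-level
MeSH/chemical metadata is correlated with the labels the abstract contains.
Sentence "text" is space-joined word tokens and lemmas equal lowercased
tokens, which is all the feature pipeline consumes.

Two generators are provided: :func:`generate_corpus` (the realistic-shape
corpus above) and :func:`generate_separable_corpus`, which gives every node
a disjoint signature vocabulary with at least two signature words per label
in every positive sentence, guaranteeing linear separability per node — the
fixture used for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .corpus_io import AbstractRecord, SentenceRecord
from .taxonomy import Taxonomy

__all__ = ["SyntheticSpec", "generate_corpus", "generate_separable_corpus"]

# Shape of the label-count distribution among labelled sentences, anchored at
# the annotated corpus: two-label sentences dominate (hypernym pairs, 16.8%
# of all sentences), exact singletons are scarce (0.9%), the rest is spread
# over three-plus-label sentences.
_LABELLED_SHAPE = {1: 0.009, 2: 0.168, 3: 0.055, 4: 0.018}


def _sanitize(code: str) -> str:
    return code.replace(".", "x")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic corpus generator."""

    n_abstracts: int = 400
    sentences_per_abstract: Tuple[int, int] = (4, 8)
    p_unlabeled: float = 0.75
    label_marginals: Optional[Dict[str, float]] = None
    vocab_per_class: int = 10
    background_vocab: int = 500
    keyword_rate: float = 0.6
    metadata_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for name in ("p_unlabeled", "keyword_rate", "metadata_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_abstracts", "vocab_per_class", "background_vocab"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.sentences_per_abstract
        if not 1 <= lo <= hi:
            raise ValueError("invalid sentences_per_abstract range")

    def label_count_distribution(self) -> Dict[int, float]:
        """Distribution of labels-per-sentence implied by ``p_unlabeled`` and
        the annotated-corpus shape of the labelled mass."""
        labelled_mass = 1.0 - self.p_unlabeled
        total_shape = sum(_LABELLED_SHAPE.values())
        dist = {0: self.p_unlabeled}
        for k, w in _LABELLED_SHAPE.items():
            dist[k] = labelled_mass * w / total_shape
        return dist


def _chains_by_size(taxonomy: Taxonomy) -> Dict[int, List[str]]:
    by_size: Dict[int, List[str]] = {1: [], 2: [], 3: []}
    for node in taxonomy:
        if node.level in by_size:
            by_size[node.level].append(node.code)
    return {k: sorted(v) for k, v in by_size.items()}


def _closure(taxonomy: Taxonomy, code: str) -> Set[str]:
    return {code, *taxonomy.ancestors(code)}


def _sample_label_set(
    rng: np.random.Generator,
    taxonomy: Taxonomy,
    k: int,
    chains: Dict[int, List[str]],
    weights: Optional[Dict[str, float]],
) -> Set[str]:
    """A closed label set of exactly k codes, composed of whole ancestor
    chains with distinct roots (hypernym-coupled multi-labels)."""
    for _ in range(50):
        parts: List[int] = []
        remaining = k
        while remaining > 0:
            allowed = [s for s in (1, 2, 3) if s <= remaining and chains[s]]
            probs = np.array([{1: 0.15, 2: 0.55, 3: 0.30}[s] for s in allowed])
            parts.append(int(rng.choice(allowed, p=probs / probs.sum())))
            remaining -= parts[-1]
        labels: Set[str] = set()
        roots: Set[str] = set()
        ok = True
        for size in parts:
            candidates = chains[size]
            if weights:
                w = np.array([weights.get(c, 1.0) for c in candidates], dtype=float)
                code = str(rng.choice(candidates, p=w / w.sum()))
            else:
                code = str(rng.choice(candidates))
            chain = _closure(taxonomy, code)
            root = min(chain, key=len)
            if root in roots:
                ok = False
                break
            roots.add(root)
            labels |= chain
        if ok and len(labels) == k:
            return labels
    # Fallback: accumulate chains until >= k (rare; only for extreme k).
    labels = set()
    while len(labels) < k:
        labels |= _closure(taxonomy, str(rng.choice(taxonomy.codes)))
    return labels


def _class_words(code: str, count: int) -> List[str]:
    return [f"kw{_sanitize(code)}w{j}" for j in range(count)]


def generate_corpus(
    spec: SyntheticSpec, taxonomy: Taxonomy
) -> Tuple[List[AbstractRecord], List[SentenceRecord]]:
    """Generate abstracts and annotated sentences; reproducible from seed.

    Labelled sentences draw each of their classes' keywords with probability
    ``keyword_rate`` on top of background words; a subclass label always
    brings its ancestors (closure holds by construction).  Abstract metadata
    (``MH-<code>`` MeSH descriptors, ``CH-<code>`` chemicals) is attached
    per contained label with probability ``metadata_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    chains = _chains_by_size(taxonomy)
    dist = spec.label_count_distribution()
    ks = np.array(sorted(dist))
    probs = np.array([dist[k] for k in ks])
    probs = probs / probs.sum()
    background = [f"bg{j}" for j in range(spec.background_vocab)]

    abstracts: List[AbstractRecord] = []
    sentences: List[SentenceRecord] = []
    lo, hi = spec.sentences_per_abstract
    for a in range(spec.n_abstracts):
        pmid = f"S{a + 1:06d}"
        n_sent = int(rng.integers(lo, hi + 1))
        abstract_labels: Set[str] = set()
        records: List[SentenceRecord] = []
        for i in range(n_sent):
            k = int(rng.choice(ks, p=probs))
            labels = (
                _sample_label_set(rng, taxonomy, k, chains, spec.label_marginals)
                if k
                else set()
            )
            abstract_labels |= labels
            words: List[str] = []
            for code in sorted(labels):
                for word in _class_words(code, spec.vocab_per_class):
                    if rng.random() < spec.keyword_rate:
                        words.append(word)
            n_bg = int(rng.integers(8, 16))
            words.extend(str(w) for w in rng.choice(background, size=n_bg))
            rng.shuffle(words)
            tokens = [w.capitalize() if j == 0 else w for j, w in enumerate(words)]
            records.append(
                SentenceRecord(
                    pmid=pmid,
                    index=i,
                    text=" ".join(tokens),
                    tokens=tokens,
                    lemmas=[t.lower() for t in tokens],
                    gold_labels=labels,
                )
            )
        mesh = [
            f"MH-{code}"
            for code in sorted(abstract_labels)
            if rng.random() < spec.metadata_rate
        ]
        chem = [
            f"CH-{code}"
            for code in sorted(abstract_labels)
            if rng.random() < spec.metadata_rate
        ]
        for rec in records:
            rec.mesh_terms = list(mesh)
            rec.chemicals = list(chem)
        body = " ".join(rec.text + "." for rec in records)
        abstracts.append(
            AbstractRecord(
                pmid=pmid,
                title=f"Synthetic abstract {pmid}",
                body=body,
                mesh_terms=mesh,
                chemicals=chem,
                sentences=records,
            )
        )
        sentences.extend(records)
    return abstracts, sentences


def generate_separable_corpus(
    taxonomy: Taxonomy,
    n: int,
    seed: int = 0,
    signature_size: int = 6,
    background_vocab: int = 200,
    sentences_per_abstract: int = 5,
) -> List[SentenceRecord]:
    """Linearly separable fixture: disjoint signature vocabulary per node.

    Sentence ``i`` is assigned node ``i mod 37`` with full ancestor closure;
    every labelled sentence contains at least two (here three) signature
    words of each of its labels, so each node's positives are separable from
    all other sentences by the presence of its signature words.
    """
    if n < 10 * len(taxonomy):
        raise ValueError(f"n={n} too small; need at least {10 * len(taxonomy)}")
    rng = np.random.default_rng(seed)
    codes = taxonomy.codes
    signatures = {
        code: [f"sig{_sanitize(code)}w{j}" for j in range(signature_size)]
        for code in codes
    }
    background = [f"bg{j}" for j in range(background_vocab)]
    sentences: List[SentenceRecord] = []
    order = rng.permutation(n)
    for i in range(n):
        code = codes[int(order[i]) % len(codes)]
        labels = _closure(taxonomy, code)
        words: List[str] = []
        for label in sorted(labels):
            picks = rng.choice(signatures[label], size=3, replace=False)
            words.extend(str(w) for w in picks)
        words.extend(str(w) for w in rng.choice(background, size=5))
        rng.shuffle(words)
        pmid = f"P{i // sentences_per_abstract + 1:06d}"
        tokens = [w.capitalize() if j == 0 else w for j, w in enumerate(words)]
        sentences.append(
            SentenceRecord(
                pmid=pmid,
                index=i % sentences_per_abstract,
                text=" ".join(tokens),
                tokens=tokens,
                lemmas=[t.lower() for t in tokens],
                gold_labels=labels,
            )
        )
    return sentences
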