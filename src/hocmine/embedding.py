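"""Joint word-label embedding for the semantic-distance feature.

A shallow predictive model (skip-gram with negative sampling) is trained on
the annotated corpus with the sentence's hallmark labels injected as
pseudo-tokens into the sentence's context: every in-vocabulary word of a
labelled sentence predicts the sentence's label tokens and vice versa, with
the label's effective window spanning the whole sentence.  Words and labels
therefore live in one vector space, and the cosine similarity between a
sentence's words and a class label becomes a classification feature.

Training is plain numpy (mini-batched gradient updates), deterministic for a
fixed seed, and sized for annotated-corpus-scale data (thousands of
sentences), not for web-scale text.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from ._text import STOPWORDS
from .corpus_io import SentenceRecord
from .taxonomy import Taxonomy

__all__ = ["EmbeddingConfig", "EmbeddingModel", "train_embedding"]

_LABEL_PREFIX = "__label__"


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters of the joint embedding.

    ``dim`` is the vector length; ``window`` the one-sided word-word context
    width (label tokens always see the whole sentence); ``negatives`` the
    number of noise samples per positive pair drawn from the unigram^0.75
    distribution.
    """

    dim: int = 100
    window: int = 5
    epochs: int = 20
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    negatives: int = 5
    min_count: int = 1
    batch_size: int = 4096
    seed: int = 0


class EmbeddingModel:
    """Vocabulary plus packed vectors for words and label pseudo-tokens."""

    def __init__(self, vocab: List[str], vectors: np.ndarray, config: EmbeddingConfig):
        if vectors.shape[0] != len(vocab):
            raise ValueError("vocab/vector row mismatch")
        self.vocab = vocab
        self.vectors = vectors
        self.config = config
        self._index: Dict[str, int] = {tok: i for i, tok in enumerate(vocab)}

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def word_vector(self, lemma: str) -> Optional[np.ndarray]:
        idx = self._index.get(lemma.lower())
        return None if idx is None else self.vectors[idx]

    def label_vector(self, code: str) -> Optional[np.ndarray]:
        idx = self._index.get(_LABEL_PREFIX + code)
        return None if idx is None else self.vectors[idx]

    def has_label(self, code: str) -> bool:
        return _LABEL_PREFIX + code in self._index

    def similarity(self, lemma: str, code: str) -> Optional[float]:
        """Cosine similarity in [-1, 1]; None when either side is missing or
        zero (out-of-vocabulary is a first-class outcome, not an error)."""
        w = self.word_vector(lemma)
        v = self.label_vector(code)
        if w is None or v is None:
            return None
        nw, nv = np.linalg.norm(w), np.linalg.norm(v)
        if nw == 0.0 or nv == 0.0:
            return None
        return float(np.clip(np.dot(w, v) / (nw * nv), -1.0, 1.0))

    def max_similarity(self, lemmas: Sequence[str], code: str) -> Optional[float]:
        """Max cosine similarity of any in-vocabulary lemma to the label."""
        v = self.label_vector(code)
        if v is None:
            return None
        rows = [self._index[l] for l in {l.lower() for l in lemmas} if l in self._index]
        if not rows:
            return None
        mat = self.vectors[rows]
        norms = np.linalg.norm(mat, axis=1)
        nv = np.linalg.norm(v)
        valid = (norms > 0) & (nv > 0)
        if not valid.any():
            return None
        sims = (mat[valid] @ v) / (norms[valid] * nv)
        return float(np.clip(sims.max(), -1.0, 1.0))

    # ---------------------------------------------------------- persistence

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "embedding_config.json"), "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)
        with open(os.path.join(directory, "embedding_vocab.json"), "w") as fh:
            json.dump(self.vocab, fh)
        np.save(os.path.join(directory, "embedding_vectors.npy"), self.vectors)

    @classmethod
    def load(cls, directory) -> "EmbeddingModel":
        with open(os.path.join(directory, "embedding_config.json")) as fh:
            config = EmbeddingConfig(**json.load(fh))
        with open(os.path.join(directory, "embedding_vocab.json")) as fh:
            vocab = json.load(fh)
        vectors = np.load(os.path.join(directory, "embedding_vectors.npy"))
        return cls(vocab, vectors, config)


def _closed_labels(s: SentenceRecord, taxonomy: Taxonomy) -> List[str]:
    closed = set(s.gold_labels)
    for label in s.gold_labels:
        closed.update(taxonomy.ancestors(label))
    return sorted(closed)


def train_embedding(
    sentences: Sequence[SentenceRecord],
    taxonomy: Taxonomy,
    config: EmbeddingConfig = EmbeddingConfig(),
) -> EmbeddingModel:
    """Train the joint space with skip-gram negative sampling.

    Word-word pairs use the sliding window; word-label pairs are generated
    for every (in-vocabulary word, closed sentence label) combination so the
    label's context is the whole sentence.  Raises ``ValueError`` when the
    corpus has no labelled sentence — without labels there is nothing to
    embed jointly.
    """
    if not any(s.gold_labels for s in sentences):
        raise ValueError("corpus has no labelled sentences; joint embedding undefined")

    counts: Dict[str, int] = {}
    for s in sentences:
        for lemma in s.lemmas:
            low = lemma.lower()
            if low not in STOPWORDS:
                counts[low] = counts.get(low, 0) + 1
    vocab = sorted(w for w, c in counts.items() if c >= config.min_count)
    label_tokens = sorted(
        {_LABEL_PREFIX + code for s in sentences for code in _closed_labels(s, taxonomy)}
    )
    vocab = vocab + label_tokens
    index = {tok: i for i, tok in enumerate(vocab)}

    centers: List[int] = []
    contexts: List[int] = []
    freq = np.zeros(len(vocab), dtype=np.float64)
    for s in sentences:
        word_ids = [index[l.lower()] for l in s.lemmas if l.lower() in index]
        for wid in word_ids:
            freq[wid] += 1
        for i, wid in enumerate(word_ids):
            lo = max(0, i - config.window)
            hi = min(len(word_ids), i + config.window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(wid)
                    contexts.append(word_ids[j])
        for code in _closed_labels(s, taxonomy):
            lid = index[_LABEL_PREFIX + code]
            freq[lid] += 1
            for wid in word_ids:
                centers.append(wid)
                contexts.append(lid)
                centers.append(lid)
                contexts.append(wid)

    if not centers:
        raise ValueError("no training pairs; corpus vocabulary is empty")

    centers_arr = np.asarray(centers, dtype=np.int64)
    contexts_arr = np.asarray(contexts, dtype=np.int64)
    n_pairs = len(centers_arr)

    rng = np.random.default_rng(config.seed)
    noise = np.maximum(freq, 1.0) ** 0.75
    noise /= noise.sum()

    v = len(vocab)
    w_in = (rng.random((v, config.dim)) - 0.5) / config.dim
    w_out = np.zeros((v, config.dim))

    # On small corpora a full-size minibatch accumulates many duplicate-index
    # updates against stale weights and destabilizes training; cap the batch
    # at ~1/8 of the pair count so tiny corpora train near-sequentially.
    batch_size = max(16, min(config.batch_size, n_pairs // 8))
    total_batches = max(1, config.epochs * int(np.ceil(n_pairs / batch_size)))
    batch_no = 0
    for _ in range(config.epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            sel = order[start : start + batch_size]
            c = centers_arr[sel]
            o = contexts_arr[sel]
            frac = batch_no / total_batches
            lr = config.learning_rate * (1 - frac) + config.min_learning_rate * frac
            batch_no += 1

            negs = rng.choice(v, size=(len(sel), config.negatives), p=noise)
            h = w_in[c]                                    # (B, d)
            ctx = w_out[o]                                 # (B, d)
            neg = w_out[negs]                              # (B, K, d)

            # logits clipped to +/-6 (word2vec-style sigmoid table range)
            pos_logit = np.clip(np.einsum("bd,bd->b", h, ctx), -6.0, 6.0)
            neg_logit = np.clip(np.einsum("bd,bkd->bk", h, neg), -6.0, 6.0)
            pos_score = 1.0 / (1.0 + np.exp(-pos_logit))
            neg_score = 1.0 / (1.0 + np.exp(-neg_logit))

            g_pos = (pos_score - 1.0)[:, None]             # (B, 1)
            g_neg = neg_score[:, :, None]                  # (B, K, 1)

            grad_h = g_pos * ctx + np.einsum("bk,bkd->bd", neg_score, neg)
            np.add.at(w_in, c, -lr * grad_h)
            np.add.at(w_out, o, -lr * (g_pos * h))
            np.add.at(
                w_out.reshape(-1),
                (negs[:, :, None] * config.dim + np.arange(config.dim)).ravel(),
                (-lr * (g_neg * h[:, None, :])).ravel(),
            )

    # Combined input+output representation: the sum captures first-order
    # co-occurrence (word-label attraction lives in the input.output product),
    # which is exactly what the semantic-distance feature measures.
    return EmbeddingModel(vocab=vocab, vectors=w_in + w_out, config=config)
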