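"""The seven feature types, per-class feature selection, and vectorization.

Each sentence is represented in a sparse binary format: a feature is 1 when
the sentence contains it.  Seven typed extractors contribute keys:

====  =============================================================
LBOW  lemmatized bag of words (lowercased, stopwords removed)
NGRAM token bigrams and trigrams, joined with ``_``
VC    verb-class identifiers from a verb-clustering lexicon
NE    named-entity types (Protein, DNA, RNA, Cell_line, Cell_type),
      both the bare type and type:surface pairs
MESH  MeSH descriptors inherited from the abstract
CHEM  chemical-substance names inherited from the abstract
SD    semantic distance: the binned maximum cosine similarity between
      the sentence's lemmas and the class label in a joint embedding
====  =============================================================

Feature selection is per class: candidate keys must occur in at least one
abstract annotated (after hypernym closure) with the class, and their
corpus-wide sentence document frequency must lie within ``[min_count,
max_count]`` — too-rare and too-common features are filtered out.  Every
class therefore has its own :class:`FeatureSpace`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Set

import numpy as np
from scipy import sparse

from ._text import STOPWORDS
from .corpus_io import SentenceRecord
from .taxonomy import Taxonomy

__all__ = [
    "FeatureKey",
    "FeatureSpace",
    "SparseVector",
    "VerbClassLexicon",
    "GazetteerTagger",
    "FeatureExtractor",
    "FEATURE_KINDS",
    "ENTITY_TYPES",
    "extract_lbow",
    "extract_ngrams",
    "extract_verb_classes",
    "extract_entities",
    "extract_metadata",
    "extract_semantic_distance",
    "select_features",
    "vectorize",
    "build_matrix",
    "EmptyClassError",
]

FEATURE_KINDS = ("LBOW", "NGRAM", "VC", "NE", "MESH", "CHEM", "SD")
ENTITY_TYPES = ("Protein", "DNA", "RNA", "Cell_line", "Cell_type")

DEFAULT_MIN_COUNT = 5
DEFAULT_MAX_COUNT = 500
DEFAULT_SD_BINS = 10


class EmptyClassError(ValueError):
    """A class has no positive sentences (after hypernym closure)."""


class FeatureKey(NamedTuple):
    kind: str
    value: str


# ------------------------------------------------------------------ lexicons


class VerbClassLexicon:
    """Mapping from verb lemma to verb-class identifier(s).

    Verb classes group semantically similar predicates so the classifier can
    abstract away from individual verbs under data sparsity.  The original
    resource is an automatically induced clustering of 399 verbs; the shipped
    default (``verb_classes.synthetic.tsv``) is a small hand-written stand-in
    with the same file format.
    """

    def __init__(self, mapping: Mapping[str, Set[str]]):
        self.mapping: Dict[str, Set[str]] = {
            lemma.lower(): set(classes) for lemma, classes in mapping.items()
        }

    def classes_for(self, lemma: str) -> Set[str]:
        return self.mapping.get(lemma.lower(), set())

    @classmethod
    def from_tsv(cls, path) -> "VerbClassLexicon":
        mapping: Dict[str, Set[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                lemma, class_id = line.split("\t")[:2]
                mapping.setdefault(lemma.lower(), set()).add(class_id)
        return cls(mapping)

    @classmethod
    def default(cls) -> "VerbClassLexicon":
        ref = resources.files("hocmine.data").joinpath("verb_classes.synthetic.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


class GazetteerTagger:
    """Dictionary-based entity tagger over per-type term lists.

    Implements the tagging contract (one tag per token, ``O`` for none).  The
    shipped gazetteers are synthetic stand-ins for an external biomedical
    tagger; a subprocess adapter satisfying the same contract can replace it.
    """

    identity = "hocmine-gazetteer-tagger/1"

    def __init__(self, gazetteers: Mapping[str, Set[str]]):
        self.gazetteers = {t: {w.lower() for w in ws} for t, ws in gazetteers.items()}

    def tag(self, tokens: Sequence[str]) -> List[str]:
        tags = []
        for token in tokens:
            low = token.lower()
            tag = "O"
            for etype in ENTITY_TYPES:
                if low in self.gazetteers.get(etype, ()):
                    tag = etype
                    break
            tags.append(tag)
        return tags

    @classmethod
    def default(cls) -> "GazetteerTagger":
        base = resources.files("hocmine.data").joinpath("gazetteers")
        file_for = {
            "Protein": "protein.synthetic.txt",
            "DNA": "dna.synthetic.txt",
            "RNA": "rna.synthetic.txt",
            "Cell_line": "cell_line.synthetic.txt",
            "Cell_type": "cell_type.synthetic.txt",
        }
        gazetteers = {}
        for etype, fname in file_for.items():
            text = base.joinpath(fname).read_text(encoding="utf-8")
            gazetteers[etype] = {w.strip() for w in text.splitlines() if w.strip()}
        return cls(gazetteers)


# ---------------------------------------------------------------- extractors


def extract_lbow(s: SentenceRecord, stopwords: FrozenSet[str] = STOPWORDS) -> Set[FeatureKey]:
    """One LBOW key per distinct non-stopword lemma, lowercased."""
    if not s.lemmas and s.tokens:
        raise ValueError(f"sentence {s.sentence_id} has tokens but no lemmas; lemmatize first")
    return {
        FeatureKey("LBOW", lemma.lower())
        for lemma in s.lemmas
        if lemma.lower() not in stopwords
    }


def extract_ngrams(s: SentenceRecord) -> Set[FeatureKey]:
    """All contiguous token bigrams and trigrams, joined with ``_``."""
    tokens = s.tokens
    keys: Set[FeatureKey] = set()
    for n in (2, 3):
        for i in range(len(tokens) - n + 1):
            keys.add(FeatureKey("NGRAM", "_".join(tokens[i : i + n])))
    return keys


def extract_verb_classes(s: SentenceRecord, lexicon: VerbClassLexicon) -> Set[FeatureKey]:
    keys: Set[FeatureKey] = set()
    for lemma in s.lemmas:
        for class_id in lexicon.classes_for(lemma):
            keys.add(FeatureKey("VC", class_id))
    return keys


def extract_entities(s: SentenceRecord, tagger) -> Set[FeatureKey]:
    """NE keys for the bare entity type and for type:surface pairs."""
    tags = tagger.tag(s.tokens)
    if len(tags) != len(s.tokens):
        raise ValueError(
            f"entity tagger returned {len(tags)} tags for {len(s.tokens)} tokens"
        )
    keys: Set[FeatureKey] = set()
    for token, tag in zip(s.tokens, tags):
        if tag != "O":
            keys.add(FeatureKey("NE", tag))
            keys.add(FeatureKey("NE", f"{tag}:{token.lower()}"))
    return keys


def extract_metadata(s: SentenceRecord) -> Set[FeatureKey]:
    """MESH and CHEM keys from the metadata inherited from the abstract."""
    keys = {FeatureKey("MESH", term) for term in s.mesh_terms}
    keys |= {FeatureKey("CHEM", name) for name in s.chemicals}
    return keys


def sd_bin(similarity: float, bins: int = DEFAULT_SD_BINS) -> int:
    """Index of the equal-width bin over [-1, 1] containing ``similarity``.

    Bins partition [-1, 1]: bin i covers [-1 + 2i/B, -1 + 2(i+1)/B), with the
    final bin closed at 1.
    """
    idx = int(np.floor((similarity + 1.0) / 2.0 * bins))
    return min(max(idx, 0), bins - 1)


def extract_semantic_distance(
    s: SentenceRecord,
    embedding,
    code: str,
    bins: int = DEFAULT_SD_BINS,
    stopwords: FrozenSet[str] = STOPWORDS,
) -> Set[FeatureKey]:
    """Binned maximum cosine similarity between sentence lemmas and the label.

    Returns the empty set when no lemma is in the embedding vocabulary; a
    label missing from the embedding altogether is a model error.
    """
    if hasattr(embedding, "has_label") and not embedding.has_label(code):
        raise ValueError(f"label {code!r} missing from the embedding model")
    sims = [
        sim
        for lemma in set(s.lemmas)
        if lemma.lower() not in stopwords
        and (sim := embedding.similarity(lemma, code)) is not None
    ]
    if not sims:
        return set()
    return {FeatureKey("SD", f"{code}|bin{sd_bin(max(sims), bins)}")}


# --------------------------------------------------------- extractor bundle


@dataclass
class FeatureExtractor:
    """Configured set of extractors applied uniformly across the pipeline."""

    kinds: Sequence[str] = FEATURE_KINDS
    lexicon: Optional[VerbClassLexicon] = None
    tagger: Optional[GazetteerTagger] = None
    embedding: Optional[object] = None
    sd_bins: int = DEFAULT_SD_BINS
    stopwords: FrozenSet[str] = STOPWORDS

    def __post_init__(self):
        unknown = set(self.kinds) - set(FEATURE_KINDS)
        if unknown:
            raise ValueError(f"unknown feature kinds: {sorted(unknown)}")
        self.kinds = tuple(self.kinds)
        if "VC" in self.kinds and self.lexicon is None:
            self.lexicon = VerbClassLexicon.default()
        if "NE" in self.kinds and self.tagger is None:
            self.tagger = GazetteerTagger.default()

    def without(self, kind: str) -> "FeatureExtractor":
        """A copy with one feature kind removed (leave-one-out ablation)."""
        return FeatureExtractor(
            kinds=tuple(k for k in self.kinds if k != kind),
            lexicon=self.lexicon,
            tagger=self.tagger,
            embedding=self.embedding,
            sd_bins=self.sd_bins,
            stopwords=self.stopwords,
        )

    def base_keys(self, s: SentenceRecord) -> Set[FeatureKey]:
        """All class-independent keys (everything except SD)."""
        keys: Set[FeatureKey] = set()
        if "LBOW" in self.kinds:
            keys |= extract_lbow(s, self.stopwords)
        if "NGRAM" in self.kinds:
            keys |= extract_ngrams(s)
        if "VC" in self.kinds:
            keys |= extract_verb_classes(s, self.lexicon)
        if "NE" in self.kinds:
            keys |= extract_entities(s, self.tagger)
        if "MESH" in self.kinds or "CHEM" in self.kinds:
            meta = extract_metadata(s)
            if "MESH" not in self.kinds:
                meta = {k for k in meta if k.kind != "MESH"}
            if "CHEM" not in self.kinds:
                meta = {k for k in meta if k.kind != "CHEM"}
            keys |= meta
        return keys

    def keys(self, s: SentenceRecord, code: Optional[str] = None) -> Set[FeatureKey]:
        """All keys for one sentence, including SD when a class is given."""
        keys = self.base_keys(s)
        if "SD" in self.kinds and code is not None and self.embedding is not None:
            keys |= extract_semantic_distance(
                s, self.embedding, code, self.sd_bins, self.stopwords
            )
        return keys


# ----------------------------------------------------- selection and vectors


@dataclass
class FeatureSpace:
    """Per-class bijection from selected feature keys to column indices."""

    node_code: str
    index: Dict[FeatureKey, int]
    min_count: int
    max_count: Dict[str, int]

    @property
    def dimension(self) -> int:
        return len(self.index)

    def to_json(self, path) -> None:
        payload = {
            "node_code": self.node_code,
            "min_count": self.min_count,
            "max_count": self.max_count,
            "features": [
                {"kind": k.kind, "value": k.value, "column": col}
                for k, col in sorted(self.index.items(), key=lambda kv: kv[1])
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FeatureSpace":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        index = {
            FeatureKey(f["kind"], f["value"]): f["column"] for f in payload["features"]
        }
        return cls(
            node_code=payload["node_code"],
            index=index,
            min_count=payload["min_count"],
            max_count=payload["max_count"],
        )


@dataclass(frozen=True)
class SparseVector:
    """Active column positions of one sentence (implicit values of 1)."""

    columns: FrozenSet[int]
    dimension: int

    def __post_init__(self):
        if any(c < 0 or c >= self.dimension for c in self.columns):
            raise ValueError("column position outside vector dimension")


def _resolve_max_count(max_count) -> Dict[str, int]:
    if isinstance(max_count, Mapping):
        resolved = {k: DEFAULT_MAX_COUNT for k in FEATURE_KINDS}
        resolved.update(max_count)
        return resolved
    return {k: int(max_count) for k in FEATURE_KINDS}


def select_features(
    sentences: Sequence[SentenceRecord],
    code: str,
    taxonomy: Taxonomy,
    extractor: FeatureExtractor,
    min_count: int = DEFAULT_MIN_COUNT,
    max_count=DEFAULT_MAX_COUNT,
    key_sets: Optional[Sequence[Set[FeatureKey]]] = None,
) -> FeatureSpace:
    """Build the :class:`FeatureSpace` for one class.

    Candidates are keys occurring in at least one sentence of an abstract
    annotated with ``code`` after hypernym closure; they are kept when their
    corpus-wide sentence document frequency lies in ``[min_count,
    max_count[kind]]`` (bounds inclusive).  ``key_sets`` may supply
    precomputed per-sentence key sets aligned with ``sentences``.

    Raises :class:`EmptyClassError` when no sentence is positive for
    ``code``.
    """
    if not sentences:
        raise EmptyClassError(f"no sentences supplied for class {code}")
    if key_sets is None:
        key_sets = [extractor.keys(s, code) for s in sentences]
    max_by_kind = _resolve_max_count(max_count)

    positive_pmids: Set[str] = set()
    for s in sentences:
        closed = set(s.gold_labels)
        for label in s.gold_labels:
            closed.update(taxonomy.ancestors(label))
        if code in closed:
            positive_pmids.add(s.pmid)
    if not positive_pmids:
        raise EmptyClassError(f"class {code} has no positive sentences after closure")

    counts: Dict[FeatureKey, int] = {}
    candidates: Set[FeatureKey] = set()
    for s, keys in zip(sentences, key_sets):
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
        if s.pmid in positive_pmids:
            candidates.update(keys)

    selected = sorted(
        k for k in candidates if min_count <= counts[k] <= max_by_kind[k.kind]
    )
    index = {key: col for col, key in enumerate(selected)}
    return FeatureSpace(
        node_code=code, index=index, min_count=min_count, max_count=max_by_kind
    )


def vectorize(
    s: SentenceRecord,
    space: FeatureSpace,
    extractor: FeatureExtractor,
    keys: Optional[Set[FeatureKey]] = None,
) -> SparseVector:
    """Sparse binary vector of one sentence in a class's feature space.

    Keys absent from the space are silently dropped.
    """
    if keys is None:
        keys = extractor.keys(s, space.node_code)
    columns = frozenset(space.index[k] for k in keys if k in space.index)
    return SparseVector(columns=columns, dimension=space.dimension)


def build_matrix(vectors: Sequence[SparseVector]) -> sparse.csr_matrix:
    """Stack sparse binary vectors into a CSR matrix (rows = sentences)."""
    if not vectors:
        raise ValueError("no vectors to stack")
    dim = vectors[0].dimension
    indptr = [0]
    indices: List[int] = []
    for v in vectors:
        if v.dimension != dim:
            raise ValueError("inconsistent vector dimensions")
        cols = sorted(v.columns)
        indices.extend(cols)
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.float64)
    return sparse.csr_matrix(
        (data, np.asarray(indices, dtype=np.int32), np.asarray(indptr, dtype=np.int32)),
        shape=(len(vectors), dim),
    )
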