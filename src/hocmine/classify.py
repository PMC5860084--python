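"""One-vs-rest linear classifiers over the hallmark taxonomy.

One binary linear max-margin classifier (liblinear, squared hinge, primal)
is trained per taxonomy node on the entire corpus.  Positive examples for a
node are the sentences whose gold labels, after hypernym closure, contain
the node — a sentence annotated "Apoptosis" is a positive example for
"Resisting cell death" as well.  Class imbalance (most sentences are
negative for every node) is handled by inverse-proportional class weighting,
w_c = N / (2 n_c).

Prediction is the sign of the decision value per node; the independent
binary decisions are then integrated into a hierarchy-consistent label set
by a top-down, parent-favoring pass: a child predicted positive under a
negative parent is suppressed, because parent classifiers (with more
positive data) are on average the stronger ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.svm import LinearSVC

from .corpus_io import SentenceRecord
from .embedding import EmbeddingConfig, EmbeddingModel, train_embedding
from .features import (
    DEFAULT_MAX_COUNT,
    DEFAULT_MIN_COUNT,
    DEFAULT_SD_BINS,
    FEATURE_KINDS,
    FeatureExtractor,
    FeatureSpace,
    build_matrix,
    select_features,
    vectorize,
)
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "NodeClassifier",
    "ModelBundle",
    "PredictionSet",
    "closure_labels",
    "compute_class_weights",
    "train_node",
    "train_bundle",
    "postprocess",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a trained model."""

    feature_kinds: Tuple[str, ...] = FEATURE_KINDS
    min_count: int = DEFAULT_MIN_COUNT
    max_count: int = DEFAULT_MAX_COUNT
    sd_bins: int = DEFAULT_SD_BINS
    C: float = 1.0
    C_grid: Tuple[float, ...] = DEFAULT_C_GRID
    outer_folds: int = 4
    inner_folds: int = 5
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_kinds"] = list(self.feature_kinds)
        d["C_grid"] = list(self.C_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["feature_kinds"] = tuple(d["feature_kinds"])
        d["C_grid"] = tuple(d["C_grid"])
        d["embedding"] = EmbeddingConfig(**d["embedding"])
        return cls(**d)


def closure_labels(labels: Set[str], taxonomy: Taxonomy) -> Set[str]:
    """Gold labels unioned with all their ancestors (hypernym closure)."""
    closed = set(labels)
    for label in labels:
        closed.update(taxonomy.ancestors(label))
    return closed


def compute_class_weights(n_pos: int, n_neg: int) -> Tuple[float, float]:
    """Inverse-proportional (balanced) class weights w_c = N / (2 n_c)."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError(f"empty class: n_pos={n_pos}, n_neg={n_neg}")
    total = n_pos + n_neg
    return total / (2.0 * n_pos), total / (2.0 * n_neg)


@dataclass
class NodeClassifier:
    """Linear decision function for one taxonomy node."""

    node_code: str
    weights: np.ndarray
    bias: float
    C: float
    class_weights: Tuple[float, float]

    def decision(self, columns) -> float:
        """Signed decision value for a sparse binary vector (active cols)."""
        cols = list(columns)
        return float(self.weights[cols].sum() + self.bias) if cols else float(self.bias)

    def predict(self, columns) -> bool:
        return self.decision(columns) > 0.0


def _fit_linear(X, y: np.ndarray, C: float, seed: int) -> Tuple[np.ndarray, float]:
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if X.shape[1] == 0:
        # Degenerate space (every candidate filtered): constant majority vote.
        return np.zeros(0), (1.0 if n_pos > n_neg else -1.0)
    w_pos, w_neg = compute_class_weights(n_pos, n_neg)
    clf = LinearSVC(
        C=C,
        class_weight={1: w_pos, 0: w_neg},
        dual=False,
        tol=1e-4,
        max_iter=5000,
        random_state=seed,
    )
    clf.fit(X, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def train_node(
    sentences: Sequence[SentenceRecord],
    code: str,
    space: FeatureSpace,
    extractor: FeatureExtractor,
    taxonomy: Taxonomy,
    C: float = 1.0,
    seed: int = 0,
) -> NodeClassifier:
    """Fit one node's classifier on the whole corpus.

    Positives are sentences whose closed gold set contains ``code``; every
    other sentence is a negative.
    """
    vectors = [vectorize(s, space, extractor) for s in sentences]
    X = build_matrix(vectors)
    y = np.array(
        [code in closure_labels(s.gold_labels, taxonomy) for s in sentences],
        dtype=np.int64,
    )
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"class {code} is single-class; cannot train")
    n_pos = int(y.sum())
    weights, bias = _fit_linear(X, y, C, seed)
    return NodeClassifier(
        node_code=code,
        weights=weights,
        bias=bias,
        C=C,
        class_weights=compute_class_weights(n_pos, len(y) - n_pos),
    )


def postprocess(raw: Mapping[str, bool], taxonomy: Taxonomy) -> Set[str]:
    """Parent-favoring top-down resolution of the 37 binary decisions.

    Nodes are visited parents-first; a node survives only if its raw
    prediction is positive and its parent (after resolution) survived.  The
    result always satisfies hierarchy consistency, and the pass is
    idempotent.
    """
    final: Set[str] = set()
    for code in sorted(raw, key=lambda c: (taxonomy.node(c).level if c in taxonomy else 99, c)):
        if not raw[code]:
            continue
        parent = taxonomy.node(code).parent_code if code in taxonomy else None
        if parent is None or parent in final:
            final.add(code)
    return final


@dataclass
class PredictionSet:
    """Raw per-node scores/labels plus the hierarchy-consistent final set."""

    sentence_id: Tuple[str, int]
    scores: Dict[str, float]
    raw_labels: Dict[str, bool]
    final_labels: Set[str]


class ModelBundle:
    """A trained model: taxonomy + per-node feature space and classifier +
    the joint embedding + the full pipeline config."""

    def __init__(
        self,
        taxonomy: Taxonomy,
        spaces: Dict[str, FeatureSpace],
        classifiers: Dict[str, NodeClassifier],
        extractor: FeatureExtractor,
        config: PipelineConfig,
        embedding: Optional[EmbeddingModel] = None,
    ):
        if set(spaces) != set(taxonomy.codes) or set(classifiers) != set(taxonomy.codes):
            raise ValueError("bundle must carry one space and classifier per node")
        self.taxonomy = taxonomy
        self.spaces = spaces
        self.classifiers = classifiers
        self.extractor = extractor
        self.config = config
        self.embedding = embedding

    def predict_raw(self, s: SentenceRecord) -> Tuple[Dict[str, float], Dict[str, bool]]:
        scores: Dict[str, float] = {}
        labels: Dict[str, bool] = {}
        base = self.extractor.base_keys(s)
        for code, clf in self.classifiers.items():
            space = self.spaces[code]
            keys = set(base)
            if "SD" in self.extractor.kinds and self.extractor.embedding is not None:
                from .features import extract_semantic_distance

                keys |= extract_semantic_distance(
                    s, self.extractor.embedding, code, self.extractor.sd_bins,
                    self.extractor.stopwords,
                )
            vec = vectorize(s, space, self.extractor, keys=keys)
            scores[code] = clf.decision(vec.columns)
            labels[code] = scores[code] > 0.0
        return scores, labels

    def predict(self, s: SentenceRecord) -> PredictionSet:
        scores, raw = self.predict_raw(s)
        return PredictionSet(
            sentence_id=s.sentence_id,
            scores=scores,
            raw_labels=raw,
            final_labels=postprocess(raw, self.taxonomy),
        )

    # ---------------------------------------------------------- persistence

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        self.taxonomy.to_tsv(os.path.join(directory, "taxonomy.tsv"))
        manifest = {
            "config": self.config.to_dict(),
            "segmenter": "hocmine-regex-segmenter/1",
            "lemmatizer": "hocmine-lowercase-lemmatizer/1",
            "nodes": sorted(self.classifiers),
        }
        blob = json.dumps(manifest, sort_keys=True).encode()
        manifest["config_hash"] = hashlib.sha256(blob).hexdigest()
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)
        nodes_dir = os.path.join(directory, "nodes")
        os.makedirs(nodes_dir, exist_ok=True)
        for code, space in self.spaces.items():
            safe = code.replace(".", "_")
            space.to_json(os.path.join(nodes_dir, f"{safe}.space.json"))
            clf = self.classifiers[code]
            np.save(os.path.join(nodes_dir, f"{safe}.weights.npy"), clf.weights)
            with open(os.path.join(nodes_dir, f"{safe}.meta.json"), "w") as fh:
                json.dump(
                    {
                        "node_code": code,
                        "bias": clf.bias,
                        "C": clf.C,
                        "class_weights": list(clf.class_weights),
                    },
                    fh,
                )
        if self.embedding is not None:
            self.embedding.save(os.path.join(directory, "embedding"))

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        taxonomy = Taxonomy.from_tsv(os.path.join(directory, "taxonomy.tsv"))
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        config = PipelineConfig.from_dict(manifest["config"])
        embedding = None
        emb_dir = os.path.join(directory, "embedding")
        if os.path.isdir(emb_dir):
            embedding = EmbeddingModel.load(emb_dir)
        spaces: Dict[str, FeatureSpace] = {}
        classifiers: Dict[str, NodeClassifier] = {}
        nodes_dir = os.path.join(directory, "nodes")
        for code in manifest["nodes"]:
            safe = code.replace(".", "_")
            space = FeatureSpace.from_json(os.path.join(nodes_dir, f"{safe}.space.json"))
            weights = np.load(os.path.join(nodes_dir, f"{safe}.weights.npy"))
            with open(os.path.join(nodes_dir, f"{safe}.meta.json")) as fh:
                meta = json.load(fh)
            spaces[code] = space
            classifiers[code] = NodeClassifier(
                node_code=code,
                weights=weights,
                bias=meta["bias"],
                C=meta["C"],
                class_weights=tuple(meta["class_weights"]),
            )
        extractor = FeatureExtractor(
            kinds=config.feature_kinds, embedding=embedding, sd_bins=config.sd_bins
        )
        return cls(taxonomy, spaces, classifiers, extractor, config, embedding)


def train_bundle(
    sentences: Sequence[SentenceRecord],
    taxonomy: Taxonomy,
    config: PipelineConfig = PipelineConfig(),
    per_node_C: Optional[Mapping[str, float]] = None,
) -> ModelBundle:
    """Per-node feature selection + training over the whole taxonomy.

    Trains the joint embedding first when SD features are enabled.  Nodes
    with no closed positives are reported together in one error.
    """
    closed_sets = [closure_labels(s.gold_labels, taxonomy) for s in sentences]
    missing = [
        code
        for code in taxonomy.codes
        if not any(code in closed for closed in closed_sets)
    ]
    if missing:
        raise ValueError(f"no positive sentences for nodes: {', '.join(missing)}")

    embedding = None
    if "SD" in config.feature_kinds:
        emb_config = EmbeddingConfig(
            **{**asdict(config.embedding), "seed": config.embedding.seed or config.seed}
        )
        embedding = train_embedding(sentences, taxonomy, emb_config)
    extractor = FeatureExtractor(
        kinds=config.feature_kinds, embedding=embedding, sd_bins=config.sd_bins
    )

    base_keys = [extractor.base_keys(s) for s in sentences]
    spaces: Dict[str, FeatureSpace] = {}
    classifiers: Dict[str, NodeClassifier] = {}
    for code in taxonomy.codes:
        if "SD" in extractor.kinds and embedding is not None:
            from .features import extract_semantic_distance

            key_sets = [
                keys
                | extract_semantic_distance(
                    s, embedding, code, config.sd_bins, extractor.stopwords
                )
                for s, keys in zip(sentences, base_keys)
            ]
        else:
            key_sets = base_keys
        space = select_features(
            sentences,
            code,
            taxonomy,
            extractor,
            min_count=config.min_count,
            max_count=config.max_count,
            key_sets=key_sets,
        )
        X = build_matrix(
            [vectorize(s, space, extractor, keys=k) for s, k in zip(sentences, key_sets)]
        )
        y = np.array([code in closed for closed in closed_sets], dtype=np.int64)
        C = per_node_C.get(code, config.C) if per_node_C else config.C
        weights, bias = _fit_linear(X, y, C, config.seed)
        n_pos = int(y.sum())
        spaces[code] = space
        classifiers[code] = NodeClassifier(
            node_code=code,
            weights=weights,
            bias=bias,
            C=C,
            class_weights=compute_class_weights(n_pos, len(y) - n_pos),
        )
        logger.info("trained node %s: %d features, %d positives", code, space.dimension, n_pos)
    return ModelBundle(taxonomy, spaces, classifiers, extractor, config, embedding)
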