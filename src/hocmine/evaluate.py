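"""Intrinsic evaluation: nested cross-validation, P/R/F1/accuracy with
macro and micro averaging, leave-one-out feature ablation, and Cohen's κ.

The evaluation protocol is 4-fold outer cross-validation (train on 75%,
test on 25%, rotated) with 5-fold inner cross-validation inside each outer
training split to select the SVM regularization constant per node.  Folds
are grouped by abstract so sentences from one abstract never straddle a
train/test boundary.

Metrics are reported in percent, per node and as a macro average (the
unweighted mean of per-node values) and a micro average (metrics of the
pooled confusion counts over nodes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .classify import (
    PipelineConfig,
    closure_labels,
    postprocess,
    _fit_linear,
)
from .corpus_io import SentenceRecord
from .embedding import EmbeddingConfig, train_embedding
from .features import (
    EmptyClassError,
    FeatureExtractor,
    build_matrix,
    extract_semantic_distance,
    select_features,
    vectorize,
)
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvalReport",
    "prf_accuracy",
    "macro_micro",
    "nested_cv",
    "ablate_features",
    "cohen_kappa",
    "KappaReport",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def add(self, other: "ConfusionCounts") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.tn += other.tn
        self.fn += other.fn


@dataclass
class Metrics:
    """Precision/recall/F1/accuracy in percent.

    A ratio with a zero denominator is reported as 0 and flagged in
    ``undefined`` rather than raising.
    """

    precision: float
    recall: float
    f1: float
    accuracy: float
    undefined: Tuple[str, ...] = ()


def prf_accuracy(c: ConfusionCounts) -> Metrics:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN), Accuracy = (TP+TN)/total,
    F1 = 2PR/(P+R), all in percent."""
    undefined: List[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return 100.0 * num / den

    p = ratio(c.tp, c.tp + c.fp, "precision")
    r = ratio(c.tp, c.tp + c.fn, "recall")
    a = ratio(c.tp + c.tn, c.total, "accuracy")
    if p + r == 0.0:
        undefined.append("f1")
        f = 0.0
    else:
        f = 2.0 * p * r / (p + r)
    return Metrics(precision=p, recall=r, f1=f, accuracy=a, undefined=tuple(undefined))


def f1_from_percent(precision: float, recall: float) -> float:
    """F1 (percent) from precision and recall already expressed in percent."""
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    per_node_counts: Dict[str, ConfusionCounts]
    per_node_metrics: Dict[str, Metrics]
    macro: Metrics
    micro: Metrics
    fold_plan: Dict[str, object] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    selected_C: Dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code, m in self.per_node_metrics.items():
            c = self.per_node_counts[code]
            rows.append(
                {
                    "node": code,
                    "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
                    "precision": round(m.precision, 1),
                    "recall": round(m.recall, 1),
                    "f1": round(m.f1, 1),
                    "accuracy": round(m.accuracy, 1),
                }
            )
        for name, m in (("Macro-average", self.macro), ("Micro-average", self.micro)):
            rows.append(
                {
                    "node": name,
                    "tp": "", "fp": "", "tn": "", "fn": "",
                    "precision": round(m.precision, 1),
                    "recall": round(m.recall, 1),
                    "f1": round(m.f1, 1),
                    "accuracy": round(m.accuracy, 1),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def macro_micro(per_node: Mapping[str, ConfusionCounts]) -> EvalReport:
    """Macro = unweighted mean of per-node metrics; micro = metrics of the
    summed counts."""
    if not per_node:
        raise ValueError("no nodes to aggregate")
    metrics = {code: prf_accuracy(c) for code, c in per_node.items()}
    macro = Metrics(
        precision=float(np.mean([m.precision for m in metrics.values()])),
        recall=float(np.mean([m.recall for m in metrics.values()])),
        f1=float(np.mean([m.f1 for m in metrics.values()])),
        accuracy=float(np.mean([m.accuracy for m in metrics.values()])),
    )
    pooled = ConfusionCounts()
    for c in per_node.values():
        pooled.add(c)
    return EvalReport(
        per_node_counts=dict(per_node),
        per_node_metrics=metrics,
        macro=macro,
        micro=prf_accuracy(pooled),
    )


def macro_of_table(table: pd.DataFrame) -> Metrics:
    """Unweighted column means of a per-node metric table (percent values).

    Used to recompute a published macro-average row from its printed
    per-node rows.
    """
    return Metrics(
        precision=float(table["precision"].mean()),
        recall=float(table["recall"].mean()),
        f1=float(table["f1"].mean()),
        accuracy=float(table["accuracy"].mean()),
    )


# ------------------------------------------------------------------ folding


def _group_folds(
    sentences: Sequence[SentenceRecord], k: int, seed: int
) -> np.ndarray:
    """Abstract-grouped fold assignment: all sentences of a PMID share a
    fold; PMIDs are shuffled then dealt round-robin."""
    pmids = sorted({s.pmid for s in sentences})
    rng = np.random.default_rng(seed)
    rng.shuffle(pmids)
    fold_of_pmid = {pmid: i % k for i, pmid in enumerate(pmids)}
    return np.array([fold_of_pmid[s.pmid] for s in sentences], dtype=np.int64)


def _node_key_sets(sentences, base_keys, extractor, code):
    if "SD" in extractor.kinds and extractor.embedding is not None:
        return [
            keys
            | extract_semantic_distance(
                s, extractor.embedding, code, extractor.sd_bins, extractor.stopwords
            )
            for s, keys in zip(sentences, base_keys)
        ]
    return base_keys


def _pooled_f1(counts: ConfusionCounts) -> float:
    return prf_accuracy(counts).f1


def nested_cv(
    sentences: Sequence[SentenceRecord],
    taxonomy: Taxonomy,
    config: PipelineConfig = PipelineConfig(),
    codes: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Outer-K (default 4) nested cross-validation with inner-K (default 5)
    model selection of C per node by pooled inner F1.

    Outer test predictions are post-processed (parent-favoring) across all
    nodes, pooled across folds, and scored against closed gold labels.
    Nodes with too few positives in some training split are excluded with a
    warning recorded in the report.
    """
    codes = list(codes) if codes is not None else taxonomy.codes
    closed_sets = [closure_labels(s.gold_labels, taxonomy) for s in sentences]
    outer = _group_folds(sentences, config.outer_folds, config.seed)

    per_node = {code: ConfusionCounts() for code in codes}
    warnings: List[str] = []
    excluded: Set[str] = set()
    selected_C: Dict[str, List[float]] = {code: [] for code in codes}

    for fold in range(config.outer_folds):
        train_idx = np.flatnonzero(outer != fold)
        test_idx = np.flatnonzero(outer == fold)
        train_sents = [sentences[i] for i in train_idx]
        test_sents = [sentences[i] for i in test_idx]
        train_closed = [closed_sets[i] for i in train_idx]
        test_closed = [closed_sets[i] for i in test_idx]

        embedding = None
        if "SD" in config.feature_kinds:
            emb_cfg = EmbeddingConfig(
                **{
                    **config.embedding.__dict__,
                    "seed": (config.embedding.seed or config.seed) + fold + 1,
                }
            )
            embedding = train_embedding(train_sents, taxonomy, emb_cfg)
        extractor = FeatureExtractor(
            kinds=config.feature_kinds, embedding=embedding, sd_bins=config.sd_bins
        )
        train_base = [extractor.base_keys(s) for s in train_sents]
        test_base = [extractor.base_keys(s) for s in test_sents]
        inner = _group_folds(train_sents, config.inner_folds, config.seed + 1000 * (fold + 1))

        raw_by_sentence: List[Dict[str, bool]] = [dict() for _ in test_sents]
        for code in codes:
            y_train = np.array([code in c for c in train_closed], dtype=np.int64)
            if y_train.sum() == 0 or y_train.sum() == len(y_train):
                warnings.append(
                    f"node {code}: single-class training data in outer fold {fold}; excluded"
                )
                excluded.add(code)
                continue
            train_keys = _node_key_sets(train_sents, train_base, extractor, code)
            test_keys = _node_key_sets(test_sents, test_base, extractor, code)
            try:
                space = select_features(
                    train_sents,
                    code,
                    taxonomy,
                    extractor,
                    min_count=config.min_count,
                    max_count=config.max_count,
                    key_sets=train_keys,
                )
            except EmptyClassError as exc:
                warnings.append(f"node {code}: {exc}; excluded")
                excluded.add(code)
                continue
            X_train = build_matrix(
                [vectorize(s, space, extractor, keys=k) for s, k in zip(train_sents, train_keys)]
            )
            X_test = build_matrix(
                [vectorize(s, space, extractor, keys=k) for s, k in zip(test_sents, test_keys)]
            )

            best_C = config.C_grid[0]
            if len(config.C_grid) > 1:
                best_f1 = -1.0
                for C in config.C_grid:
                    pooled = ConfusionCounts()
                    for ifold in range(config.inner_folds):
                        tr = np.flatnonzero(inner != ifold)
                        va = np.flatnonzero(inner == ifold)
                        y_tr = y_train[tr]
                        if y_tr.sum() == 0 or y_tr.sum() == len(y_tr):
                            continue
                        w, b = _fit_linear(X_train[tr], y_tr, C, config.seed)
                        pred = (X_train[va] @ w + b) > 0
                        gold = y_train[va].astype(bool)
                        pooled.add(
                            ConfusionCounts(
                                tp=int((pred & gold).sum()),
                                fp=int((pred & ~gold).sum()),
                                tn=int((~pred & ~gold).sum()),
                                fn=int((~pred & gold).sum()),
                            )
                        )
                    f1 = _pooled_f1(pooled)
                    if f1 > best_f1 + 1e-12:
                        best_f1, best_C = f1, C
            selected_C[code].append(best_C)

            w, b = _fit_linear(X_train, y_train, best_C, config.seed)
            raw = (X_test @ w + b) > 0
            for i, value in enumerate(raw):
                raw_by_sentence[i][code] = bool(value)

        for i, raw in enumerate(raw_by_sentence):
            final = postprocess(raw, taxonomy)
            gold = test_closed[i]
            for code in raw:
                predicted = code in final
                actual = code in gold
                c = per_node[code]
                if predicted and actual:
                    c.tp += 1
                elif predicted:
                    c.fp += 1
                elif actual:
                    c.fn += 1
                else:
                    c.tn += 1

    kept = {code: c for code, c in per_node.items() if code not in excluded}
    if not kept:
        raise ValueError("all nodes were excluded; corpus too small for nested CV")
    report = macro_micro(kept)
    report.warnings = warnings
    report.fold_plan = {
        "outer_folds": config.outer_folds,
        "inner_folds": config.inner_folds,
        "seed": config.seed,
        "grouping": "abstract",
        "C_grid": list(config.C_grid),
    }
    report.selected_C = {
        code: float(np.median(cs)) for code, cs in selected_C.items() if cs
    }
    return report


def ablate_features(
    sentences: Sequence[SentenceRecord],
    taxonomy: Taxonomy,
    config: PipelineConfig = PipelineConfig(),
    kinds: Optional[Sequence[str]] = None,
) -> Dict[str, Dict[str, float]]:
    """Leave-one-out feature analysis.

    Runs nested CV once with the full feature set and once per feature kind
    with that kind removed, all with identical (seeded) fold assignments.
    Returns ``{kind: {"macro_f1": ..., "delta": full - without}}`` plus a
    ``"FULL"`` entry; a positive delta means the kind helps.
    """
    kinds = list(kinds) if kinds is not None else list(config.feature_kinds)
    full = nested_cv(sentences, taxonomy, config)
    results: Dict[str, Dict[str, float]] = {
        "FULL": {"macro_f1": full.macro.f1, "delta": 0.0}
    }
    for kind in kinds:
        reduced_cfg = replace(
            config, feature_kinds=tuple(k for k in config.feature_kinds if k != kind)
        )
        report = nested_cv(sentences, taxonomy, reduced_cfg)
        results[kind] = {
            "macro_f1": report.macro.f1,
            "delta": full.macro.f1 - report.macro.f1,
        }
    return results


# -------------------------------------------------------------------- kappa


@dataclass
class KappaReport:
    per_node: Dict[str, float]
    mean: float
    excluded: List[str]


def cohen_kappa(
    a: Sequence[Set[str]],
    b: Sequence[Set[str]],
    nodes: Sequence[str],
) -> KappaReport:
    """Mean per-node binary Cohen's κ between two annotators.

    κ = (p_o - p_e) / (1 - p_e) per node over the shared sentence inventory;
    nodes on which both annotators are constant (p_e = 1) are flagged and
    excluded from the mean.
    """
    if len(a) != len(b):
        raise ValueError("annotator label sequences differ in length")
    if not a:
        raise ValueError("empty sentence inventory")
    n = len(a)
    per_node: Dict[str, float] = {}
    excluded: List[str] = []
    for code in nodes:
        va = np.array([code in labels for labels in a])
        vb = np.array([code in labels for labels in b])
        po = float((va == vb).mean())
        pa, pb = float(va.mean()), float(vb.mean())
        pe = pa * pb + (1 - pa) * (1 - pb)
        if pe >= 1.0 - 1e-15:
            excluded.append(code)
            continue
        per_node[code] = (po - pe) / (1 - pe)
    if not per_node:
        raise ValueError("all nodes degenerate; kappa undefined")
    return KappaReport(
        per_node=per_node,
        mean=float(np.mean(list(per_node.values()))),
        excluded=excluded,
    )
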