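"""Supervised link prediction on entity embeddings.

Positive (drug, target) or (drug, disease) pairs are balanced with uniformly
sampled negatives, split 80/20, featurized as the drug embedding concatenated
with the candidate embedding, and scored by one of four classifiers: an ANN
(one hidden layer of twice the input width), a random forest (50 trees),
L2-regularized logistic regression (C = 10), or a Siamese network.
Evaluation reports AUROC, AUPR, per-drug recall and per-drug candidate
rankings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from ._nn import MLPBinaryClassifier, SiameseBinaryClassifier
from .vectors import EmbeddingTable

Pair = tuple[str, str]


@dataclass
class PairDataset:
    """Labeled (drug, candidate) pairs; ``split`` tags train vs test."""

    pairs: list[tuple[str, str, int]]
    split: str = "train"

    def __post_init__(self) -> None:
        by_label: dict[Pair, set[int]] = {}
        for d, c, y in self.pairs:
            by_label.setdefault((d, c), set()).add(y)
        clashes = [p for p, labels in by_label.items() if len(labels) > 1]
        if clashes:
            raise ValueError(f"pairs with both labels: {clashes[:3]}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def positives(self) -> list[Pair]:
        return [(d, c) for d, c, y in self.pairs if y == 1]

    @property
    def negatives(self) -> list[Pair]:
        return [(d, c) for d, c, y in self.pairs if y == 0]

    def labels(self) -> np.ndarray:
        return np.array([y for _, _, y in self.pairs], dtype=np.int64)


@dataclass
class ClassifierSpec:
    """Classifier kind plus the hyperparameters the pipeline fixes.

    Defaults follow the published settings: ann = single hidden layer of
    twice the input width (ReLU, sigmoid output, cross-entropy, RMSprop);
    rf = 50 trees, Gini impurity, min 1 sample per leaf; lr = L2 penalty with
    C = 10.  The siamese encoder depth/merge are open choices: one shared
    dense layer per tower with absolute-difference merge.
    """

    kind: str = "ann"
    seed: int = 0
    ann_epochs: int = 100
    ann_batch_size: int = 128
    ann_lr: float = 1e-3
    rf_trees: int = 50
    lr_C: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("ann", "rf", "lr", "siamese"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


def select_entity_pool(
    kg_vocab: Iterable[str],
    text_vocab: Iterable[str],
    mode: str = "overlap",
    *,
    restrict_to: Iterable[str] | None = None,
) -> set[str]:
    """Entity pool used for evaluation: overlap/union/single-modality vocabularies.

    ``restrict_to`` limits the result to the evaluation entity types (e.g.,
    the drugs and targets of the benchmark).
    """
    kg_vocab, text_vocab = set(kg_vocab), set(text_vocab)
    if mode == "overlap":
        pool = kg_vocab & text_vocab
    elif mode == "union":
        pool = kg_vocab | text_vocab
    elif mode == "kg_only":
        pool = kg_vocab
    elif mode == "text_only":
        pool = text_vocab
    else:
        raise ValueError(f"unknown pool mode {mode!r}")
    if restrict_to is not None:
        pool &= set(restrict_to)
    return pool


def build_pair_dataset(
    positives: Iterable[Pair],
    drug_pool: Iterable[str],
    candidate_pool: Iterable[str],
    *,
    ratio: float = 1.0,
    seed: int = 0,
    test_fraction: float = 0.2,
) -> tuple[PairDataset, PairDataset]:
    """Balance positives with sampled negatives and split 80/20.

    Negatives are drawn uniformly without replacement from
    (drug_pool x candidate_pool) \\ positives, once per experiment, before the
    random train/test split — so negatives are shared consistently across
    classifiers and the two splits are disjoint.
    """
    drug_pool = sorted(set(drug_pool))
    candidate_pool = sorted(set(candidate_pool))
    pos = sorted({(d, c) for d, c in positives if d in set(drug_pool) and c in set(candidate_pool)})
    if not pos:
        raise ValueError("no positives fall inside the supplied pools")
    n_neg = round(ratio * len(pos))
    space = len(drug_pool) * len(candidate_pool) - len(pos)
    if space < n_neg:
        raise ValueError(
            f"negative space too small: need {n_neg}, only {space} non-positive pairs exist"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    pos_set = set(pos)
    negatives: set[Pair] = set()
    # rejection-sample flat indices of the drug x candidate grid
    while len(negatives) < n_neg:
        draw = rng.integers(len(drug_pool) * len(candidate_pool), size=2 * (n_neg - len(negatives)) + 8)
        for flat in draw:
            pair = (drug_pool[flat // len(candidate_pool)], candidate_pool[flat % len(candidate_pool)])
            if pair in pos_set or pair in negatives:
                continue
            negatives.add(pair)
            if len(negatives) == n_neg:
                break
    labeled = [(d, c, 1) for d, c in pos] + [(d, c, 0) for d, c in sorted(negatives)]
    order = rng.permutation(len(labeled))
    n_test = round(test_fraction * len(labeled))
    test_idx = set(order[:n_test].tolist())
    train = [labeled[i] for i in range(len(labeled)) if i not in test_idx]
    test = [labeled[i] for i in sorted(test_idx)]
    return PairDataset(train, "train"), PairDataset(test, "test")


def make_features(pair: Pair, embeddings: EmbeddingTable, *, zero_fill: bool = False) -> np.ndarray:
    """Drug embedding concatenated with the candidate embedding (drug first)."""
    vecs = []
    for entity in pair:
        v = embeddings.get(entity)
        if v is None:
            if not zero_fill:
                raise KeyError(f"entity {entity!r} has no embedding (use zero_fill)")
            v = np.zeros(embeddings.dim)
        vecs.append(v)
    return np.concatenate(vecs)


def _feature_matrix(pairs: Sequence[Pair], embeddings: EmbeddingTable, zero_fill: bool) -> np.ndarray:
    return np.stack([make_features(p, embeddings, zero_fill=zero_fill) for p in pairs])


class FittedPairClassifier:
    """A trained classifier exposing per-pair confidence scores in [0, 1]."""

    def __init__(self, spec: ClassifierSpec, model, embeddings: EmbeddingTable, zero_fill: bool):
        self.spec = spec
        self.model = model
        self.embeddings = embeddings
        self.zero_fill = zero_fill

    def score_pairs(self, pairs: Sequence[Pair]) -> np.ndarray:
        X = _feature_matrix(pairs, self.embeddings, self.zero_fill)
        if hasattr(self.model, "predict_proba"):
            proba = self.model.predict_proba(X)
            if proba.ndim == 2:  # sklearn returns (n, 2)
                proba = proba[:, 1]
            return proba
        raise TypeError("underlying model lacks predict_proba")  # pragma: no cover

    @property
    def hidden_width(self) -> int | None:
        return getattr(self.model, "hidden_width", None)


def train_classifier(
    spec: ClassifierSpec,
    train: PairDataset,
    embeddings: EmbeddingTable,
    *,
    zero_fill: bool = False,
) -> FittedPairClassifier:
    """Fit the requested classifier on featurized training pairs."""
    if len(train) == 0:
        raise ValueError("empty training set")
    y = train.labels()
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = _feature_matrix([(d, c) for d, c, _ in train.pairs], embeddings, zero_fill)
    if spec.kind == "ann":
        model = MLPBinaryClassifier(
            epochs=spec.ann_epochs, batch_size=spec.ann_batch_size, lr=spec.ann_lr, seed=spec.seed
        ).fit(X, y)
    elif spec.kind == "siamese":
        model = SiameseBinaryClassifier(
            epochs=spec.ann_epochs, batch_size=spec.ann_batch_size, lr=spec.ann_lr, seed=spec.seed
        ).fit(X, y)
    elif spec.kind == "rf":
        model = RandomForestClassifier(
            n_estimators=spec.rf_trees,
            criterion="gini",
            min_samples_leaf=1,
            random_state=spec.seed,
        ).fit(X, y)
    else:  # lr
        # l1_ratio=0 is a pure L2 penalty (sklearn's current spelling of penalty="l2")
        model = LogisticRegression(
            l1_ratio=0.0, C=spec.lr_C, max_iter=2000, random_state=spec.seed
        ).fit(X, y)
    return FittedPairClassifier(spec, model, embeddings, zero_fill)


@dataclass
class EvalReport:
    auroc: float
    aupr: float
    per_drug_recall: dict[str, float]
    macro_recall: float
    rankings: dict[str, list[tuple[str, float, int]]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "macro_recall": self.macro_recall,
            "per_drug_recall": self.per_drug_recall,
        }


def evaluate(
    model: FittedPairClassifier,
    test: PairDataset,
    *,
    threshold: float = 0.5,
    recall_at_k: int | None = None,
) -> EvalReport:
    """Score the held-out pairs and compute AUROC/AUPR and per-drug recall.

    AUROC counts tied scores with half credit; AUPR is the step-wise
    integration of the precision-recall curve.  Per-drug recall is the
    fraction of a drug's test positives scoring >= ``threshold`` (or, with
    ``recall_at_k``, ranked in the drug's top k), macro-averaged over drugs
    with at least one test positive.
    """
    y = test.labels()
    if len(np.unique(y)) < 2:
        raise ValueError("test set must contain both classes for AUROC")
    pairs = [(d, c) for d, c, _ in test.pairs]
    scores = model.score_pairs(pairs)
    auroc = float(roc_auc_score(y, scores))
    aupr = float(average_precision_score(y, scores))

    by_drug: dict[str, list[tuple[str, float, int]]] = {}
    for (d, c), s, label in zip(pairs, scores, y):
        by_drug.setdefault(d, []).append((c, float(s), int(label)))

    per_drug_recall: dict[str, float] = {}
    rankings: dict[str, list[tuple[str, float, int]]] = {}
    for drug, entries in by_drug.items():
        ranked = sorted(entries, key=lambda e: (-e[1], e[0]))
        rankings[drug] = ranked
        positives = [e for e in entries if e[2] == 1]
        if not positives:
            continue
        if recall_at_k is not None:
            top = {c for c, _, _ in ranked[:recall_at_k]}
            hit = sum(1 for c, _, _ in positives if c in top)
        else:
            hit = sum(1 for _, s, _ in positives if s >= threshold)
        per_drug_recall[drug] = hit / len(positives)
    macro = float(np.mean(list(per_drug_recall.values()))) if per_drug_recall else float("nan")
    return EvalReport(auroc, aupr, per_drug_recall, macro, rankings)


def rank_candidates(
    model: FittedPairClassifier,
    drug: str,
    candidates: Sequence[str],
    *,
    known_positives: Iterable[str] = (),
) -> tuple[list[tuple[str, float]], dict[str, int]]:
    """Rank candidate entities for one drug by descending confidence.

    Ties break lexicographically by IRI for determinism.  Returns the ordered
    (candidate, score) list and the 1-based rank of each supplied known
    positive.
    """
    scores = model.score_pairs([(drug, c) for c in candidates])
    ranked = sorted(zip(candidates, scores), key=lambda e: (-e[1], e[0]))
    positions = {c: i + 1 for i, (c, _) in enumerate(ranked)}
    pos_ranks = {c: positions[c] for c in known_positives if c in positions}
    return [(c, float(s)) for c, s in ranked], pos_ranks


def load_benchmark_pairs(
    path,
    id_map: Mapping[str, str] | None = None,
) -> tuple[set[Pair], int]:
    """Load a two-column gold-standard interaction list (Yamanishi style).

    ``id_map`` optionally translates first-column IDs (e.g., KEGG drug IDs to
    PubChem CIDs); rows whose drug ID cannot be mapped are excluded and
    counted.  Returns (distinct mapped pairs, number of unmappable rows).
    """
    pairs: set[Pair] = set()
    unmapped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            drug, target = fields[0].strip(), fields[1].strip()
            if id_map is not None:
                mapped = id_map.get(drug)
                if mapped is None:
                    unmapped += 1
                    continue
                drug = mapped
            pairs.add((drug, target))
    if unmapped:
        warnings.warn(f"{path}: {unmapped} rows with unmappable drug IDs", stacklevel=2)
    return pairs, unmapped
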