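"""TransE translational knowledge-graph embeddings.

A triple (s, p, o) is scored by the distance d(s + p, o) under the L1 or L2
norm; training minimizes the margin ranking loss

    L = sum over positives and their corruptions of
        max(0, gamma + d(s + p, o) - d(s' + p, o'))

where a corrupted triple replaces the head or the tail (coin flip) with a
uniformly random entity.  Entity vectors are renormalized to unit L2 norm
every epoch, as in the original TransE protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .kg import Triple
from .vectors import EmbeddingTable


@dataclass
class TransEConfig:
    dimension: int = 128
    margin: float = 1.0
    norm: str = "L1"  # L1 | L2
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 64
    negatives_per_positive: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if self.norm not in ("L1", "L2"):
            raise ValueError("norm must be 'L1' or 'L2'")


@dataclass
class TransEModel:
    entities: list[str]
    relations: list[str]
    entity_vectors: np.ndarray
    relation_vectors: np.ndarray
    config: TransEConfig
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._ent_index = {e: i for i, e in enumerate(self.entities)}
        self._rel_index = {r: i for i, r in enumerate(self.relations)}

    def entity_table(self) -> EmbeddingTable:
        return EmbeddingTable(self.entities, self.entity_vectors)

    def relation_table(self) -> EmbeddingTable:
        return EmbeddingTable(self.relations, self.relation_vectors)

    def entity_id(self, iri: str) -> int:
        return self._ent_index[iri]

    def relation_id(self, name: str) -> int:
        return self._rel_index[name]


def _distance(diff: np.ndarray, norm: str) -> np.ndarray:
    if norm == "L1":
        return np.abs(diff).sum(axis=-1)
    return np.sqrt((diff ** 2).sum(axis=-1))


def transe_score(model: TransEModel, s: str, p: str, o: str) -> float:
    """d(s + p, o) under the configured norm; 0 when the translation is exact."""
    diff = (
        model.entity_vectors[model.entity_id(s)]
        + model.relation_vectors[model.relation_id(p)]
        - model.entity_vectors[model.entity_id(o)]
    )
    return float(_distance(diff, model.config.norm))


def transe_loss(
    model: TransEModel,
    positives: Sequence[Triple],
    negatives: Sequence[Triple],
) -> float:
    """Margin ranking loss summed over aligned positive/corrupted pairs."""
    if len(positives) != len(negatives):
        raise ValueError(
            f"positives ({len(positives)}) and negatives ({len(negatives)}) must align 1:1"
        )
    gamma = model.config.margin
    total = 0.0
    for pos, neg in zip(positives, negatives):
        d_pos = transe_score(model, *pos)
        d_neg = transe_score(model, *neg)
        total += max(0.0, gamma + d_pos - d_neg)
    return total


def _encode_triples(triples: Iterable[Triple]) -> tuple[list[str], list[str], np.ndarray]:
    triples = list(triples)
    entities = sorted({t.subject for t in triples} | {t.object for t in triples})
    relations = sorted({t.predicate for t in triples})
    ent_index = {e: i for i, e in enumerate(entities)}
    rel_index = {r: i for i, r in enumerate(relations)}
    enc = np.array(
        [(ent_index[t.subject], rel_index[t.predicate], ent_index[t.object]) for t in triples],
        dtype=np.int64,
    )
    return entities, relations, enc


def train_transe(triples: Iterable[Triple], config: TransEConfig) -> TransEModel:
    """Minibatch SGD with uniform head-or-tail corruption.

    Deterministic given the seed; records the per-epoch mean hinge loss in
    ``model.loss_trace``.
    """
    entities, relations, enc = _encode_triples(triples)
    if len(enc) == 0:
        raise ValueError("need at least one triple")
    if len(entities) < 2:
        raise ValueError("need at least two entities to corrupt triples")

    rng = np.random.Generator(np.random.PCG64(config.seed))
    dim = config.dimension
    bound = 6.0 / np.sqrt(dim)
    ent = rng.uniform(-bound, bound, size=(len(entities), dim))
    rel = rng.uniform(-bound, bound, size=(len(relations), dim))
    rel /= np.maximum(np.linalg.norm(rel, axis=1, keepdims=True), 1e-12)

    n = len(enc)
    k = config.negatives_per_positive
    cfg_norm = config.norm
    loss_trace: list[float] = []

    for _epoch in range(config.epochs):
        ent /= np.maximum(np.linalg.norm(ent, axis=1, keepdims=True), 1e-12)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_terms = 0
        for start in range(0, n, config.batch_size):
            batch = enc[order[start:start + config.batch_size]]
            if k > 1:
                batch = np.repeat(batch, k, axis=0)
            s, p, o = batch[:, 0], batch[:, 1], batch[:, 2]
            # corrupt head or tail with a uniformly random entity
            corrupt_head = rng.random(len(batch)) < 0.5
            random_ent = rng.integers(len(entities), size=len(batch))
            s_neg = np.where(corrupt_head, random_ent, s)
            o_neg = np.where(corrupt_head, o, random_ent)

            diff_pos = ent[s] + rel[p] - ent[o]
            diff_neg = ent[s_neg] + rel[p] - ent[o_neg]
            d_pos = _distance(diff_pos, cfg_norm)
            d_neg = _distance(diff_neg, cfg_norm)
            violation = config.margin + d_pos - d_neg
            active = violation > 0
            epoch_loss += float(np.maximum(violation, 0.0).sum())
            n_terms += len(batch)
            if not active.any():
                continue

            if cfg_norm == "L1":
                g_pos = np.sign(diff_pos[active])
                g_neg = np.sign(diff_neg[active])
            else:
                g_pos = diff_pos[active] / np.maximum(d_pos[active, None], 1e-12)
                g_neg = diff_neg[active] / np.maximum(d_neg[active, None], 1e-12)
            lr = config.learning_rate
            # d_pos is pushed down, d_neg pushed up
            np.add.at(ent, s[active], -lr * g_pos)
            np.add.at(ent, o[active], lr * g_pos)
            np.add.at(rel, p[active], -lr * g_pos)
            np.add.at(ent, s_neg[active], lr * g_neg)
            np.add.at(ent, o_neg[active], -lr * g_neg)
            np.add.at(rel, p[active], lr * g_neg)
        loss_trace.append(epoch_loss / max(n_terms, 1))

    ent /= np.maximum(np.linalg.norm(ent, axis=1, keepdims=True), 1e-12)
    return TransEModel(entities, relations, ent, rel, config, loss_trace)


def rank_triples(
    model: TransEModel,
    queries: Sequence[Triple],
    *,
    k: int = 10,
    filtered: bool = False,
    known_triples: Iterable[Triple] = (),
) -> tuple[float, float]:
    """Mean rank of the true object and hits@k over (s, p, ?) queries.

    Every entity is ranked by ascending score as candidate object; with
    ``filtered=True`` other known-true objects are excluded before ranking.
    """
    known: dict[tuple[str, str], set[str]] = {}
    if filtered:
        for t in known_triples:
            known.setdefault((t.subject, t.predicate), set()).add(t.object)

    ranks = []
    for s, p, o in queries:
        si, pi, oi = model.entity_id(s), model.relation_id(p), model.entity_id(o)
        diff = model.entity_vectors[si] + model.relation_vectors[pi] - model.entity_vectors
        scores = _distance(diff, model.config.norm)
        if filtered:
            for other in known.get((s, p), ()):  # keep the query object itself
                if other != o:
                    scores[model.entity_id(other)] = np.inf
        # rank = 1 + number of entities scoring strictly better
        ranks.append(1 + int((scores < scores[oi]).sum()))
    ranks_arr = np.array(ranks, dtype=np.float64)
    return float(ranks_arr.mean()), float((ranks_arr <= k).mean())
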