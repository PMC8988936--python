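"""End-to-end experiment orchestration.

Wires the full method together: remove the evaluation relation from the
graph, walk the residual graph into corpus 1, normalize the abstracts into
corpus 2, train embeddings for the requested modality, build a balanced pair
dataset over the chosen entity pool, fit a classifier and evaluate it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .combine import concat_corpora, concat_embeddings
from .kg import KnowledgeGraph, remove_edges_by_predicate
from .predict import (
    ClassifierSpec,
    EvalReport,
    PairDataset,
    build_pair_dataset,
    evaluate,
    select_entity_pool,
    train_classifier,
)
from .skipgram import SkipGramConfig, train_skipgram
from .textnorm import AnnotatedDocument, IdMap, build_text_corpus
from .transe import TransEConfig, train_transe
from .vectors import EmbeddingTable
from .walks import WalkConfig, WalkCorpus, generate_walks

MODALITIES = ("kg", "text", "joint", "concat", "transe")

_CANDIDATE_TYPE = {"has_target": "gene", "has_indication": "disease"}


@dataclass
class ExperimentResult:
    modality: str
    task: str
    report: EvalReport
    embeddings: EmbeddingTable
    train: PairDataset
    test: PairDataset
    extras: dict = field(default_factory=dict)


def build_modality_embeddings(
    graph: KnowledgeGraph,
    docs: list[AnnotatedDocument],
    id_map: IdMap,
    task: str,
    modality: str,
    *,
    seed: int = 0,
    walk_config: WalkConfig | None = None,
    sg_config: SkipGramConfig | None = None,
    transe_config: TransEConfig | None = None,
) -> tuple[EmbeddingTable, KnowledgeGraph, WalkCorpus | None]:
    """Embeddings for one modality, with the task's edges removed first.

    Returns (embeddings, residual graph, walk corpus or None).  The edge
    removal happens *before* corpus generation, so no embedding can encode
    the links the classifier is later asked to predict.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    residual = remove_edges_by_predicate(graph, task)
    walk_config = walk_config or WalkConfig(seed=seed)
    sg_config = sg_config or SkipGramConfig(seed=seed)

    corpus1: WalkCorpus | None = None
    if modality in ("kg", "joint", "concat"):
        corpus1 = generate_walks(residual, walk_config)
    if modality == "transe":
        transe_config = transe_config or TransEConfig(seed=seed)
        model = train_transe(residual.triples, transe_config)
        return model.entity_table(), residual, None
    if modality == "kg":
        return train_skipgram(corpus1, sg_config), residual, corpus1
    corpus2 = build_text_corpus(docs, id_map)
    if modality == "text":
        return train_skipgram(corpus2, sg_config), residual, None
    if modality == "joint":
        merged = concat_corpora(corpus1, corpus2, seed=seed)
        return train_skipgram(merged, sg_config), residual, corpus1
    # concat: separate trainings, stacked vectors
    e1 = train_skipgram(corpus1, sg_config)
    e2 = train_skipgram(corpus2, sg_config)
    return concat_embeddings(e1, e2, policy="zero_fill"), residual, corpus1


def text_entity_vocabulary(docs: list[AnnotatedDocument], id_map: IdMap) -> set[str]:
    """IRIs actually mentioned (mappably) in the document set."""
    from .textnorm import _mentioned_iris

    vocab: set[str] = set()
    for doc in docs:
        vocab |= _mentioned_iris(doc, id_map)
    return vocab


def run_experiment(
    graph: KnowledgeGraph,
    positives: set[tuple[str, str]],
    docs: list[AnnotatedDocument],
    id_map: IdMap,
    *,
    task: str = "has_target",
    modality: str = "joint",
    classifier: str = "ann",
    pool_mode: str = "overlap",
    seed: int = 0,
    walk_config: WalkConfig | None = None,
    sg_config: SkipGramConfig | None = None,
    transe_config: TransEConfig | None = None,
    negative_ratio: float = 1.0,
    test_fraction: float = 0.2,
    precomputed_embeddings: EmbeddingTable | None = None,
) -> ExperimentResult:
    """Run one full evaluation: embeddings -> balanced pairs -> classifier.

    ``positives`` are the planted (or database) pairs of the ``task``
    relation; the entity pool is selected from the graph vocabulary vs the
    text vocabulary per ``pool_mode`` (the main experiments use the overlap,
    the coverage experiment the union).
    """
    if precomputed_embeddings is not None:
        embeddings = precomputed_embeddings
        residual = remove_edges_by_predicate(graph, task)
        corpus1 = None
    else:
        embeddings, residual, corpus1 = build_modality_embeddings(
            graph,
            docs,
            id_map,
            task,
            modality,
            seed=seed,
            walk_config=walk_config,
            sg_config=sg_config,
            transe_config=transe_config,
        )
    kg_vocab = set(graph.nodes)
    text_vocab = text_entity_vocabulary(docs, id_map)
    candidate_type = _CANDIDATE_TYPE[task]
    pool = select_entity_pool(kg_vocab, text_vocab, pool_mode)
    # only entities with a vector can be featurized without zero-fill
    zero_fill = pool_mode == "union"
    if not zero_fill:
        pool &= embeddings.vocabulary()
    drug_pool = {e for e in pool if graph.nodes.get(e) == "drug"}
    candidate_pool = {e for e in pool if graph.nodes.get(e) == candidate_type}
    train, test = build_pair_dataset(
        positives,
        drug_pool,
        candidate_pool,
        ratio=negative_ratio,
        seed=seed,
        test_fraction=test_fraction,
    )
    spec = ClassifierSpec(kind=classifier, seed=seed)
    model = train_classifier(spec, train, embeddings, zero_fill=zero_fill)
    report = evaluate(model, test)
    return ExperimentResult(
        modality,
        task,
        report,
        embeddings,
        train,
        test,
        extras={
            "residual_graph": residual,
            "walk_corpus": corpus1,
            "drug_pool": drug_pool,
            "candidate_pool": candidate_pool,
            "fitted": model,
        },
    )
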