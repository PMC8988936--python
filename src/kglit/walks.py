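"""Edge-labeled iterated random walks over the knowledge graph (corpus 1).

Every node starts ``num_walks`` walks; each step picks one outgoing
``(predicate, object)`` edge uniformly at random, with no restart.  Walks are
emitted as sentences alternating node and relation tokens, so that skip-gram
sees relations and entities in one shared vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kg import KnowledgeGraph


@dataclass
class WalkConfig:
    """Corpus-generation hyperparameters.

    walk_length counts node visits, so a sentence has at most
    ``2 * walk_length - 1`` tokens with edge labels on.
    """

    walk_length: int = 10
    num_walks: int = 20
    seed: int = 0
    include_edge_labels: bool = True

    def __post_init__(self) -> None:
        if self.walk_length < 1:
            raise ValueError("walk_length must be >= 1")
        if self.num_walks < 1:
            raise ValueError("num_walks must be >= 1")


class WalkCorpus:
    """A list of token sequences (sentences) produced by random walks."""

    def __init__(self, sentences: list[list[str]]):
        self.sentences = sentences

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WalkCorpus):
            return NotImplemented
        return self.sentences == other.sentences

    def num_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


def generate_walks(graph: KnowledgeGraph, config: WalkConfig) -> WalkCorpus:
    """Run ``num_walks`` uniform random walks from every node.

    Deterministic given the seed: nodes are iterated in sorted IRI order and a
    single seeded PCG64 stream drives every edge choice.  A walk reaching a
    sink node ends early; a walk started at a sink emits the single-node
    sentence, so the corpus always has ``num_walks * num_nodes`` sentences.
    """
    if graph.num_nodes() == 0:
        raise ValueError("cannot walk an empty graph")
    rng = np.random.Generator(np.random.PCG64(config.seed))
    # freeze adjacency into arrays for speed and determinism
    adjacency = {node: graph.out_edges(node) for node in sorted(graph.nodes)}
    sentences: list[list[str]] = []
    for node, _ in sorted(adjacency.items()):
        for _ in range(config.num_walks):
            sentence = [node]
            current = node
            for _ in range(config.walk_length - 1):
                edges = adjacency[current]
                if not edges:
                    break
                predicate, obj = edges[rng.integers(len(edges))]
                if config.include_edge_labels:
                    sentence.append(predicate)
                sentence.append(obj)
                current = obj
            sentences.append(sentence)
    return WalkCorpus(sentences)


def validate_corpus(corpus: WalkCorpus, graph: KnowledgeGraph) -> list[tuple[int, int, tuple[str, str, str]]]:
    """Check every consecutive (node, edge, node) window against the graph.

    Returns a list of violations ``(sentence_index, token_offset, window)``;
    empty for any corpus produced by :func:`generate_walks` with edge labels.
    """
    triples = graph.triples
    violations = []
    for i, sentence in enumerate(corpus.sentences):
        for j in range(0, len(sentence) - 2, 2):
            window = (sentence[j], sentence[j + 1], sentence[j + 2])
            if window not in triples:
                violations.append((i, j, window))
    return violations


def write_corpus(corpus: WalkCorpus, path) -> None:
    """One sentence per line, tokens whitespace-separated."""
    with open(path, "w", encoding="utf-8") as fh:
        for sentence in corpus.sentences:
            fh.write(" ".join(sentence) + "\n")


def read_corpus(path) -> WalkCorpus:
    sentences = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                sentences.append(line.split(" "))
    return WalkCorpus(sentences)
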