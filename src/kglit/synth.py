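"""Synthetic knowledge graphs and annotated abstracts with planted links.

A latent-factor world: every entity carries a low-dimensional factor vector,
and *all* relations — the drug-target / drug-indication ground truth as well
as the correlated side relations (side effects, gene-disease associations,
protein-protein interactions, gene functions) — are the top-scoring pairs
under the factor inner product.  Text is generated so that truly linked pairs
co-occur in abstracts ``co_mention_lift`` times more often than unlinked
pairs.  Graph structure and text co-occurrence therefore carry partially
overlapping, partially complementary signal about the planted pairs — the
property the multi-modal method exploits.

Named presets:

* ``default`` — the standard study conditions (200 drugs, 300 genes,
  100 diseases, 2,000 abstracts).
* ``complementary`` — a fraction of drugs have no side edges in the graph
  (recoverable only from text) while a fraction of entities are absent from
  text (recoverable only from the graph).
* ``null`` — no-signal control: side relations are drawn from independent
  factors and ``co_mention_lift = 1``, so nothing predicts the planted pairs
  once the ground-truth edges are removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kg import KnowledgeGraph, Triple, build_graph, remove_edges_by_predicate
from .textnorm import AnnotatedDocument, Annotation, IdMap

_FILLER_LEXICON_SIZE = 500
_MENTIONABLE_TYPES = ("drug", "gene", "disease")


def _default_densities() -> dict[str, float]:
    return {
        "has_target": 0.02,
        "has_indication": 0.03,
        "has_sideeffect": 0.04,
        "has_disease_association": 0.03,
        "has_disease_phenotype": 0.05,
        "has_function": 0.05,
        "interacts_with": 0.01,
    }


@dataclass
class SynthConfig:
    n_drugs: int = 200
    n_genes: int = 300
    n_diseases: int = 100
    n_phenotypes: int = 80
    n_classes: int = 40
    densities: dict[str, float] = field(default_factory=_default_densities)
    n_docs: int = 2000
    co_mention_lift: float = 100.0
    mention_noise: float = 0.05
    text_overlap_fraction: float = 0.9
    latent_dim: int = 8
    graph_poor_drug_fraction: float = 0.0
    #: no-signal control: positives drawn uniformly at random (no latent
    #: structure) and side relations generated from independent factors, so
    #: nothing observable correlates with the planted labels
    null_signal: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_genes", "n_diseases", "n_phenotypes", "n_classes", "n_docs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.co_mention_lift < 1:
            raise ValueError("co_mention_lift must be >= 1")
        for name in ("mention_noise", "text_overlap_fraction", "graph_poor_drug_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def preset(name: str, seed: int = 0) -> SynthConfig:
    """Named study conditions; see the module docstring."""
    base = SynthConfig(seed=seed)
    if name == "default":
        return base
    if name == "complementary":
        return replace(base, text_overlap_fraction=0.7, graph_poor_drug_fraction=0.3)
    if name == "null":
        return replace(base, co_mention_lift=1.0, null_signal=True)
    raise ValueError(f"unknown preset {name!r}")


@dataclass
class GroundTruth:
    """Planted positives plus the latent factors that generated them."""

    has_target: set[tuple[str, str]]
    has_indication: set[tuple[str, str]]
    latents: dict[str, np.ndarray]
    graph_poor_drugs: set[str] = field(default_factory=set)

    def pairs(self, relation: str) -> set[tuple[str, str]]:
        return {"has_target": self.has_target, "has_indication": self.has_indication}[relation]


def _entity_iris(config: SynthConfig) -> dict[str, list[str]]:
    return {
        "drug": [f"stitch:CID{i:06d}" for i in range(config.n_drugs)],
        "gene": [f"entrez:{1000 + i}" for i in range(config.n_genes)],
        "disease": [f"doid:{100 + i}" for i in range(config.n_diseases)],
        "phenotype": [f"hp:{i:07d}" for i in range(config.n_phenotypes)],
        "function_class": [f"go:{i:07d}" for i in range(config.n_classes)],
    }


def _top_pairs(
    za: np.ndarray, zb: np.ndarray, n_edges: int, *, exclude_diagonal: bool = False
) -> list[tuple[int, int]]:
    """Indices of the n_edges largest inner products (brute-force threshold)."""
    scores = za @ zb.T
    if exclude_diagonal:
        np.fill_diagonal(scores, -np.inf)
    flat = scores.ravel()
    if n_edges > (flat > -np.inf).sum():
        raise ValueError(f"density implies {n_edges} edges, pair space is smaller")
    idx = np.argpartition(flat, -n_edges)[-n_edges:]
    # deterministic order: sort by score descending, then index
    idx = idx[np.lexsort((idx, -flat[idx]))]
    return [(int(i // zb.shape[0]), int(i % zb.shape[0])) for i in idx]


def generate_synthetic_kg(config: SynthConfig) -> tuple[KnowledgeGraph, GroundTruth]:
    """Build the typed graph and the planted positive pair sets.

    Edge counts per relation are ``round(density * |A| * |B|)`` and the edges
    are exactly the top-scoring latent-factor pairs, so an independent
    threshold scan over the returned factors reproduces every edge.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    iris = _entity_iris(config)
    k = config.latent_dim
    latents: dict[str, np.ndarray] = {}
    for group in ("drug", "gene", "disease", "phenotype", "function_class"):
        z = rng.normal(size=(len(iris[group]), k)) / math.sqrt(k)
        for iri, vec in zip(iris[group], z):
            latents[iri] = vec

    def z_of(group: str) -> np.ndarray:
        return np.stack([latents[i] for i in iris[group]])

    # independent factors for the side relations in the no-signal control
    if config.null_signal:
        side_latents = {
            group: rng.normal(size=(len(iris[group]), k)) / math.sqrt(k)
            for group in iris
        }

        def z_side(group: str) -> np.ndarray:
            return side_latents[group]
    else:
        z_side = z_of

    def relation_edges(relation, group_a, group_b, za, zb, exclude_diag=False):
        density = config.densities.get(relation, 0.0)
        n_a, n_b = len(iris[group_a]), len(iris[group_b])
        n_edges = round(density * n_a * n_b)
        if n_edges == 0:
            return set()
        pairs = _top_pairs(za, zb, n_edges, exclude_diagonal=exclude_diag)
        return {
            Triple(iris[group_a][i], relation, iris[group_b][j]) for i, j in pairs
        }

    def uniform_edges(relation, group_a, group_b):
        density = config.densities.get(relation, 0.0)
        n_a, n_b = len(iris[group_a]), len(iris[group_b])
        n_edges = round(density * n_a * n_b)
        if n_edges > n_a * n_b:
            raise ValueError(f"density implies {n_edges} edges, pair space is smaller")
        flat = rng.choice(n_a * n_b, size=n_edges, replace=False)
        return {
            Triple(iris[group_a][int(f // n_b)], relation, iris[group_b][int(f % n_b)])
            for f in flat
        }

    if config.null_signal:
        target = uniform_edges("has_target", "drug", "gene")
        indication = uniform_edges("has_indication", "drug", "disease")
    else:
        target = relation_edges("has_target", "drug", "gene", z_of("drug"), z_of("gene"))
        indication = relation_edges(
            "has_indication", "drug", "disease", z_of("drug"), z_of("disease")
        )
    side_sets = [
        relation_edges("has_sideeffect", "drug", "phenotype", z_side("drug"), z_side("phenotype")),
        relation_edges(
            "has_disease_association", "gene", "disease", z_side("gene"), z_side("disease")
        ),
        relation_edges(
            "has_disease_phenotype", "disease", "phenotype", z_side("disease"), z_side("phenotype")
        ),
        relation_edges("has_function", "gene", "function_class", z_side("gene"), z_side("function_class")),
        relation_edges(
            "interacts_with", "gene", "gene", z_side("gene"), z_side("gene"), exclude_diag=True
        ),
    ]
    # ontology chains (GO/HPO style): every term points to its most similar
    # predecessor, giving walks access to superclasses
    subclass = set()
    for group in ("function_class", "phenotype"):
        zc = z_of(group)
        for i in range(1, len(iris[group])):
            parent = int(np.argmax(zc[i] @ zc[:i].T))
            subclass.add(Triple(iris[group][i], "subclass_of", iris[group][parent]))
    side_sets.append(subclass)

    graph_poor: set[str] = set()
    if config.graph_poor_drug_fraction > 0:
        n_poor = round(config.graph_poor_drug_fraction * config.n_drugs)
        poor_idx = rng.choice(config.n_drugs, size=n_poor, replace=False)
        graph_poor = {iris["drug"][i] for i in poor_idx}
        side_sets = [
            {t for t in s if t.subject not in graph_poor and t.object not in graph_poor}
            for s in side_sets
        ]
        indication_kept = {t for t in indication if t.subject not in graph_poor}
    else:
        indication_kept = indication

    graph = build_graph([target, indication_kept, *side_sets])
    # register every entity even if isolated, so walks/pools see the full roster
    for group in iris:
        for iri in iris[group]:
            graph._node_types.setdefault(iri, group)

    truth = GroundTruth(
        has_target={(t.subject, t.object) for t in target},
        has_indication={(t.subject, t.object) for t in indication},
        latents=latents,
        graph_poor_drugs=graph_poor,
    )
    return graph, truth


# -- synthetic literature ---------------------------------------------


def _filler_lexicon() -> list[str]:
    return [f"word{i:03d}" for i in range(_FILLER_LEXICON_SIZE)]


def _mention_surface(iri: str) -> str:
    if iri.startswith("stitch:"):
        return "Compound" + iri.split("CID")[1].lstrip("0").rjust(1, "0")
    if iri.startswith("entrez:"):
        return "GENE" + iri.split(":")[1]
    return "Morbus" + iri.split(":")[1]


def _source_id(iri: str) -> tuple[str, str]:
    """(PubTator entity type, source-vocabulary ID) for a graph IRI."""
    if iri.startswith("stitch:"):
        return "Chemical", "CID" + iri.split("CID")[1].rjust(9, "0")
    if iri.startswith("entrez:"):
        return "Gene", iri.split(":")[1]
    return "Disease", "MESH:D" + iri.split(":")[1].rjust(6, "0")


def generate_synthetic_abstracts(
    kg: KnowledgeGraph,
    ground_truth: GroundTruth,
    config: SynthConfig,
) -> tuple[list[AnnotatedDocument], IdMap]:
    """Emit PubTator-style documents with planted co-mentions.

    Each document mentions the two members of one entity pair: with
    probability pi the pair is drawn from the planted positives, otherwise
    uniformly from unlinked drug-gene / drug-disease pairs, with pi solved so
    that P(co-mention | linked) / P(co-mention | unlinked) equals
    ``co_mention_lift`` exactly.  ``mention_noise`` is the chance that an
    annotation loses its identifier (un-normalizable mention);
    ``text_overlap_fraction`` controls how many entities the IdMap covers,
    entities outside it being the graph-only zero-shot cases.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed + 1))
    mentionable = sorted(
        iri for iri, t in kg.nodes.items() if t in _MENTIONABLE_TYPES
    )
    n_covered = math.ceil(config.text_overlap_fraction * len(mentionable))
    # graph-poor drugs must stay text-covered: exclude them from the drop pool
    droppable = [m for m in mentionable if m not in ground_truth.graph_poor_drugs]
    n_drop = len(mentionable) - n_covered
    dropped = set(
        np.array(droppable, dtype=object)[
            rng.choice(len(droppable), size=min(n_drop, len(droppable)), replace=False)
        ].tolist()
        if n_drop > 0
        else []
    )
    covered = [m for m in mentionable if m not in dropped]

    id_map = IdMap()
    for iri in covered:
        etype, source_id = _source_id(iri)
        id_map.add(etype, source_id, iri)

    covered_set = set(covered)
    by_type: dict[str, list[str]] = {"drug": [], "gene": [], "disease": []}
    for iri in covered:
        by_type[kg.nodes[iri]].append(iri)

    positives = sorted(
        {
            (d, x)
            for pairs in (ground_truth.has_target, ground_truth.has_indication)
            for d, x in pairs
            if d in covered_set and x in covered_set
        }
    )
    pos_set = set(positives)
    unlinked = sorted(
        (d, x)
        for d in by_type["drug"]
        for x in by_type["gene"] + by_type["disease"]
        if (d, x) not in pos_set
    )
    if not positives or not unlinked:
        raise ValueError("degenerate text world: need both linked and unlinked pairs")
    lift = config.co_mention_lift
    pi = lift * len(positives) / (lift * len(positives) + len(unlinked))

    lexicon = _filler_lexicon()
    zipf = 1.0 / np.arange(1, len(lexicon) + 1)
    zipf /= zipf.sum()

    docs: list[AnnotatedDocument] = []
    for doc_idx in range(config.n_docs):
        if rng.random() < pi:
            pair = positives[rng.integers(len(positives))]
        else:
            pair = unlinked[rng.integers(len(unlinked))]
        members = list(pair)
        if rng.random() < 0.5:
            members.reverse()

        def filler(n: int) -> list[str]:
            return [lexicon[i] for i in rng.choice(len(lexicon), size=n, p=zipf)]

        title_words = filler(3)
        title = " ".join(title_words)
        abstract_tokens: list[tuple[str, str | None]] = []  # (word, iri or None)
        abstract_tokens += [(w, None) for w in filler(4)]
        abstract_tokens.append((_mention_surface(members[0]), members[0]))
        abstract_tokens += [(w, None) for w in filler(3)]
        abstract_tokens.append((_mention_surface(members[1]), members[1]))
        abstract_tokens += [(w, None) for w in filler(3)]

        abstract = " ".join(w for w, _ in abstract_tokens)
        doc = AnnotatedDocument(str(10_000 + doc_idx), title, abstract)
        offset = len(title) + 1  # title + single space
        annotations = []
        for word, iri in abstract_tokens:
            if iri is not None:
                etype, source_id = _source_id(iri)
                if rng.random() < config.mention_noise:
                    source_id = ""
                annotations.append(
                    Annotation(offset, offset + len(word), word, etype, source_id)
                )
            offset += len(word) + 1
        doc.annotations = annotations
        docs.append(doc)
    return docs, id_map


def degrade(obj, drop_fraction: float, seed: int = 0):
    """Uniformly drop ``drop_fraction`` of graph edges or documents.

    Supports the modality-ablation experiments; surviving count is
    ``n - round(drop_fraction * n)``, deterministic by seed.
    """
    if not 0 <= drop_fraction <= 1:
        raise ValueError("drop_fraction must be in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(seed))
    if isinstance(obj, KnowledgeGraph):
        triples = sorted(obj.triples)
        n_drop = round(drop_fraction * len(triples))
        drop_idx = set(rng.choice(len(triples), size=n_drop, replace=False).tolist())
        kept = [t for i, t in enumerate(triples) if i not in drop_idx]
        g = build_graph([kept], obj.type_map, custom_relations=obj._custom_relations, symmetric=())
        for iri, etype in obj.nodes.items():
            g._node_types.setdefault(iri, etype)
        return g
    docs = list(obj)
    n_drop = round(drop_fraction * len(docs))
    drop_idx = set(rng.choice(len(docs), size=n_drop, replace=False).tolist())
    return [d for i, d in enumerate(docs) if i not in drop_idx]


__all__ = [
    "SynthConfig",
    "GroundTruth",
    "preset",
    "generate_synthetic_kg",
    "generate_synthetic_abstracts",
    "degrade",
]
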