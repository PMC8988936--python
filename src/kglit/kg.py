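"""Typed biomedical knowledge graph: construction, editing, serialization.

The graph links drugs, genes/proteins, diseases, phenotypes and ontology
classes with a small vocabulary of directed relations (``has_target``,
``has_indication``, ``has_sideeffect``, ...).  Edge lists come from
STITCH/SIDER/STRING-style TSV files, class hierarchies from OBO flat files,
and the whole graph round-trips through N-Triples.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from typing import Iterable, Mapping, NamedTuple

import obonet
import rdflib

logger = logging.getLogger(__name__)

#: Canonical relation vocabulary.  Predicates outside this set must be
#: registered explicitly via ``KnowledgeGraph.register_relation``.
RELATIONS = frozenset(
    {
        "has_target",
        "has_indication",
        "has_sideeffect",
        "has_disease_association",
        "has_disease_phenotype",
        "has_function",
        "interacts_with",
        "subclass_of",
    }
)

#: Relations that are biologically symmetric and stored as two directed triples.
SYMMETRIC_RELATIONS = frozenset({"interacts_with"})

ENTITY_TYPES = ("drug", "gene", "disease", "phenotype", "function_class", "other")

#: Default IRI-prefix -> entity type map, mirroring the prefix conventions of
#: the source databases (STITCH chemicals, Entrez genes, DO, HPO, GO).
DEFAULT_TYPE_MAP = {
    "stitch:": "drug",
    "entrez:": "gene",
    "doid:": "disease",
    "hp:": "phenotype",
    "go:": "function_class",
}

#: Namespace used when serializing bare relation names as IRIs.
RELATION_NAMESPACE = "b2v:"


class Triple(NamedTuple):
    """A directed labeled edge ``(subject, predicate, object)``."""

    subject: str
    predicate: str
    object: str

    def validate(self) -> "Triple":
        if not self.subject or not self.predicate or not self.object:
            raise ValueError(f"triple has empty field: {self!r}")
        return self


class KnowledgeGraph:
    """Directed, edge-labeled graph over typed biomedical entities.

    Nodes are IRIs typed by longest-prefix match against a prefix->type map;
    triples are deduplicated; adjacency (outgoing ``(predicate, object)``
    lists) is kept exactly consistent with the triple set.
    """

    def __init__(self, type_map: Mapping[str, str] | None = None):
        self.type_map = dict(DEFAULT_TYPE_MAP if type_map is None else type_map)
        self._node_types: dict[str, str] = {}
        self._triples: set[Triple] = set()
        self._adjacency: dict[str, list[tuple[str, str]]] = defaultdict(list)
        self._custom_relations: set[str] = set()

    # -- construction -------------------------------------------------

    def register_relation(self, predicate: str) -> None:
        """Allow a predicate outside the canonical vocabulary."""
        self._custom_relations.add(predicate)

    def _type_of(self, iri: str) -> str:
        best = ""
        best_type = "other"
        for prefix, etype in self.type_map.items():
            if iri.startswith(prefix) and len(prefix) > len(best):
                best, best_type = prefix, etype
        return best_type

    def add_triple(self, triple: Triple) -> None:
        triple = Triple(*triple).validate()
        if triple.predicate not in RELATIONS and triple.predicate not in self._custom_relations:
            raise ValueError(
                f"predicate {triple.predicate!r} is not in the relation vocabulary; "
                "call register_relation() first"
            )
        if triple in self._triples:
            return
        self._triples.add(triple)
        for iri in (triple.subject, triple.object):
            if iri not in self._node_types:
                self._node_types[iri] = self._type_of(iri)
        self._adjacency[triple.subject].append((triple.predicate, triple.object))

    # -- inspection ---------------------------------------------------

    @property
    def nodes(self) -> dict[str, str]:
        """IRI -> entity type for every registered node."""
        return dict(self._node_types)

    @property
    def triples(self) -> frozenset[Triple]:
        return frozenset(self._triples)

    def num_nodes(self) -> int:
        return len(self._node_types)

    def num_triples(self) -> int:
        return len(self._triples)

    def out_edges(self, iri: str) -> list[tuple[str, str]]:
        """Outgoing ``(predicate, object)`` pairs of a node (copy)."""
        return list(self._adjacency.get(iri, ()))

    def predicates(self) -> set[str]:
        return {t.predicate for t in self._triples}

    def nodes_of_type(self, entity_type: str) -> set[str]:
        return {n for n, t in self._node_types.items() if t == entity_type}

    def has_triple(self, s: str, p: str, o: str) -> bool:
        return Triple(s, p, o) in self._triples

    def __contains__(self, iri: str) -> bool:
        return iri in self._node_types

    def __len__(self) -> int:
        return len(self._node_types)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return self._triples == other._triples and self._node_types == other._node_types

    def __repr__(self) -> str:
        return f"<KnowledgeGraph nodes={self.num_nodes()} triples={self.num_triples()}>"

    def copy(self) -> "KnowledgeGraph":
        g = KnowledgeGraph(self.type_map)
        g._custom_relations = set(self._custom_relations)
        for t in self._triples:
            g.add_triple(t)
        # preserve isolated nodes (possible after edge removal)
        for iri, etype in self._node_types.items():
            g._node_types.setdefault(iri, etype)
        return g


def load_edge_tsv(
    path,
    predicate: str,
    subject_prefix: str = "",
    object_prefix: str = "",
    *,
    header: bool = False,
    min_score: float | None = None,
    score_column: int = 2,
) -> set[Triple]:
    """Load a two-or-more-column TSV edge list as a deduplicated triple set.

    ``subject_prefix``/``object_prefix`` are prepended to the first/second
    column, so that e.g. row ``CID1<TAB>P53`` with prefixes ``stitch:`` /
    ``entrez:`` yields ``(stitch:CID1, predicate, entrez:P53)``.  An optional
    numeric score column (STITCH/STRING combined scores) can be thresholded
    with ``min_score``; by default all rows are kept.
    """
    triples: set[Triple] = set()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 2 tab-separated columns, got {len(fields)}"
                )
            if min_score is not None:
                if len(fields) <= score_column:
                    raise ValueError(
                        f"{path}: line {lineno}: no score column {score_column} for thresholding"
                    )
                if float(fields[score_column]) < min_score:
                    continue
            n_rows += 1
            triples.add(
                Triple(subject_prefix + fields[0], predicate, object_prefix + fields[1]).validate()
            )
    if n_rows == 0:
        warnings.warn(f"{path}: empty edge list", stacklevel=2)
    logger.info("%s: %d rows -> %d distinct %s triples", path, n_rows, len(triples), predicate)
    return triples


def load_obo_hierarchy(path, predicate: str = "subclass_of") -> set[Triple]:
    """Extract ``(child, subclass_of, parent)`` triples from an OBO flat file.

    Obsolete terms contribute no triples; an ``is_a`` referencing a term not
    declared in the file is still emitted (forward references are legal OBO).
    """
    graph = obonet.read_obo(path)
    triples: set[Triple] = set()
    declared = set(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in declared:  # pragma: no cover - obonet creates target nodes
            warnings.warn(f"{path}: is_a references undeclared id {parent}", stacklevel=2)
        triples.add(Triple(child, predicate, parent))
    logger.info("%s: %d %s triples", path, len(triples), predicate)
    return triples


def build_graph(
    triple_sets: Iterable[Iterable[Triple]],
    type_map: Mapping[str, str] | None = None,
    *,
    custom_relations: Iterable[str] = (),
    symmetric: Iterable[str] = SYMMETRIC_RELATIONS,
) -> KnowledgeGraph:
    """Union triple sets into one typed graph.

    Relations listed in ``symmetric`` (protein-protein ``interacts_with`` by
    default) are materialized in both directions so that walks can traverse
    them either way.
    """
    symmetric = set(symmetric)
    g = KnowledgeGraph(type_map)
    for predicate in custom_relations:
        g.register_relation(predicate)
    for triple_set in triple_sets:
        for t in triple_set:
            g.add_triple(t)
            if t.predicate in symmetric:
                g.add_triple(Triple(t.object, t.predicate, t.subject))
    return g


def remove_edges_by_predicate(graph: KnowledgeGraph, predicate: str) -> KnowledgeGraph:
    """Return a copy of ``graph`` with every triple of ``predicate`` removed.

    Nodes are preserved (they may become isolated); the input is untouched.
    """
    g = KnowledgeGraph(graph.type_map)
    g._custom_relations = set(graph._custom_relations)
    for t in graph.triples:
        if t.predicate != predicate:
            g.add_triple(t)
    for iri, etype in graph.nodes.items():
        g._node_types.setdefault(iri, etype)
    return g


# -- N-Triples serialization -----------------------------------------


def _predicate_iri(predicate: str) -> str:
    return predicate if ":" in predicate else RELATION_NAMESPACE + predicate


def _predicate_name(iri: str) -> str:
    if iri.startswith(RELATION_NAMESPACE):
        return iri[len(RELATION_NAMESPACE):]
    return iri


def write_ntriples(graph: KnowledgeGraph, path) -> None:
    """Serialize the triple set as sorted N-Triples (bare relation names get
    the ``b2v:`` namespace)."""
    rg = rdflib.Graph()
    for t in graph.triples:
        rg.add(
            (
                rdflib.URIRef(t.subject),
                rdflib.URIRef(_predicate_iri(t.predicate)),
                rdflib.URIRef(t.object),
            )
        )
    lines = sorted(rg.serialize(format="nt").splitlines())
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            if line.strip():
                fh.write(line + "\n")


def read_ntriples(path, type_map: Mapping[str, str] | None = None) -> KnowledgeGraph:
    """Parse an N-Triples file back into a :class:`KnowledgeGraph`."""
    rg = rdflib.Graph()
    with open(path, encoding="utf-8") as fh:
        data = fh.read()
    try:
        rg.parse(data=data, format="nt")
    except Exception as exc:  # rdflib reports the offending line
        raise ValueError(f"{path}: invalid N-Triples: {exc}") from exc
    triples = {
        Triple(str(s), _predicate_name(str(p)), str(o)) for s, p, o in rg
    }
    custom = {t.predicate for t in triples} - RELATIONS
    # serialization already materialized both directions of symmetric edges
    return build_graph([triples], type_map, custom_relations=custom, symmetric=())
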