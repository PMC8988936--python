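"""Literature corpus construction (corpus 2).

Parses PubTator-annotated abstracts, replaces entity mentions (chemicals,
genes, diseases) with the IRIs used in the knowledge graph so the two corpora
overlap at the token level, and computes drug-target / drug-disease
co-occurrence statistics plus the co-occurrence document ablation.

Offsets follow the PubTator convention: 0-based, end-exclusive, over
``title + " " + abstract``.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

logger = logging.getLogger(__name__)

_PUNCT = ".,;:!?()[]{}\"'`“”‘’«»<>"


@dataclass(frozen=True)
class Annotation:
    """A single entity mention with character offsets into the document text."""

    start: int
    end: int
    mention: str
    entity_type: str  # Chemical | Gene | Disease | other
    identifier: str  # source-vocabulary ID, possibly ""


@dataclass
class AnnotatedDocument:
    doc_id: str
    title: str
    abstract: str
    annotations: list[Annotation] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Concatenated title + single space + abstract, the offset frame."""
        return self.title + " " + self.abstract if self.abstract else self.title


def _normalize_id(entity_type: str, identifier: str) -> tuple[str, str]:
    """Canonicalize mixed identifier dialects to (type, uppercased ID)."""
    return (entity_type, identifier.strip().upper())


class IdMap:
    """Mapping from (entity_type, source-vocabulary ID) to graph IRI.

    Unmapped lookups return ``None`` — an IRI is never fabricated.
    """

    def __init__(self, mapping: Mapping[tuple[str, str], str] | None = None):
        self._map: dict[tuple[str, str], str] = {}
        if mapping:
            for (etype, source_id), iri in mapping.items():
                self.add(etype, source_id, iri)

    def add(self, entity_type: str, source_id: str, iri: str) -> None:
        self._map[_normalize_id(entity_type, source_id)] = iri

    def get(self, entity_type: str, source_id: str) -> str | None:
        if not source_id:
            return None
        return self._map.get(_normalize_id(entity_type, source_id))

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return _normalize_id(*key) in self._map

    def iris(self) -> set[str]:
        return set(self._map.values())

    @classmethod
    def from_tsv(cls, path) -> "IdMap":
        """Read a 3-column TSV: entity_type, source_id, IRI."""
        m = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(f"{path}: line {lineno}: expected 3 columns")
                m.add(*fields)
        return m

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for (etype, source_id), iri in sorted(self._map.items()):
                fh.write(f"{etype}\t{source_id}\t{iri}\n")


# -- PubTator parsing -------------------------------------------------


def parse_pubtator(stream: TextIO | str, *, strict: bool = False) -> list[AnnotatedDocument]:
    """Parse PubTator exchange format into annotated documents.

    Blocks are ``PMID|t|title`` and ``PMID|a|abstract`` lines followed by
    tab-separated annotation lines, separated by blank lines.  Annotations
    whose offsets do not reproduce the mention text are dropped (counted in a
    warning) unless ``strict``, in which case they raise.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [line.rstrip("\n") for line in stream]

    docs: list[AnnotatedDocument] = []
    title: str | None = None
    abstract = ""
    doc_id: str | None = None
    pending: list[tuple[str, ...]] = []
    dropped = 0

    def flush():
        nonlocal title, abstract, doc_id, pending, dropped
        if doc_id is None:
            return
        if title is None:
            raise ValueError(f"PubTator block for {doc_id} is missing a |t| title line")
        doc = AnnotatedDocument(doc_id, title, abstract)
        text = doc.text
        anns = []
        for fields in pending:
            start, end = int(fields[1]), int(fields[2])
            mention, etype = fields[3], fields[4]
            identifier = fields[5] if len(fields) > 5 else ""
            if not (0 <= start < end <= len(text)) or text[start:end] != mention:
                if strict:
                    raise ValueError(
                        f"doc {doc_id}: annotation [{start},{end}) does not match text"
                    )
                dropped += 1
                continue
            anns.append(Annotation(start, end, mention, etype, identifier))
        doc.annotations = sorted(anns, key=lambda a: (a.start, a.end))
        docs.append(doc)
        title, abstract, doc_id, pending = None, "", None, []

    for line in lines:
        if not line.strip():
            flush()
            continue
        m = re.match(r"^([^|\t]+)\|t\|(.*)$", line)
        if m:
            flush()
            doc_id, title = m.group(1), m.group(2)
            continue
        m = re.match(r"^([^|\t]+)\|a\|(.*)$", line)
        if m:
            if doc_id is None or m.group(1) != doc_id:
                raise ValueError(f"abstract line for unknown PMID {m.group(1)}")
            abstract = m.group(2)
            continue
        fields = tuple(line.split("\t"))
        if len(fields) < 5:
            raise ValueError(f"malformed PubTator annotation line: {line!r}")
        if doc_id is None or fields[0] != doc_id:
            raise ValueError(f"annotation references unknown PMID {fields[0]}")
        pending.append(fields)
    flush()
    if dropped:
        warnings.warn(f"dropped {dropped} annotations with invalid offsets", stacklevel=2)
    return docs


def write_pubtator(docs: Iterable[AnnotatedDocument], path) -> None:
    """Serialize documents back to PubTator exchange format."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(f"{doc.doc_id}|t|{doc.title}\n")
            fh.write(f"{doc.doc_id}|a|{doc.abstract}\n")
            for a in doc.annotations:
                fh.write(
                    f"{doc.doc_id}\t{a.start}\t{a.end}\t{a.mention}\t{a.entity_type}\t{a.identifier}\n"
                )
            fh.write("\n")


# -- normalization ----------------------------------------------------


def _tokenize_words(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip flanking punctuation."""
    tokens = []
    for raw in text.lower().split():
        token = raw.strip(_PUNCT)
        if token:
            tokens.append(token)
    return tokens


def _select_annotations(annotations: list[Annotation]) -> list[Annotation]:
    """Resolve overlaps: keep the longest span; ties broken by earliest start."""
    chosen: list[Annotation] = []
    order = sorted(annotations, key=lambda a: (-(a.end - a.start), a.start, a.end))
    for a in order:
        if all(a.end <= c.start or a.start >= c.end for c in chosen):
            chosen.append(a)
    return sorted(chosen, key=lambda a: a.start)


def normalize_document(doc: AnnotatedDocument, id_map: IdMap) -> list[str]:
    """Replace mapped entity mentions by their graph IRIs, tokenize the rest.

    Each mapped annotation contributes exactly one case-preserved IRI token;
    unmapped annotations are left in place as ordinary (lowercased) words.
    """
    text = doc.text
    tokens: list[str] = []
    cursor = 0
    for a in _select_annotations(doc.annotations):
        iri = id_map.get(a.entity_type, a.identifier)
        if iri is None:
            continue  # mention stays as plain text
        tokens.extend(_tokenize_words(text[cursor:a.start]))
        tokens.append(iri)
        cursor = a.end
    tokens.extend(_tokenize_words(text[cursor:]))
    return tokens


class TextCorpus:
    """Sentences mixing graph IRIs and lowercased words; one per document."""

    def __init__(self, sentences: list[list[str]]):
        self.sentences = sentences

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def num_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


def build_text_corpus(docs: Iterable[AnnotatedDocument], id_map: IdMap) -> TextCorpus:
    """Normalize every document into one sentence (title + abstract tokens)."""
    return TextCorpus([normalize_document(doc, id_map) for doc in docs])


# -- co-occurrence statistics -----------------------------------------


def _mentioned_iris(doc: AnnotatedDocument, id_map: IdMap) -> set[str]:
    return {
        iri
        for a in doc.annotations
        if (iri := id_map.get(a.entity_type, a.identifier)) is not None
    }


def _norm_pair(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass
class CooccurrenceStats:
    """Document-level co-mention statistics for unordered entity pairs.

    ``positive_fraction_of_cooccurring`` answers: of all entity pairs that
    co-occur in at least one document (within the pair universe surveyed),
    what fraction are known positives?  ``cooccurring_fraction_of_positives``:
    of the known positives, what fraction co-occur at least once?
    """

    per_pair_doc_counts: dict[tuple[str, str], int]
    n_cooccurring_pairs: int
    n_cooccurring_positive: int
    positive_fraction_of_cooccurring: float
    cooccurring_fraction_of_positives: float


def cooccurrence_stats(
    docs: Iterable[AnnotatedDocument],
    pairs: set[tuple[str, str]],
    id_map: IdMap,
    *,
    pair_universe: "set[tuple[str, str]] | None" = None,
    entity_types: Mapping[str, str] | None = None,
) -> CooccurrenceStats:
    """Count per-pair co-mention documents and positive-pair overlap.

    ``pairs`` is the positive set (unordered).  The co-occurring pair universe
    is every unordered pair of distinct mapped IRIs observed together in a
    document; ``pair_universe`` (or an ``entity_types`` map restricting to
    drug-gene / drug-disease combinations) narrows it to the pairs of
    interest.
    """
    positives = {_norm_pair(p) for p in pairs}
    counts: dict[tuple[str, str], int] = {}
    for doc in docs:
        iris = sorted(_mentioned_iris(doc, id_map))
        for i, a in enumerate(iris):
            for b in iris[i + 1:]:
                pair = (a, b)
                if pair_universe is not None and pair not in pair_universe:
                    continue
                if entity_types is not None:
                    ta, tb = entity_types.get(a), entity_types.get(b)
                    if {ta, tb} not in ({"drug", "gene"}, {"drug", "disease"}):
                        continue
                counts[pair] = counts.get(pair, 0) + 1
    n_cooc = len(counts)
    n_cooc_pos = sum(1 for p in counts if p in positives)
    n_pos_cooc = sum(1 for p in positives if counts.get(p, 0) >= 1)
    return CooccurrenceStats(
        per_pair_doc_counts=counts,
        n_cooccurring_pairs=n_cooc,
        n_cooccurring_positive=n_cooc_pos,
        positive_fraction_of_cooccurring=n_cooc_pos / n_cooc if n_cooc else 0.0,
        cooccurring_fraction_of_positives=n_pos_cooc / len(positives) if positives else 0.0,
    )


def filter_cooccurring_docs(
    docs: list[AnnotatedDocument],
    pairs: set[tuple[str, str]],
    id_map: IdMap,
) -> list[AnnotatedDocument]:
    """Drop every document in which both members of any pair are mentioned.

    Supports the ablation asking whether predictions merely read explicitly
    co-stated associations out of the text.  The input list is not modified.
    """
    positives = {_norm_pair(p) for p in pairs}
    kept = []
    for doc in docs:
        iris = _mentioned_iris(doc, id_map)
        if any(a in iris and b in iris for a, b in positives):
            continue
        kept.append(doc)
    return kept
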