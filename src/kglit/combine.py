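"""Combining the two modalities: corpus concatenation and vector concatenation.

Two routes to a multi-modal representation:

* ``concat_corpora`` merges the walk corpus and the literature corpus into one
  shuffled corpus for *jointly learned* embeddings (a single skip-gram run
  sees both modalities; entities shared between them tie the spaces together);
* ``concat_embeddings`` stacks separately trained vectors side by side.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .vectors import EmbeddingTable
from .walks import WalkCorpus


def concat_corpora(c1: Iterable[Iterable[str]], c2: Iterable[Iterable[str]], seed: int = 0) -> WalkCorpus:
    """Multiset union of sentences from both corpora, deterministically shuffled."""
    sentences = [list(s) for s in c1] + [list(s) for s in c2]
    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(len(sentences))
    return WalkCorpus([sentences[i] for i in order])


def concat_embeddings(
    e1: EmbeddingTable,
    e2: EmbeddingTable,
    policy: str = "intersect",
) -> EmbeddingTable:
    """Stack two embedding tables into (d1 + d2)-dimensional vectors.

    ``intersect`` keeps tokens present in both vocabularies; ``zero_fill``
    keeps the union, padding the missing block with zeros (this is how
    zero-shot entities — present in only one modality — still get a feature
    vector).
    """
    if policy not in ("intersect", "zero_fill"):
        raise ValueError("policy must be 'intersect' or 'zero_fill'")
    if len(e1) == 0 and len(e2) == 0:
        raise ValueError("both embedding tables are empty")
    if policy == "intersect":
        tokens = sorted(e1.vocabulary() & e2.vocabulary())
    else:
        tokens = sorted(e1.vocabulary() | e2.vocabulary())
    d1, d2 = e1.dim, e2.dim
    out = np.zeros((len(tokens), d1 + d2))
    for i, token in enumerate(tokens):
        v1 = e1.get(token)
        if v1 is not None:
            out[i, :d1] = v1
        v2 = e2.get(token)
        if v2 is not None:
            out[i, d1:] = v2
    return EmbeddingTable(tokens, out)
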