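"""Token -> vector tables and word2vec-text-format I/O."""

from __future__ import annotations

import numpy as np


class EmbeddingTable:
    """An ordered vocabulary with one fixed-dimension real vector per token."""

    def __init__(self, tokens: list[str], vectors: np.ndarray):
        vectors = np.asarray(vectors, dtype=np.float64)
        if vectors.ndim != 2 or vectors.shape[0] != len(tokens):
            raise ValueError("vectors must be (len(tokens), dim)")
        if not np.isfinite(vectors).all():
            raise ValueError("embedding vectors contain NaN/Inf")
        if len(set(tokens)) != len(tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self.tokens = list(tokens)
        self.vectors = vectors
        self.index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[self.index[token]]

    def get(self, token: str, default=None):
        i = self.index.get(token)
        return default if i is None else self.vectors[i]

    def vocabulary(self) -> set[str]:
        return set(self.tokens)

    def cosine(self, a: str, b: str) -> float:
        va, vb = self[a], self[b]
        denom = np.linalg.norm(va) * np.linalg.norm(vb)
        if denom == 0:
            return 0.0
        return float(va @ vb / denom)


def write_vectors(table: EmbeddingTable, path) -> None:
    """word2vec text format: header ``vocab_size dim``, then token + floats."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dim}\n")
        for token, vec in zip(table.tokens, table.vectors):
            fh.write(token + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")


def read_vectors(path) -> EmbeddingTable:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header")
        n, dim = int(header[0]), int(header[1])
        tokens, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: line {lineno}: expected {dim + 1} fields")
            tokens.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(tokens) != n:
        raise ValueError(f"{path}: header claims {n} vectors, found {len(tokens)}")
    return EmbeddingTable(tokens, np.array(rows))
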