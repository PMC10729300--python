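"""Embedding + random-forest baseline regressor.

The comparison model embeds each variant sequence as a fixed-length real
vector and fits a random-forest regressor per target with library-default
settings. The embedding is pluggable: the built-in one-hot encoding (20·L
dimensions) is the default, and externally computed embedding tables — e.g.
the 1900-dimensional averaged-hidden-state representation of a pretrained
protein language model — can be loaded from TSV. The reproducible content
is the comparison protocol, not any particular pretrained embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .sequence_space import AA_INDEX


class EmbeddingError(ValueError):
    """Raised for malformed embeddings or id mismatches."""


@dataclass(frozen=True)
class Embedding:
    """Per-variant real vectors of one fixed dimension."""

    name: str
    vectors: np.ndarray  # (n, dimension)
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2:
            raise EmbeddingError("embedding vectors must form a 2-D array")
        if not np.all(np.isfinite(v)):
            raise EmbeddingError("embedding contains non-finite values")
        if self.ids and len(self.ids) != v.shape[0]:
            raise EmbeddingError("ids and vectors must align")
        object.__setattr__(self, "vectors", v)

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


def onehot_embed(sequences: list[str], ids: list[str] | None = None) -> Embedding:
    """One-hot encode equal-length sequences: dimension 20·L, row sums L."""
    if not sequences:
        raise EmbeddingError("empty sequence list")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise EmbeddingError("sequences of unequal length")
    X = np.zeros((len(sequences), 20 * L))
    for i, s in enumerate(sequences):
        for j, aa in enumerate(s):
            if aa not in AA_INDEX:
                raise EmbeddingError(f"non-canonical residue {aa!r}")
            X[i, 20 * j + AA_INDEX[aa]] = 1.0
    return Embedding(name="onehot", vectors=X, ids=tuple(ids) if ids else ())


def load_embedding_table(
    path: str | Path, expected_ids: list[str] | None = None, name: str = "external"
) -> Embedding:
    """Load a TSV of ``id, v1, ..., vD`` rows as an Embedding.

    When ``expected_ids`` is given, rows are reordered to match it and every
    id must be present.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise EmbeddingError("embedding table needs an id column plus vector columns")
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    vec = df.iloc[:, 1:].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    ids = list(df[id_col])
    if expected_ids is not None:
        index = {vid: i for i, vid in enumerate(ids)}
        missing = [vid for vid in expected_ids if vid not in index]
        if missing:
            raise EmbeddingError(f"embedding table missing ids: {missing}")
        vec = vec[[index[vid] for vid in expected_ids]]
        ids = list(expected_ids)
    return Embedding(name=name, vectors=vec, ids=tuple(ids))


def rf_fit_predict(
    train: Embedding,
    train_targets: dict[str, np.ndarray],
    test: Embedding,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Fit one default-settings random forest per target and predict.

    Deterministic given ``seed``. Tree-ensemble predictions are averages of
    training targets, so they never leave the training-target range.
    """
    if train.n < 2:
        raise EmbeddingError("need at least 2 training points")
    if train.dimension != test.dimension:
        raise EmbeddingError(
            f"dimension mismatch: train {train.dimension}, test {test.dimension}"
        )
    out: dict[str, np.ndarray] = {}
    for name, y in train_targets.items():
        y = np.asarray(y, dtype=float)
        if y.shape != (train.n,):
            raise EmbeddingError(f"target {name!r} misaligned with training embedding")
        rf = RandomForestRegressor(random_state=seed)
        rf.fit(train.vectors, y)
        out[name] = rf.predict(test.vectors)
    return out
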