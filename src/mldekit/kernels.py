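"""Sequence-similarity kernels over equal-length protein variants.

The working kernel compares two sequences position by position through a
substitution matrix: the raw value is the summed BLOSUM62 score
``k_raw(x, y) = sum_i B62(x_i, y_i)``, optionally cosine-normalized so that
every sequence has unit self-similarity. A Hamming (identity fraction)
kernel is available as the classical alternative. Because BLOSUM62 is a
log-odds table and not itself a valid Mercer kernel, Gram matrices may have
small negative eigenvalues; the Gaussian-process layer absorbs this with an
additive ridge, and an explicit eigenvalue-clipping repair is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .sequence_space import AMINO_ACIDS, AA_INDEX


class KernelError(ValueError):
    """Raised for invalid kernel configurations or incompatible inputs."""


def load_substitution_matrix(name_or_path: str = "BLOSUM62") -> np.ndarray:
    """Load a 20×20 substitution-score table keyed by :data:`AMINO_ACIDS`.

    ``name_or_path`` is either a named matrix bundled with biopython
    ("BLOSUM62", "PAM250", ...) or a path to an NCBI-format matrix file.
    """
    if Path(name_or_path).is_file():
        mat = substitution_matrices.read(str(name_or_path))
    else:
        mat = substitution_matrices.load(name_or_path)
    table = np.empty((20, 20), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            try:
                table[i, j] = mat[a, b]
            except (KeyError, IndexError) as exc:
                raise KernelError(f"residue pair ({a},{b}) absent from matrix") from exc
    if not np.allclose(table, table.T):
        raise KernelError("substitution matrix is not symmetric")
    return table


@dataclass(frozen=True)
class KernelSpec:
    """Configuration of a sequence kernel.

    family : ``"blosum_position"`` (position-summed substitution scores) or
        ``"hamming"`` (fraction of identical positions).
    substitution_matrix : 20×20 symmetric score table, BLOSUM62 by default;
        ignored by the hamming family.
    normalize : cosine-normalize so k(x, x) = 1 (blosum_position only;
        hamming is already 1 on the diagonal).
    """

    family: str = "blosum_position"
    substitution_matrix: np.ndarray = field(
        default_factory=lambda: load_substitution_matrix("BLOSUM62")
    )
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("blosum_position", "hamming"):
            raise KernelError(f"unknown kernel family {self.family!r}")
        m = np.asarray(self.substitution_matrix, dtype=float)
        if m.shape != (20, 20) or not np.allclose(m, m.T):
            raise KernelError("substitution matrix must be symmetric 20×20")
        object.__setattr__(self, "substitution_matrix", m)


@dataclass(frozen=True)
class GramMatrix:
    """Symmetric kernel matrix over an ordered sequence set."""

    values: np.ndarray
    kernel: KernelSpec
    sequence_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise KernelError("Gram matrix must be square")
        if not np.all(np.isfinite(v)):
            raise KernelError("Gram matrix has non-finite entries")
        if not np.allclose(v, v.T, atol=1e-10):
            raise KernelError("Gram matrix is not symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def encode_sequences(sequences: list[str]) -> np.ndarray:
    """Integer-encode equal-length sequences as an (n, L) array."""
    if not sequences:
        raise KernelError("empty sequence list")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise KernelError(f"sequences of unequal length: {sorted(lengths)}")
    try:
        return np.array([[AA_INDEX[a] for a in s] for s in sequences], dtype=np.intp)
    except KeyError as exc:
        raise KernelError(f"residue {exc.args[0]!r} absent from the canonical alphabet")


def _raw_cross(X: np.ndarray, Z: np.ndarray, B: np.ndarray) -> np.ndarray:
    # sum_l B[x_l, z_l] accumulated position by position; n·m·L work
    K = np.zeros((X.shape[0], Z.shape[0]))
    for l in range(X.shape[1]):
        K += B[np.ix_(X[:, l], Z[:, l])]
    return K


def _raw_self(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    return B[X, X].sum(axis=1)


def kernel_value(x: str, y: str, spec: KernelSpec) -> float:
    """Kernel value between two equal-length sequences."""
    X = encode_sequences([x, y])
    if spec.family == "hamming":
        return float(np.mean(X[0] == X[1]))
    B = spec.substitution_matrix
    raw = float(_raw_cross(X[:1], X[1:], B)[0, 0])
    if not spec.normalize:
        return raw
    sx, sy = _raw_self(X, B)
    return raw / float(np.sqrt(sx * sy))


def cross_gram(X: list[str], Z: list[str], spec: KernelSpec) -> np.ndarray:
    """Kernel matrix between two sequence lists; rows index ``X``."""
    if not X or not Z:
        raise KernelError("empty sequence list")
    if len(X[0]) != len(Z[0]):
        raise KernelError("X and Z sequences must share one length")
    Xe = encode_sequences(X)
    Ze = encode_sequences(Z)
    if spec.family == "hamming":
        K = np.zeros((len(X), len(Z)))
        for l in range(Xe.shape[1]):
            K += (Xe[:, l][:, None] == Ze[:, l][None, :])
        return K / Xe.shape[1]
    B = spec.substitution_matrix
    K = _raw_cross(Xe, Ze, B)
    if spec.normalize:
        sx = _raw_self(Xe, B)
        sz = _raw_self(Ze, B)
        K = K / np.sqrt(np.outer(sx, sz))
    return K


def self_kernel(X: list[str], spec: KernelSpec) -> np.ndarray:
    """Diagonal k(x, x) for each sequence (prior variance of each point)."""
    if spec.family == "hamming" or spec.normalize:
        return np.ones(len(X))
    return _raw_self(encode_sequences(X), spec.substitution_matrix)


def gram(X: list[str], spec: KernelSpec, ids: list[str] | None = None) -> GramMatrix:
    """Full pairwise Gram matrix over a sequence list."""
    K = cross_gram(X, X, spec)
    K = (K + K.T) / 2.0  # enforce exact symmetry against float round-off
    if ids is None:
        ids = [f"s{i}" for i in range(len(X))]
    return GramMatrix(values=K, kernel=spec, sequence_ids=tuple(ids))


def psd_repair(G: GramMatrix, mode: str = "clip") -> GramMatrix:
    """Project a symmetric Gram matrix onto the PSD cone.

    ``mode="none"`` returns the input unchanged; ``mode="clip"`` zeroes
    negative eigenvalues and re-symmetrizes.
    """
    if mode == "none":
        return G
    if mode != "clip":
        raise KernelError(f"unknown psd_repair mode {mode!r}")
    w, V = np.linalg.eigh(G.values)
    repaired = (V * np.clip(w, 0.0, None)) @ V.T
    repaired = (repaired + repaired.T) / 2.0
    return GramMatrix(values=repaired, kernel=G.kernel, sequence_ids=G.sequence_ids)
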