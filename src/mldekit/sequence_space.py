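"""Protein sequence space: parents, point mutations, variant libraries.

Variants are represented as a parent sequence plus a set of single-residue
substitutions in the standard one-letter notation (e.g. ``G20R``: Gly at
position 20 replaced by Arg). Positions are 1-based on the full expressed
construct, so printed variant names match the numbering used on the bench;
regions that must not be mutated (e.g. an affinity tag) are handled as an
exclusion mask rather than by renumbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class SequenceError(ValueError):
    """Raised for malformed sequences, mutations, or variant tables."""


@dataclass(frozen=True, order=True)
class Mutation:
    """A single amino-acid substitution, ordered by (position, mut_aa)."""

    position: int
    wt_aa: str = field(compare=False)
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_SET or self.mut_aa not in AA_SET:
            raise SequenceError(
                f"non-canonical residue in mutation {self.wt_aa}{self.position}{self.mut_aa}"
            )
        if self.position < 1:
            raise SequenceError(f"mutation position must be >= 1, got {self.position}")
        if self.wt_aa == self.mut_aa:
            raise SequenceError(
                f"silent substitution {self.wt_aa}{self.position}{self.mut_aa}: "
                "wild-type and mutant residue are identical"
            )

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def parse_mutation(token: str) -> Mutation:
    """Parse one-letter mutation notation such as ``"G20R"``.

    Round-trips with ``str(mutation)``.
    """
    m = _MUTATION_RE.match(token.strip())
    if m is None:
        raise SequenceError(f"malformed mutation token {token!r} (expected e.g. 'G20R')")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return Mutation(position=pos, wt_aa=wt, mut_aa=mut)


def parse_mutation_list(text: str, sep: str = ";") -> frozenset[Mutation]:
    """Parse a separator-joined mutation list; empty text means wild type."""
    text = text.strip()
    if not text:
        return frozenset()
    return frozenset(parse_mutation(tok) for tok in text.split(sep) if tok.strip())


@dataclass(frozen=True)
class ParentSequence:
    """A reference protein over the canonical 20-letter alphabet.

    ``excluded_positions`` are 1-based positions barred from mutation
    (tag regions, catalytic residues the screen must not touch, ...).
    """

    id: str
    residues: str
    excluded_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("parent sequence must be non-empty")
        bad = set(self.residues) - AA_SET
        if bad:
            raise SequenceError(
                f"parent {self.id!r} contains non-canonical residues: {sorted(bad)}"
            )
        object.__setattr__(self, "excluded_positions", frozenset(self.excluded_positions))
        out = [p for p in self.excluded_positions if not 1 <= p <= len(self.residues)]
        if out:
            raise SequenceError(f"excluded positions out of range: {sorted(out)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Variant:
    """A parent plus a set of point substitutions; sequence is derived."""

    parent: ParentSequence
    mutations: frozenset[Mutation]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutations", frozenset(self.mutations))
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise SequenceError("at most one mutation per position")
        for m in self.mutations:
            if m.position > len(self.parent):
                raise SequenceError(f"mutation {m} beyond parent length {len(self.parent)}")
            if self.parent.residues[m.position - 1] != m.wt_aa:
                raise SequenceError(
                    f"wild-type mismatch for {m}: parent has "
                    f"{self.parent.residues[m.position - 1]!r} at position {m.position}"
                )

    @property
    def sequence(self) -> str:
        chars = list(self.parent.residues)
        for m in self.mutations:
            chars[m.position - 1] = m.mut_aa
        return "".join(chars)

    @property
    def name(self) -> str:
        if not self.mutations:
            return "WT"
        return ";".join(str(m) for m in sorted(self.mutations))

    def __len__(self) -> int:
        return len(self.parent)


def apply_mutations(parent: ParentSequence, mutations: Iterable[Mutation]) -> Variant:
    """Build a variant, checking every wild-type residue against the parent."""
    return Variant(parent=parent, mutations=frozenset(mutations))


def diff_against_parent(parent: ParentSequence, sequence: str) -> frozenset[Mutation]:
    """Recover the mutation set of a full-length sequence relative to a parent."""
    if len(sequence) != len(parent):
        raise SequenceError(
            f"sequence length {len(sequence)} != parent length {len(parent)}"
        )
    bad = set(sequence) - AA_SET
    if bad:
        raise SequenceError(f"non-canonical residues in sequence: {sorted(bad)}")
    return frozenset(
        Mutation(position=i + 1, wt_aa=p, mut_aa=s)
        for i, (p, s) in enumerate(zip(parent.residues, sequence))
        if p != s
    )


def enumerate_single_mutants(parent: ParentSequence) -> list[Variant]:
    """All 19×(L − |excluded|) single-substitution variants of ``parent``.

    Deterministic order: position-major, then alphabetical mutant residue —
    so downstream ranking ties break reproducibly.
    """
    allowed = [p for p in range(1, len(parent) + 1) if p not in parent.excluded_positions]
    if not allowed:
        raise SequenceError("all positions are excluded; nothing to enumerate")
    out: list[Variant] = []
    for pos in allowed:
        wt = parent.residues[pos - 1]
        for aa in AMINO_ACIDS:
            if aa != wt:
                out.append(Variant(parent, frozenset({Mutation(pos, wt, aa)})))
    return out


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class VariantDataset:
    """Equal-length variant sequences with per-variant measured targets.

    ``targets`` maps a target name (e.g. ``"rate"``, ``"atp_ratio"``) to a
    float array aligned with ``variants``. At least two variants are needed
    before a model can be fitted (standardization requires spread).
    """

    variants: list[Variant]
    targets: dict[str, np.ndarray]
    ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        n = len(self.variants)
        if len(self.ids) != n:
            raise SequenceError("ids and variants must align")
        if len(set(self.ids)) != n:
            raise SequenceError("duplicate variant ids")
        lengths = {len(v) for v in self.variants}
        if len(lengths) > 1:
            raise SequenceError(f"variants of unequal length: {sorted(lengths)}")
        clean: dict[str, np.ndarray] = {}
        for name, vals in self.targets.items():
            arr = np.asarray(vals, dtype=float)
            if arr.shape != (n,):
                raise SequenceError(f"target {name!r} has shape {arr.shape}, expected ({n},)")
            if not np.all(np.isfinite(arr)):
                raise SequenceError(f"target {name!r} contains non-finite values")
            clean[name] = arr
        self.targets = clean

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def sequences(self) -> list[str]:
        return [v.sequence for v in self.variants]

    def subset(self, indices: Sequence[int]) -> "VariantDataset":
        idx = list(indices)
        return VariantDataset(
            variants=[self.variants[i] for i in idx],
            targets={k: v[idx] for k, v in self.targets.items()},
            ids=[self.ids[i] for i in idx],
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, strict: bool = True) -> list[ParentSequence]:
    """Read FASTA records as parent sequences.

    In strict mode (default) any residue outside the canonical 20 letters is
    an error; there is no permissive remapping of ambiguity codes.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    parents = []
    for rec in records:
        residues = str(rec.seq).upper()
        if strict and (set(residues) - AA_SET):
            raise SequenceError(
                f"record {rec.id!r} has residues outside the canonical alphabet"
            )
        parents.append(ParentSequence(id=rec.id, residues=residues))
    return parents


def write_fasta(seqs: Iterable[ParentSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


#: Variant-table columns. ``mutations`` or ``sequence`` must be present.
TABLE_COLUMNS = ("id", "mutations", "sequence", "rate", "atp_ratio")


def read_variant_table(
    path: str | Path,
    parent: ParentSequence,
    target_columns: Sequence[str] = ("rate", "atp_ratio"),
    sep: str = "\t",
) -> VariantDataset:
    """Read a TSV/CSV variant table against a parent sequence.

    Each row supplies either a ``mutations`` list (``"G20R;L100N"``, empty for
    wild type) or a full ``sequence`` (diffed against the parent), plus one
    numeric column per target.
    """
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    if "id" not in df.columns:
        raise SequenceError("variant table must have an 'id' column")
    has_mut = "mutations" in df.columns
    has_seq = "sequence" in df.columns
    if not (has_mut or has_seq):
        raise SequenceError("variant table needs a 'mutations' or 'sequence' column")
    missing = [c for c in target_columns if c not in df.columns]
    if missing:
        raise SequenceError(f"missing target columns: {missing}")

    variants: list[Variant] = []
    for _, row in df.iterrows():
        if has_mut and isinstance(row.get("mutations"), str) and row["mutations"].strip():
            muts = parse_mutation_list(row["mutations"])
        elif has_seq and isinstance(row.get("sequence"), str) and row["sequence"].strip():
            muts = diff_against_parent(parent, row["sequence"].strip().upper())
        else:
            muts = frozenset()  # wild-type control row
        variants.append(apply_mutations(parent, muts))

    targets = {}
    for col in target_columns:
        vals = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        targets[col] = vals
    return VariantDataset(
        variants=variants,
        targets=targets,
        ids=[str(i) for i in df["id"]],
        provenance=str(path),
    )


def write_variant_table(dataset: VariantDataset, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {
            "id": dataset.ids,
            "mutations": [v.name if v.mutations else "" for v in dataset.variants],
            "sequence": dataset.sequences,
            **dataset.targets,
        }
    )
    df.to_csv(path, sep=sep, index=False)
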