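"""Protein sequence and GO-annotation I/O, filtering, and one-hot encoding.

Sequences come in as FASTA, annotations as a two-column tab-separated table
(accession, GO identifier).  Sequences are encoded to fixed-length one-hot
batches over the 20 canonical amino acids plus one padding symbol (V = 21);
non-canonical residue codes (B, J, O, U, X, Z) map to padding by default,
or raise in strict mode.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "PAD",
    "ProteinRecord",
    "AnnotationTable",
    "Vocabulary",
    "EncodedBatch",
    "read_fasta",
    "write_fasta",
    "filter_by_length",
    "read_annotations",
    "write_annotations",
    "encode_batch",
    "decode_batch",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "-"
_GO_RE = re.compile(r"^GO:\d{7}$")


class FastaFormatError(ValueError):
    pass


class AnnotationFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession plus amino-acid sequence."""

    accession: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Vocabulary:
    """Ordered residue alphabet with a trailing padding symbol."""

    symbols: str = AMINO_ACIDS + PAD

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("vocabulary symbols must be unique")
        self.index = {ch: i for i, ch in enumerate(self.symbols)}

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def pad_index(self) -> int:
        return self.size - 1

    @property
    def pad_symbol(self) -> str:
        return self.symbols[-1]


@dataclass
class EncodedBatch:
    """Batch of fixed-length sequence encodings, shape (n, L, V).

    Rows lie on the probability simplex per position: one-hot for encoded
    real sequences, a soft simplex for generator output.
    """

    tensor: np.ndarray
    accessions: list = field(default_factory=list)

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=np.float64)
        if self.tensor.ndim != 3:
            raise ValueError("encoded batch must be 3-D (batch, length, vocab)")

    @property
    def n(self) -> int:
        return self.tensor.shape[0]

    @property
    def seq_len(self) -> int:
        return self.tensor.shape[1]

    @property
    def vocab_size(self) -> int:
        return self.tensor.shape[2]

    def check_simplex(self, atol: float = 1e-8) -> None:
        sums = self.tensor.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=atol) or self.tensor.min() < -atol:
            raise AssertionError("batch rows are not on the probability simplex")


@dataclass
class AnnotationTable:
    """Deduplicated (accession, GO id) pairs with per-class counts."""

    pairs: set

    def __post_init__(self):
        self.pairs = set(self.pairs)

    @property
    def class_counts(self) -> dict:
        counts: dict = {}
        for _, go in self.pairs:
            counts[go] = counts.get(go, 0) + 1
        return counts

    @property
    def accessions(self) -> set:
        return {acc for acc, _ in self.pairs}

    @property
    def classes(self) -> list:
        return sorted(self.class_counts)

    def annotations_for(self, accession: str) -> set:
        return {go for acc, go in self.pairs if acc == accession}


def read_fasta(path) -> list:
    """Read FASTA into records; accession is the first header token, sequences
    are uppercased with terminal stop characters stripped."""
    path = Path(path)
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper().rstrip("*")
        if not rec.id:
            raise FastaFormatError(f"{path}: entry {i + 1} has an empty header")
        if not seq:
            raise FastaFormatError(f"{path}: entry {i + 1} ({rec.id}) has an empty sequence")
        records.append(ProteinRecord(accession=rec.id, sequence=seq))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def filter_by_length(records, max_len: int = 2000):
    """Keep records with at most ``max_len`` residues (order preserved).

    Returns (kept, n_removed)."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    kept = [r for r in records if r.length <= max_len]
    return kept, len(records) - len(kept)


def read_annotations(path, known_accessions=None) -> AnnotationTable:
    """Read a two-column tab-separated annotation table.

    Duplicate rows collapse to one pair.  A malformed GO id raises with the
    line number; accessions absent from ``known_accessions`` (when given)
    are collected as warnings on the returned table, not errors.
    """
    path = Path(path)
    pairs = set()
    unknown = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AnnotationFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            acc, go = parts[0].strip(), parts[1].strip()
            if not _GO_RE.match(go):
                raise AnnotationFormatError(
                    f"{path}:{lineno}: malformed GO identifier {go!r}"
                )
            if known_accessions is not None and acc not in known_accessions:
                unknown.append(acc)
            pairs.add((acc, go))
    table = AnnotationTable(pairs=pairs)
    table.unknown_accessions = sorted(set(unknown))
    if table.unknown_accessions:
        warnings.warn(
            f"{path}: {len(table.unknown_accessions)} annotated accession(s) "
            "absent from the sequence set", stacklevel=2)
    return table


def write_annotations(pairs, path) -> None:
    with open(path, "w") as fh:
        for acc, go in sorted(pairs):
            fh.write(f"{acc}\t{go}\n")


def encode_batch(records, vocab: Vocabulary | None = None, seq_len: int = 160,
                 strict: bool = False) -> EncodedBatch:
    """One-hot encode records to shape (n, seq_len, V).

    Sequences longer than ``seq_len`` are truncated; shorter ones are
    right-padded.  Characters outside the vocabulary map to padding, or raise
    in strict mode naming the residue and its 1-based position.
    """
    if not records:
        raise ValueError("encode_batch needs at least one record")
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    vocab = vocab or Vocabulary()
    n = len(records)
    out = np.zeros((n, seq_len, vocab.size), dtype=np.float64)
    for i, rec in enumerate(records):
        seq = rec.sequence[:seq_len]
        for pos, ch in enumerate(seq):
            idx = vocab.index.get(ch)
            if idx is None:
                if strict:
                    raise ValueError(
                        f"record {rec.accession}: residue {ch!r} at position "
                        f"{pos + 1} is outside the vocabulary"
                    )
                idx = vocab.pad_index
            out[i, pos, idx] = 1.0
        out[i, len(seq):, vocab.pad_index] = 1.0
    return EncodedBatch(tensor=out, accessions=[r.accession for r in records])


def decode_batch(batch: EncodedBatch, vocab: Vocabulary | None = None) -> list:
    """Decode each position to its argmax symbol (ties -> lowest index) and
    drop padding symbols, so decoded strings are over the residue alphabet."""
    vocab = vocab or Vocabulary()
    symbols = np.array(list(vocab.symbols))
    idx = np.argmax(batch.tensor, axis=-1)
    out = []
    for row in idx:
        chars = symbols[row]
        out.append("".join(chars[row != vocab.pad_index]))
    return out
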