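"""Sequence input/output and batch encoding.

Sequences are plain strings over the 20-letter amino-acid alphabet.  A
21st symbol (``?``) doubles as the padding token and the catch-all for
non-standard residues (B, J, O, U, X, Z, gaps ...), so that sanitization
never changes sequence length and per-residue coordinates stay valid.

Positions are 1-based in every user-facing table and 0-based internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, in the conventional alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Symbol used for padding and for unknown/non-standard residues.
UNKNOWN_SYMBOL: str = "?"


@dataclass
class ProteinRecord:
    """One protein sequence with an optional binary solubility label.

    label semantics: 1 = soluble, 0 = insoluble, None = unlabelled.
    """

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Vocabulary:
    """Token vocabulary: 20 amino acids plus one PAD/unknown symbol.

    The PAD/unknown token always occupies the last index (20).
    """

    tokens: str = AMINO_ACIDS + UNKNOWN_SYMBOL

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return len(self.tokens) - 1

    def index_of(self, symbol: str) -> int:
        i = self.tokens.find(symbol)
        if i < 0:
            raise KeyError(f"symbol {symbol!r} not in vocabulary")
        return i

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sanitized sequence to an int64 index vector."""
        try:
            return np.array([self.index_of(c) for c in sequence], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"sequence contains unsanitized symbol: {exc}") from exc

    def decode(self, indices: Iterable[int]) -> str:
        return "".join(self.tokens[i] for i in indices)


DEFAULT_VOCABULARY = Vocabulary()


def sanitize(sequence: str) -> str:
    """Uppercase a raw sequence and replace non-standard residues.

    Characters outside the 20 standard letters (B, J, O, U, X, Z, gap
    characters, ...) are replaced by :data:`UNKNOWN_SYMBOL`; the number of
    replacements is logged.  Raises ``ValueError`` on an empty sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    upper = sequence.upper()
    cleaned = "".join(c if c in AMINO_ACIDS else UNKNOWN_SYMBOL for c in upper)
    n_replaced = sum(1 for a, b in zip(upper, cleaned) if a != b)
    if n_replaced:
        logger.info("sanitize: replaced %d non-standard residue(s)", n_replaced)
    if not cleaned:
        raise ValueError("sequence empty after sanitization")
    return cleaned


def read_fasta(path: str | Path, sanitize_sequences: bool = True) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, in file order.

    Labels are left unset; attach them with :func:`read_labels` /
    :func:`attach_labels`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq)
        if sanitize_sequences:
            seq = sanitize(seq)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (id<TAB>label in {0,1}) into a dict."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>0|1', got {line!r}")
            labels[parts[0]] = int(parts[1])
    return labels


def write_labels(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.label is None:
                raise ValueError(f"record {rec.id!r} has no label")
            fh.write(f"{rec.id}\t{rec.label}\n")


def attach_labels(records: Sequence[ProteinRecord], labels: dict[str, int]) -> None:
    """Set record labels in place from an id->label mapping."""
    for rec in records:
        if rec.id in labels:
            rec.label = labels[rec.id]


def read_residue_annotations(path: str | Path) -> dict[str, dict[int, int]]:
    """Read per-residue binary annotations.

    Format: TSV with columns (id, 1-based position, label in {0,1}).
    Returns ``{id: {position: label}}``.
    """
    out: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            seq_id, pos, lab = parts[0], int(parts[1]), int(parts[2])
            if pos < 1 or lab not in (0, 1):
                raise ValueError(f"{path}:{lineno}: bad position/label {line!r}")
            out.setdefault(seq_id, {})[pos] = lab
    return out


@dataclass
class EncodedBatch:
    """A padded, length-sorted batch of encoded sequences.

    Rows are sorted by descending sequence length (stable, so equal
    lengths keep input order); ``permutation[k]`` gives the index of row
    ``k`` in the original input, so model outputs can be restored to
    input order.
    """

    token_matrix: np.ndarray  # (B, L_max) int64, PAD beyond each length
    lengths: np.ndarray  # (B,) int64, true lengths
    mask: np.ndarray  # (B, L_max) float64, 1 for real residues
    permutation: np.ndarray  # (B,) int64, row -> original input index
    ids: list[str] = field(default_factory=list)

    @property
    def batch_size(self) -> int:
        return self.token_matrix.shape[0]

    @property
    def max_length(self) -> int:
        return self.token_matrix.shape[1]


def encode_batch(
    records: Sequence[ProteinRecord],
    vocab: Vocabulary = DEFAULT_VOCABULARY,
) -> EncodedBatch:
    """Encode records into a padded batch sorted by descending length."""
    if len(records) == 0:
        raise ValueError("cannot encode an empty collection of records")
    lengths_in = np.array([len(r) for r in records], dtype=np.int64)
    # stable argsort on negated lengths keeps input order among ties
    order = np.argsort(-lengths_in, kind="stable")
    l_max = int(lengths_in.max())
    tokens = np.full((len(records), l_max), vocab.pad_index, dtype=np.int64)
    mask = np.zeros((len(records), l_max), dtype=np.float64)
    for row, orig in enumerate(order):
        enc = vocab.encode(records[orig].sequence)
        tokens[row, : enc.size] = enc
        mask[row, : enc.size] = 1.0
    return EncodedBatch(
        token_matrix=tokens,
        lengths=lengths_in[order],
        mask=mask,
        permutation=order,
        ids=[records[i].id for i in order],
    )


def decode_batch(batch: EncodedBatch, vocab: Vocabulary = DEFAULT_VOCABULARY) -> list[str]:
    """Recover the sequences of a batch, restored to input order."""
    out: list[str | None] = [None] * batch.batch_size
    for row in range(batch.batch_size):
        n = int(batch.lengths[row])
        out[batch.permutation[row]] = vocab.decode(batch.token_matrix[row, :n])
    return out  # type: ignore[return-value]
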