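"""Sequence parsing, validation, FASTA I/O and display chunking.

Input text is cleaned (whitespace and digits stripped, letters uppercased)
and then validated against the 23-letter alphabet: the 20 canonical
residues plus the ambiguity codes B (Asn/Asp), X (unspecified) and
Z (Gln/Glu).  Invalid residues raise a positioned error rather than being
silently accepted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import CANONICAL_ORDER

AMBIGUOUS: str = "BXZ"
ALPHABET: frozenset[str] = frozenset(CANONICAL_ORDER + AMBIGUOUS)


class SequenceError(ValueError):
    """Base class for sequence validation failures."""


class EmptySequenceError(SequenceError):
    """Raised when input contains no residues after cleaning."""


class InvalidResidueError(SequenceError):
    """Raised for a character outside the 23-letter alphabet.

    Carries the offending character and its 1-based position in the
    cleaned sequence.
    """

    def __init__(self, residue: str, position: int, seq_id: str = ""):
        self.residue = residue
        self.position = position
        self.seq_id = seq_id
        where = f" in record '{seq_id}'" if seq_id else ""
        super().__init__(
            f"invalid residue {residue!r} at position {position}{where}"
        )


class EmptyRecordError(SequenceError):
    """Raised for a FASTA record whose header has no sequence body."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated one-letter-code residue string with an identifier."""

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptySequenceError("empty sequence")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in ALPHABET:
                raise InvalidResidueError(ch, i, self.seq_id)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    @property
    def has_ambiguous(self) -> bool:
        """True when any B, X or Z is present."""
        return any(ch in AMBIGUOUS for ch in self.residues)

    @property
    def has_unspecified(self) -> bool:
        """True when any X (fully unspecified residue) is present."""
        return "X" in self.residues


@dataclass(frozen=True)
class SequenceBlockView:
    """Sequence split into fixed-width display blocks (default 10)."""

    blocks: tuple[str, ...]
    block_width: int

    def __str__(self) -> str:
        return " ".join(self.blocks)


def parse_sequence(raw: str, seq_id: str = "") -> ProteinSequence:
    """Clean pasted text into a validated :class:`ProteinSequence`.

    Whitespace and digits are stripped and letters uppercased; anything
    left outside the 23-letter alphabet (including ``*``) raises
    :class:`InvalidResidueError` with its 1-based position.
    """
    cleaned = "".join(
        ch for ch in raw if not (ch.isspace() or ch.isdigit())
    ).upper()
    if not cleaned:
        raise EmptySequenceError(
            f"empty sequence{f' in record {seq_id!r}' if seq_id else ''}"
        )
    return ProteinSequence(seq_id=seq_id, residues=cleaned)


def read_fasta(source: str | Path | TextIO) -> list[ProteinSequence]:
    """Read FASTA text (or a bare headerless sequence) into records.

    ``source`` may be an open text stream, a path to a file, or the text
    itself.  Text that does not start with ``>`` is treated as one bare
    sequence with an empty id.  Headers with an empty body raise
    :class:`EmptyRecordError`.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str):
        p = Path(source)
        # A string is a path only if it plausibly names an existing file.
        text = p.read_text() if "\n" not in source and p.is_file() else source
    else:
        text = source.read()

    stripped = text.lstrip()
    if not stripped:
        raise EmptySequenceError("empty sequence")
    if not stripped.startswith(">"):
        return [parse_sequence(text)]

    records: list[ProteinSequence] = []
    for rec in SeqIO.parse(io.StringIO(stripped), "fasta"):
        body = str(rec.seq)
        header = rec.description
        if not body:
            raise EmptyRecordError(f"empty record for header '{header}'")
        records.append(parse_sequence(body, seq_id=header))
    if not records:
        raise EmptyRecordError("no FASTA records found")
    return records


def write_fasta(records: Sequence[ProteinSequence], dest: str | Path | TextIO) -> None:
    """Write records as FASTA with 60-column wrapping.

    Records with an empty id get a synthesized ``seq<n>`` header (1-based
    position in the list), so output is always valid FASTA.
    """
    if not records:
        raise ValueError("no records to write")
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.seq_id or f"seq{i}", description="")
        for i, r in enumerate(records, start=1)
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            SeqIO.write(seq_records, fh, "fasta")
    else:
        SeqIO.write(seq_records, dest, "fasta")


def chunk_sequence(seq: ProteinSequence, block_width: int = 10) -> SequenceBlockView:
    """Split a sequence into display blocks of ``block_width`` residues."""
    if block_width < 1:
        raise ValueError(f"block_width must be >= 1, got {block_width}")
    s = seq.residues
    blocks = tuple(s[i:i + block_width] for i in range(0, len(s), block_width))
    return SequenceBlockView(blocks=blocks, block_width=block_width)
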