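"""Sequence I/O and shared nucleotide conventions.

All modules in this package share the conventions defined here:

* sequences are upper-case strings over ``{A, C, G, T, N}`` (``U`` is
  converted to ``T`` on input; other IUPAC ambiguity codes are rejected,
  because deaminase editing logic is only defined on concrete bases);
* coordinates are 0-based half-open internally and 1-based inclusive in
  every user-facing table;
* FASTQ qualities are Phred+33 (the encoding emitted by modern Illumina
  instruments).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""

    def __init__(self, char: str, offset: int, context: str = ""):
        self.char = char
        self.offset = offset
        where = f" in {context}" if context else ""
        super().__init__(
            f"disallowed character {char!r} at offset {offset}{where} "
            "(allowed: A, C, G, T, N)"
        )


class FastaParseError(ValueError):
    pass


class FastqParseError(ValueError):
    pass


def normalize_bases(raw: str, context: str = "") -> str:
    """Upper-case, map U->T, and validate the alphabet."""
    bases = raw.upper().replace("U", "T")
    for i, ch in enumerate(bases):
        if ch not in ALPHABET:
            raise SequenceAlphabetError(ch, i, context)
    return bases


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    bases: str

    def __post_init__(self):
        object.__setattr__(self, "bases", normalize_bases(self.bases, self.id))

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, revcomp(self.bases))


def revcomp(bases: str) -> str:
    """Watson-Crick reverse complement of a plain base string; N maps to N."""
    for i, ch in enumerate(bases):
        if ch not in ALPHABET:
            raise SequenceAlphabetError(ch, i)
    return bases.translate(_COMPLEMENT)[::-1]


def reverse_complement(seq: NucSequence) -> NucSequence:
    """Reverse complement of a :class:`NucSequence` (involution)."""
    return seq.reverse_complement()


@dataclass(frozen=True)
class CdsRecord:
    """A protein-coding sequence as read from a CDS FASTA.

    Records whose length is not a multiple of three (or that are empty)
    are *flagged* via :attr:`is_frame_valid` rather than dropped, so the
    caller can decide how to handle frame-broken gene models.
    """

    gene_id: str
    sequence: NucSequence
    length_nt: int

    @classmethod
    def from_bases(cls, gene_id: str, bases: str) -> "CdsRecord":
        seq = NucSequence(gene_id, bases)
        return cls(gene_id, seq, len(seq))

    @property
    def is_frame_valid(self) -> bool:
        return self.length_nt > 0 and self.length_nt % 3 == 0

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with Phred qualities and an optional barcode pair."""

    id: str
    bases: str
    qualities: tuple = field(default=())
    barcode_pair: Optional[tuple] = None

    def __post_init__(self):
        if len(self.qualities) != len(self.bases):
            raise FastqParseError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.qualities)} quality values"
            )
        if any(q < 0 for q in self.qualities):
            raise FastqParseError(f"read {self.id!r}: negative quality score")

    def __len__(self) -> int:
        return len(self.bases)


def read_fasta(path) -> list[CdsRecord]:
    """Read a (multi-line) FASTA file of CDS sequences.

    Record ids are the first whitespace-delimited token of each header.
    Raises :class:`FastaParseError` with a line number if the first
    non-blank line is not a header.
    """
    path = Path(path)
    with path.open() as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header starting "
                    f"with '>', got {line[:30]!r}"
                )
            break
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append(CdsRecord.from_bases(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[CdsRecord], path, width: int = 60) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence.bases), id=r.gene_id, description="")
        for r in records
    ]
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Iterate over a Phred+33 FASTQ file as :class:`ReadRecord` objects."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = tuple(rec.letter_annotations["phred_quality"])
            yield ReadRecord(rec.id, str(rec.seq).upper(), quals)
    except ValueError as exc:
        raise FastqParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with Path(path).open("w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")
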