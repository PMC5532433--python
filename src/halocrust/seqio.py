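"""Sequence I/O for the pipeline.

Thin wrappers around Biopython's SeqIO that enforce the pipeline's record
contract: non-empty unique ids, non-empty sequences, and an explicit alphabet
flag (nucleotide vs protein).  Readers are gzip-transparent.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

Alphabet = Literal["nucleotide", "protein"]

_NUC_CHARS = set("ACGTUNacgtun")


class SequenceParseError(ValueError):
    """Raised when a sequence file violates the record contract."""


@dataclass
class SequenceRecord:
    """A named sequence with an explicit alphabet flag.

    Parameters
    ----------
    id : str
        Record identifier, unique within a file.
    sequence : str
        Residues; upper-cased on construction.
    description : str
        Free-text description (the FASTA header remainder).
    alphabet : {"nucleotide", "protein"}
    quality : list of int, optional
        Phred qualities, retained for FASTQ records.
    """

    id: str
    sequence: str
    description: str = ""
    alphabet: Alphabet = "nucleotide"
    quality: list[int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceParseError("record id must be non-empty")
        if not self.sequence:
            raise SequenceParseError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        if self.alphabet == "nucleotide" and not set(self.sequence) <= _NUC_CHARS:
            bad = sorted(set(self.sequence) - _NUC_CHARS)
            raise SequenceParseError(
                f"record {self.id!r}: non-nucleotide characters {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != "nucleotide":
            raise ValueError("reverse complement requires a nucleotide record")
        return SequenceRecord(
            id=self.id,
            sequence=str(Seq(self.sequence).reverse_complement()),
            description=self.description,
            alphabet="nucleotide",
        )


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(
    path: str | Path,
    format: Literal["fasta", "fastq"] = "fasta",
    alphabet: Alphabet = "nucleotide",
) -> list[SequenceRecord]:
    """Read all records from a FASTA/FASTQ file (gzip-transparent).

    Records are returned in file order.  Duplicate ids raise
    :class:`SequenceParseError`; malformed records raise with the offending
    record named.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, format):
                if rec.id in seen:
                    raise SequenceParseError(f"duplicate record id {rec.id!r} in {path}")
                seen.add(rec.id)
                quality = rec.letter_annotations.get("phred_quality")
                desc = rec.description
                if desc.startswith(rec.id):
                    desc = desc[len(rec.id):].strip()
                records.append(
                    SequenceRecord(
                        id=rec.id,
                        sequence=str(rec.seq),
                        description=desc,
                        alphabet=alphabet,
                        quality=list(quality) if quality is not None else None,
                    )
                )
        except ValueError as exc:
            if isinstance(exc, SequenceParseError):
                raise
            raise SequenceParseError(f"malformed {format} in {path}: {exc}") from exc
    return records


def write_sequences(
    records: Iterable[SequenceRecord],
    path: str | Path,
    format: Literal["fasta", "fastq"] = "fasta",
) -> None:
    """Write records in canonical formatting (single-line FASTA sequences)."""
    bio_records = []
    for rec in records:
        bio = _BioRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        if format == "fastq":
            if rec.quality is None:
                bio.letter_annotations["phred_quality"] = [40] * len(rec.sequence)
            else:
                bio.letter_annotations["phred_quality"] = rec.quality
        bio_records.append(bio)
    with _open_text(path, "wt") as handle:
        SeqIO.write(bio_records, handle, "fasta-2line" if format == "fasta" else format)
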