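"""Shared domain types, coordinate conventions, and plain-text I/O.

Conventions used throughout the toolkit
---------------------------------------
* All coordinates are 0-based, half-open intervals on the plus strand of the
  stated template; BED output uses the same convention, so no conversion
  happens at I/O boundaries.  1-based values appear only in human-readable
  log messages and are flagged as such.
* Loci are stored on the plus strand of the supplied template.  A locus that
  is minus-strand relative to its source contig must be reverse-complemented
  by the caller before annotation.
* The data alphabet is A/C/G/T/N.  Degenerate IUPAC codes appear only in
  motif (TAM consensus) output, never in input sequences.

The domain model: a TnpB locus encodes the nuclease ORF followed by the
omegaRNA scaffold (the 3' transposon end, up to the right-end/RE boundary)
and then the guide sequence.  ``LocusRecord`` captures those three spans;
the RE boundary is the shared coordinate where the scaffold span ends and
the guide span begins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("omegakit")

# ---------------------------------------------------------------------------
# Alphabet helpers
# ---------------------------------------------------------------------------

DNA_BASES = "ACGT"
DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# uint8 encoding: A,C,G,T -> 0..3; anything else (N, gaps, padding) -> 255.
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA_BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i
_CHAR_LUT = np.frombuffer(DNA_BASES.encode("ascii"), dtype=np.uint8)

#: IUPAC degenerate nucleotide codes (motif alphabet only).
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=255)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence` for codes in 0..3."""
    return _CHAR_LUT[codes].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; the complement of N is N."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def _check_span(name: str, span: tuple[int, int], seq_len: int) -> None:
    start, end = span
    if not (0 <= start < end <= seq_len):
        raise ValueError(
            f"{name}=({start},{end}) is not a non-empty half-open interval "
            f"within [0,{seq_len})"
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusRecord:
    """A TnpB locus on the plus strand of its template.

    ``guide_span`` must begin exactly where ``scaffold_span`` ends: the
    transposon right end (RE) is the single boundary separating the omegaRNA
    scaffold from the guide.
    """

    id: str
    sequence: str
    orf_span: tuple[int, int]
    scaffold_span: tuple[int, int]
    guide_span: tuple[int, int]
    strand: str = "+"

    def __post_init__(self) -> None:
        if set(self.sequence) - DNA_ALPHABET:
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise ValueError(f"locus sequence contains non-A/C/G/T/N characters: {bad}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        n = len(self.sequence)
        _check_span("orf_span", self.orf_span, n)
        _check_span("scaffold_span", self.scaffold_span, n)
        _check_span("guide_span", self.guide_span, n)
        if self.guide_span[0] != self.scaffold_span[1]:
            raise ValueError(
                "guide_span must begin exactly at scaffold_span end "
                f"(RE boundary): guide starts at {self.guide_span[0]}, "
                f"scaffold ends at {self.scaffold_span[1]}"
            )

    @property
    def re_boundary(self) -> int:
        """The guide-scaffold (right end) boundary coordinate."""
        return self.scaffold_span[1]


@dataclass(frozen=True)
class Read:
    """A single sequencing read with optional Sanger-scale quality scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.id!r} has empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class IntervalAnnotation:
    """A labelled half-open interval on a named reference sequence."""

    ref_id: str
    start: int
    end: int
    label: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"annotation requires 0 <= start < end, got ({self.start},{self.end})"
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def _validate_fasta_lines(path: Path) -> None:
    """Pre-scan a FASTA file so malformed input fails with a line number."""
    header_line: int | None = None
    seq_seen = False
    any_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if header_line is not None and not seq_seen:
                    raise ValueError(
                        f"{path}: empty FASTA record at line {header_line}"
                    )
                if stripped == ">":
                    raise ValueError(f"{path}: empty FASTA header at line {lineno}")
                header_line = lineno
                seq_seen = False
                any_record = True
            else:
                if header_line is None:
                    raise ValueError(
                        f"{path}: sequence before any FASTA header at line {lineno}"
                    )
                seq_seen = True
    if header_line is not None and not seq_seen:
        raise ValueError(f"{path}: empty FASTA record at line {header_line}")
    if not any_record:
        raise ValueError(f"{path}: no FASTA records found")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as ``[(id, sequence), ...]`` in file order.

    Sequences are upper-cased; RNA input (U) is converted to DNA (T) with a
    logged note.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            logger.info("read_fasta: converted RNA (U) to DNA (T) in record %s", rec.id)
            seq = seq.replace("U", "T")
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[Read]:
    """Read a 4-line FASTQ file (Sanger quality encoding) as Read objects."""
    path = Path(path)
    reads: list[Read] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                Read(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path, default_quality: int = 40) -> None:
    """Write reads as FASTQ; reads without qualities get a constant score."""
    records = []
    for read in reads:
        quals = list(read.qualities) if read.qualities is not None else [default_quality] * len(read.sequence)
        rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
        rec.letter_annotations["phred_quality"] = quals
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# BED / TSV / JSON
# ---------------------------------------------------------------------------

def write_bed(annotations: Sequence[IntervalAnnotation], path: str | Path) -> None:
    """Write annotations as BED (0-based half-open, matching the internal
    convention).  Score-less annotations produce 4-column lines; scored ones
    produce 6 columns with '.' strand."""
    with open(path, "w") as fh:
        for ann in annotations:
            if ann.score is None:
                fh.write(f"{ann.ref_id}\t{ann.start}\t{ann.end}\t{ann.label}\n")
            else:
                fh.write(
                    f"{ann.ref_id}\t{ann.start}\t{ann.end}\t{ann.label}\t"
                    f"{ann.score:g}\t.\n"
                )


def read_bed(path: str | Path) -> list[IntervalAnnotation]:
    out: list[IntervalAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            score = float(parts[4]) if len(parts) >= 5 else None
            out.append(
                IntervalAnnotation(
                    ref_id=parts[0], start=int(parts[1]), end=int(parts[2]),
                    label=parts[3], score=score,
                )
            )
    return out


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with a header row and no index column."""
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj: object, path: str | Path) -> None:
    """Schema-stable JSON: sorted keys, fixed indentation, trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> object:
    with open(path) as fh:
        return json.load(fh)
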