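"""Sequence and feature I/O with a single coordinate convention.

Everything downstream works in 0-based half-open coordinates on the forward
axis of the reference sequence.  The only places where 1-based inclusive
GFF3 coordinates appear are :func:`read_features` and :func:`write_features`;
BED input is already half-open and passes through unchanged.

Sequences are uppercased on ingest and restricted to the DNA alphabet
``{A, C, G, T, N}``; soft-masking case information is deliberately discarded
(masking analyses are driven by explicit feature files instead).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable
from urllib.parse import quote, unquote

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence over {A,C,G,T,N}, uppercase."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence of {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence with a strand.

    ``strand`` is '+', '-' or '.' (unstranded).
    """

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval {self.start}..{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with another interval on the same seqid (0 if none)."""
        if self.seqid != other.seqid:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.seqid, self.start + offset, self.end + offset, self.strand)


@dataclass
class Feature:
    """A GenomicInterval plus the dialect-independent annotation payload."""

    interval: GenomicInterval
    type: str = "region"
    score: float | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.attributes.get("ID", self.attributes.get("Name", "."))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a multi-record FASTA file, validating the DNA alphabet.

    Lowercase bases are folded to uppercase.  Raises :class:`FormatError` on
    an empty file, duplicate record ids, or a character outside
    ``{A,C,G,T,N}`` (case-insensitive), naming the record and 1-based
    position of the first offender.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for pos, base in enumerate(seq, start=1):
            if base not in DNA_ALPHABET:
                raise FormatError(
                    f"illegal character {base!r} at position {pos} of record {rec.id!r}"
                )
        if not seq:
            raise FormatError(f"record {rec.id!r} has an empty sequence")
        records.append(SeqRecord(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / BED feature files
# ---------------------------------------------------------------------------

_GFF_ESCAPE_SAFE = ":/ ?&,|^*!"  # characters NOT escaped in attribute values


def _parse_gff3_line(line: str, lineno: int) -> Feature:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 9:
        raise FormatError(f"line {lineno}: expected 9 GFF3 columns, got {len(cols)}")
    seqid, source, ftype, start_s, end_s, score_s, strand, _phase, attr_s = cols
    try:
        start1, end1 = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer coordinates") from exc
    if start1 > end1:
        raise FormatError(f"line {lineno}: start {start1} > end {end1}")
    if strand not in STRANDS:
        raise FormatError(f"line {lineno}: unknown strand symbol {strand!r}")
    score = None if score_s == "." else float(score_s)
    attributes: dict[str, str] = {}
    if attr_s not in (".", ""):
        for pair in attr_s.split(";"):
            if not pair:
                continue
            key, _, value = pair.partition("=")
            attributes[unquote(key)] = unquote(value)
    if source not in (".", "g4telo"):
        attributes.setdefault("source", source)
    # GFF3 is 1-based inclusive; internal is 0-based half-open.
    interval = GenomicInterval(seqid, start1 - 1, end1, strand)
    return Feature(interval=interval, type=ftype, score=score, attributes=attributes)


def _parse_bed_line(line: str, lineno: int) -> Feature:
    cols = line.rstrip("\n").split()
    if len(cols) < 3:
        raise FormatError(f"line {lineno}: BED needs >= 3 columns")
    seqid = cols[0]
    try:
        start, end = int(cols[1]), int(cols[2])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer coordinates") from exc
    if start >= end:
        raise FormatError(f"line {lineno}: start {start} >= end {end}")
    strand = cols[5] if len(cols) > 5 else "."
    if strand not in STRANDS:
        raise FormatError(f"line {lineno}: unknown strand symbol {strand!r}")
    attributes: dict[str, str] = {}
    if len(cols) > 3 and cols[3] != ".":
        attributes["Name"] = cols[3]
    score = None
    if len(cols) > 4 and cols[4] != ".":
        score = float(cols[4])
    return Feature(
        interval=GenomicInterval(seqid, start, end, strand),
        type="region",
        score=score,
        attributes=attributes,
    )


def read_features(path: str | Path, dialect: str = "gff3") -> list[Feature]:
    """Parse a GFF3 or BED file into internal 0-based half-open features."""
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parser = _parse_gff3_line if dialect == "gff3" else _parse_bed_line
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#") or (
                dialect == "bed" and line.startswith(("track", "browser"))
            ):
                continue
            features.append(parser(line, lineno))
    return features


def _format_gff3_attributes(attributes: dict[str, str]) -> str:
    if not attributes:
        return "."
    return ";".join(
        f"{quote(k, safe=_GFF_ESCAPE_SAFE)}={quote(v, safe=_GFF_ESCAPE_SAFE)}"
        for k, v in attributes.items()
    )


def write_features(
    features: Iterable[Feature], path: str | Path | io.TextIOBase, dialect: str = "gff3"
) -> None:
    """Write features, converting back to the dialect's native coordinates.

    Round-trip guarantee: ``read_features(write_features(F)) == F`` for
    coordinates, strand, score and attributes.
    """
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown dialect {dialect!r}")
    own = not isinstance(path, io.TextIOBase)
    fh = open(path, "w") if own else path
    try:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for f in features:
                iv = f.interval
                score = "." if f.score is None else format(f.score, "g")
                fh.write(
                    "\t".join(
                        [
                            iv.seqid,
                            "g4telo",
                            f.type,
                            str(iv.start + 1),
                            str(iv.end),
                            score,
                            iv.strand,
                            ".",
                            _format_gff3_attributes(f.attributes),
                        ]
                    )
                    + "\n"
                )
        else:
            for f in features:
                iv = f.interval
                name = f.attributes.get("Name", f.attributes.get("ID", "."))
                score = "." if f.score is None else format(f.score, "g")
                fh.write(
                    f"{iv.seqid}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
    finally:
        if own:
            fh.close()
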