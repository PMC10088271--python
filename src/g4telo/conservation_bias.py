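"""DNA-versus-amino-acid conservation bias of coding alignments.

Retrotransposon *gag* genes can be more conserved at the DNA level than the
protein level would require — a signature expected where DNA structure
(e.g. quadruplex-forming potential) is itself under selection.  This module
quantifies that bias: mean pairwise DNA identity, amino-acid identity and
BLOSUM62 similarity over all sequence pairs of a codon-threaded alignment,
whole or restricted to alignment-column regions (such as the weakly
conserved N-terminal fragment versus the conserved core of GAG).

Definitions
-----------
identity
    percent of pair-gap-free columns where the two rows agree; columns with
    a gap (or X) in either row are excluded from numerator and denominator
    (pairwise deletion).
similarity
    percent of pair-gap-free amino-acid columns whose BLOSUM62 score is
    strictly positive (the convention used by common alignment viewers).

``diff_identity = DNA - AA identity`` is negative when DNA is the *less*
conserved level (the usual case: synonymous changes hit DNA only) and grows
toward zero or positive where DNA conservation overrides the protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .seqio import GenomicInterval

BLOSUM62 = substitution_matrices.load("BLOSUM62")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ThreadingError(ValueError):
    """CDS cannot be threaded onto its protein alignment row."""


class UndefinedComparisonError(ValueError):
    """No comparable (pair-gap-free) columns between two rows."""


@dataclass(frozen=True)
class ProteinMSA:
    """A protein multiple alignment: equal-length rows over AA + 'X' + '-'."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        ncol = len(self.rows[0])
        if ncol < 1 or any(len(r) != ncol for r in self.rows):
            raise ValueError("rows must be non-empty and equal length")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - AA_LETTERS - {"X", "-", "*"}
            if bad:
                raise ValueError(f"row {rid!r} has illegal symbols {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class CodonMSA:
    """A protein alignment threaded back onto in-frame coding DNA.

    Each protein column maps to three DNA columns; protein gaps are '---'.
    """

    ids: tuple[str, ...]
    codon_rows: tuple[str, ...]
    protein: ProteinMSA

    def __post_init__(self) -> None:
        expected = 3 * self.protein.n_columns
        for rid, row in zip(self.ids, self.codon_rows):
            if len(row) != expected:
                raise ValueError(f"codon row {rid!r} length {len(row)} != {expected}")

    @property
    def n_columns(self) -> int:
        return self.protein.n_columns

    def slice(self, region: "RegionSpec") -> "CodonMSA":
        s, e = region.columns
        prot = ProteinMSA(self.protein.ids, tuple(r[s:e] for r in self.protein.rows))
        return CodonMSA(self.ids, tuple(r[3 * s : 3 * e] for r in self.codon_rows), prot)


@dataclass(frozen=True)
class RegionSpec:
    """A named interval of protein-alignment columns (0-based half-open)."""

    name: str
    columns: tuple[int, int]

    def __post_init__(self) -> None:
        s, e = self.columns
        if s < 0 or e <= s:
            raise ValueError(f"bad region columns {self.columns}")


@dataclass(frozen=True)
class ConservationReport:
    mean_dna_identity: float
    mean_aa_identity: float
    mean_aa_similarity: float
    diff_identity: float
    diff_similarity: float
    n_pairs: int


def thread_codons(protein_msa: ProteinMSA, cds: Mapping[str, str]) -> CodonMSA:
    """Thread ungapped CDS back through a protein alignment ("alignment by
    translation").

    Each CDS must be exactly 3x the ungapped protein length after trimming
    one terminal stop codon if present, and must translate to the aligned
    amino acids (X matches any codon).
    """
    codon_rows: list[str] = []
    for rid, aa_row in zip(protein_msa.ids, protein_msa.rows):
        if rid not in cds:
            raise ThreadingError(f"no CDS provided for {rid!r}")
        dna = cds[rid].upper()
        ungapped = aa_row.replace("-", "")
        if len(dna) % 3 == 0 and len(dna) // 3 == len(ungapped) + 1 and dna[-3:] in STOP_CODONS:
            dna = dna[:-3]
        if len(dna) != 3 * len(ungapped):
            raise ThreadingError(
                f"CDS length mismatch for {rid!r}: {len(dna)} nt vs "
                f"{len(ungapped)} aligned residues"
            )
        row_parts: list[str] = []
        codon_i = 0
        for aa in aa_row:
            if aa == "-":
                row_parts.append("---")
                continue
            codon = dna[3 * codon_i : 3 * codon_i + 3]
            codon_i += 1
            if aa not in ("X", "*"):
                translated = str(Seq(codon).translate())
                if translated != aa:
                    raise ThreadingError(
                        f"codon {codon} at residue {codon_i} of {rid!r} "
                        f"translates to {translated}, alignment says {aa}"
                    )
            row_parts.append(codon)
        codon_rows.append("".join(row_parts))
    return CodonMSA(protein_msa.ids, tuple(codon_rows), protein_msa)


def _comparable(a: str, b: str) -> bool:
    return a not in ("-", "X") and b not in ("-", "X")


def pairwise_identity(row_i: str, row_j: str) -> float:
    """Percent identical columns among columns gap-free in both rows."""
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    same = total = 0
    for a, b in zip(row_i, row_j):
        if not _comparable(a, b):
            continue
        total += 1
        if a == b:
            same += 1
    if total == 0:
        raise UndefinedComparisonError("no comparable columns")
    return 100.0 * same / total


def pairwise_similarity(aa_row_i: str, aa_row_j: str, matrix=BLOSUM62) -> float:
    """Percent of gap-free AA columns scoring > 0 under the matrix."""
    if len(aa_row_i) != len(aa_row_j):
        raise ValueError("rows differ in length")
    positive = total = 0
    for a, b in zip(aa_row_i, aa_row_j):
        if not _comparable(a, b):
            continue
        total += 1
        if matrix[a, b] > 0:
            positive += 1
    if total == 0:
        raise UndefinedComparisonError("no comparable columns")
    return 100.0 * positive / total


def report(codon_msa: CodonMSA, region: RegionSpec | None = None) -> ConservationReport:
    """Mean pairwise DNA identity, AA identity and AA similarity.

    DNA identity is computed on the codon-threaded rows so that DNA and AA
    statistics cover exactly the same residues; a region restricts both via
    the 3x column mapping.
    """
    msa = codon_msa.slice(region) if region else codon_msa
    dna_rows = msa.codon_rows
    aa_rows = msa.protein.rows
    dna_id: list[float] = []
    aa_id: list[float] = []
    aa_sim: list[float] = []
    pairs = list(combinations(range(len(aa_rows)), 2))
    for i, j in pairs:
        # mask DNA columns of residues that are X in either protein row, so
        # DNA and AA statistics exclude the same positions
        di, dj = [], []
        for col, (a, b) in enumerate(zip(aa_rows[i], aa_rows[j])):
            if a == "X" or b == "X":
                continue
            di.append(dna_rows[i][3 * col : 3 * col + 3])
            dj.append(dna_rows[j][3 * col : 3 * col + 3])
        dna_id.append(pairwise_identity("".join(di), "".join(dj)))
        aa_id.append(pairwise_identity(aa_rows[i], aa_rows[j]))
        aa_sim.append(pairwise_similarity(aa_rows[i], aa_rows[j]))
    n = len(pairs)
    mean_dna = sum(dna_id) / n
    mean_aa = sum(aa_id) / n
    mean_sim = sum(aa_sim) / n
    return ConservationReport(
        mean_dna_identity=mean_dna,
        mean_aa_identity=mean_aa,
        mean_aa_similarity=mean_sim,
        diff_identity=mean_dna - mean_aa,
        diff_similarity=mean_dna - mean_sim,
        n_pairs=n,
    )


def count_pqs_by_region(
    pqs_intervals: Sequence[GenomicInterval], regions: Sequence[RegionSpec]
) -> dict[str, int]:
    """Count PQS per CDS region; boundary-straddlers count for every region
    they touch (deliberate double counting, reported as such).

    ``pqs_intervals`` are on CDS nucleotide coordinates; ``regions`` are
    protein-column intervals, converted via the 3x mapping.
    """
    counts = {r.name: 0 for r in regions}
    for iv in pqs_intervals:
        for r in regions:
            nt_start, nt_end = 3 * r.columns[0], 3 * r.columns[1]
            if iv.start < nt_end and iv.end > nt_start:
                counts[r.name] += 1
    return counts
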