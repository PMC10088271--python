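"""Codon-level selection signatures: NG86 dN/dS, delta-GC, GC3/C3 stats.

The Nei-Gojobori (1986) counting method estimates synonymous (S) and
nonsynonymous (N) site totals per codon, counts synonymous and
nonsynonymous differences between codon pairs by averaging over all equally
weighted mutational pathways, and corrects the raw proportions ps = Sd/S and
pn = Nd/N for multiple hits with the Jukes-Cantor transform
``d = -(3/4) ln(1 - (4/3) p)``.  dn/ds below one indicates purifying
selection on the protein; elevated synonymous constraint (or biased codon
choice) can indicate selection acting on the DNA itself, e.g. to preserve
quadruplex-forming potential.

Stop-codon handling (stated for reproducibility): single-nucleotide changes
into stop codons are excluded from both numerator and denominator of the
per-position site fractions, and mutational pathways passing through a stop
codon are dropped with the remaining pathways re-weighted equally.

delta-GC compares each codon's GC content with the mean GC of its full
synonymous family; codon sets inside predicted-quadruplex loci preferring
GC-rich variants (and cytosine at the third position on the coding strand)
mirror G-richness of the template strand where antisense PQS reside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations
from typing import Mapping, Sequence

from Bio.Data import CodonTable

from .conservation_bias import CodonMSA, RegionSpec
from .seqio import GenomicInterval

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))

#: amino acid -> tuple of synonymous codons (standard nuclear code)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

_BASES = "ACGT"

RATIO_UNDEFINED = float("nan")
RATIO_INFINITE = float("inf")


class SaturationError(ValueError):
    """Observed proportion of differences too high for Jukes-Cantor."""


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    if codon not in CODON_TO_AA:
        raise ValueError(f"invalid codon {codon!r}")
    return codon


@dataclass(frozen=True)
class CodonSite:
    """One codon of a CDS with its translation and PQS-locus flag."""

    codon: str
    aa: str
    position_index: int
    in_pqs: bool

    def __post_init__(self) -> None:
        if CODON_TO_AA.get(self.codon) != self.aa:
            raise ValueError(f"aa {self.aa!r} does not match codon {self.codon}")


@dataclass(frozen=True)
class DnDsResult:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ds: float
    dn: float
    ratio: float  # dn/ds; nan when ds == dn == 0, inf when ds == 0 < dn


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous site counts of one codon.

    Per position, the synonymous fraction is (# synonymous single-base
    changes) / (# changes not creating a stop); changes to stop codons are
    excluded from numerator and denominator.  S + N = 3 always.
    """
    codon = _check_codon(codon)
    aa = CODON_TO_AA[codon]
    s_total = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        # a position where every change creates a stop contributes nothing
        s_total += syn / valid if valid else 0.0
    return s_total, 3.0 - s_total


@lru_cache(maxsize=None)
def _codon_pair_diffs(codon_i: str, codon_j: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged over all stop-free mutational pathways, equally weighted."""
    diff_pos = [p for p in range(3) if codon_i[p] != codon_j[p]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    path_syn: list[int] = []
    path_non: list[int] = []
    for order in permutations(diff_pos):
        cur = codon_i
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_j[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            path_syn.append(syn)
            path_non.append(non)
    if not path_syn:
        # every pathway passes a stop: count all changes as nonsynonymous
        return 0.0, float(k)
    n = len(path_syn)
    return sum(path_syn) / n, sum(path_non) / n


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); raises SaturationError for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} is at or beyond JC saturation (3/4)")
    return -0.75 * math.log(1.0 - p * 4.0 / 3.0) + 0.0  # avoid -0.0 at p=0


def _iter_codon_pairs(cds_i: str, cds_j: str):
    if len(cds_i) != len(cds_j):
        raise ValueError("sequences differ in length")
    if len(cds_i) % 3:
        raise ValueError("length not a multiple of 3")
    for k in range(0, len(cds_i), 3):
        ci, cj = cds_i[k : k + 3].upper(), cds_j[k : k + 3].upper()
        if "-" in ci or "-" in cj or "N" in ci or "N" in cj:
            continue
        yield ci, cj


def ng86_pairwise(cds_i: str, cds_j: str) -> DnDsResult:
    """NG86 dN/dS between two in-frame CDS (gapped/N codon pairs skipped).

    Site counts are averaged over the two sequences; differences are
    pathway-averaged per codon pair; ds/dn are Jukes-Cantor corrected.
    """
    S = N = Sd = Nd = 0.0
    any_codon = False
    for ci, cj in _iter_codon_pairs(cds_i, cds_j):
        si, ni = ng86_site_counts(ci)
        sj, nj = ng86_site_counts(cj)
        S += (si + sj) / 2.0
        N += (ni + nj) / 2.0
        sd, nd = _codon_pair_diffs(ci, cj)
        Sd += sd
        Nd += nd
        any_codon = True
    if not any_codon:
        raise ValueError("no comparable codon pairs")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    if ds > 0:
        ratio = dn / ds
    elif dn > 0:
        ratio = RATIO_INFINITE
    else:
        ratio = RATIO_UNDEFINED
    return DnDsResult(S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, ds=ds, dn=dn, ratio=ratio)


@dataclass(frozen=True)
class RegionDnDs:
    """Per-region pairwise-mean dN/dS summary."""

    region: str
    mean_ds: float
    mean_dn: float
    mean_ratio: float  # over pairs with a finite defined ratio; nan if none
    n_pairs: int
    n_undefined: int  # pairs whose ratio was nan/inf, excluded from the mean


def dnds_alignment(
    codon_msa: CodonMSA, regions: Sequence[RegionSpec] | None = None
) -> list[RegionDnDs]:
    """Mean pairwise ds, dn and dn/ds per region of a codon alignment.

    Pairs with an undefined or infinite ratio are excluded from the ratio
    mean and counted in ``n_undefined``.
    """
    if regions is None:
        regions = [RegionSpec("all", (0, codon_msa.n_columns))]
    out: list[RegionDnDs] = []
    for region in regions:
        sub = codon_msa.slice(region)
        ds_vals: list[float] = []
        dn_vals: list[float] = []
        ratios: list[float] = []
        undefined = 0
        n_pairs = 0
        for i, j in combinations(range(len(sub.codon_rows)), 2):
            res = ng86_pairwise(sub.codon_rows[i], sub.codon_rows[j])
            n_pairs += 1
            ds_vals.append(res.ds)
            dn_vals.append(res.dn)
            if math.isfinite(res.ratio):
                ratios.append(res.ratio)
            else:
                undefined += 1
        mean_ratio = sum(ratios) / len(ratios) if ratios else float("nan")
        out.append(
            RegionDnDs(
                region=region.name,
                mean_ds=sum(ds_vals) / n_pairs,
                mean_dn=sum(dn_vals) / n_pairs,
                mean_ratio=mean_ratio,
                n_pairs=n_pairs,
                n_undefined=undefined,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Codon composition statistics
# ---------------------------------------------------------------------------

def gc_content(codon: str) -> float:
    return sum(1 for b in codon if b in "GC") / 3.0


def delta_gc(codon: str) -> float:
    """GC of the codon minus the mean GC of its full synonymous family."""
    codon = _check_codon(codon)
    family = SYNONYMOUS_FAMILIES[CODON_TO_AA[codon]]
    family_mean = sum(gc_content(c) for c in family) / len(family)
    return gc_content(codon) - family_mean


def synonymous_family_gc(aa: str) -> float:
    """Mean GC content over the amino acid's full synonymous codon family."""
    family = SYNONYMOUS_FAMILIES[aa]
    return sum(gc_content(c) for c in family) / len(family)


def partition_by_pqs(
    cds: str, pqs_intervals: Sequence[GenomicInterval]
) -> tuple[list[CodonSite], list[CodonSite]]:
    """Split a CDS into PQS-locus and non-PQS codons.

    A codon belongs to the PQS set iff it overlaps any PQS interval (on CDS
    nucleotide coordinates) by >= 1 bp.  The partition is exhaustive and
    disjoint.  Codons containing N and stop codons are dropped.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    pqs: list[CodonSite] = []
    nonpqs: list[CodonSite] = []
    for idx in range(len(cds) // 3):
        codon = cds[3 * idx : 3 * idx + 3]
        if "N" in codon or codon in STOP_CODONS:
            continue
        start, end = 3 * idx, 3 * idx + 3
        inside = any(iv.start < end and iv.end > start for iv in pqs_intervals)
        site = CodonSite(codon=codon, aa=CODON_TO_AA[codon], position_index=idx, in_pqs=inside)
        (pqs if inside else nonpqs).append(site)
    return pqs, nonpqs


def codon_position_stats(
    pqs_codons: Sequence[CodonSite],
    nonpqs_codons: Sequence[CodonSite],
    amino_acids: Sequence[str] = ("P",),
) -> Mapping[str, float]:
    """Third-position cytosine and amino-acid usage ratios, PQS vs non-PQS.

    Returns ``C3_pqs``, ``C3_nonpqs``, ``C3_ratio`` and one
    ``aa_freq_ratio(<aa>)`` entry per requested amino acid (frequency in the
    PQS set over frequency in the non-PQS set).  A zero denominator yields
    an infinite sentinel; empty partitions raise.
    """
    if not pqs_codons or not nonpqs_codons:
        raise ValueError("both partitions must be non-empty")
    c3_pqs = sum(1 for s in pqs_codons if s.codon[2] == "C") / len(pqs_codons)
    c3_non = sum(1 for s in nonpqs_codons if s.codon[2] == "C") / len(nonpqs_codons)
    stats: dict[str, float] = {
        "C3_pqs": c3_pqs,
        "C3_nonpqs": c3_non,
        "C3_ratio": c3_pqs / c3_non if c3_non > 0 else RATIO_INFINITE,
    }
    for aa in amino_acids:
        f_pqs = sum(1 for s in pqs_codons if s.aa == aa) / len(pqs_codons)
        f_non = sum(1 for s in nonpqs_codons if s.aa == aa) / len(nonpqs_codons)
        stats[f"aa_freq_ratio({aa})"] = f_pqs / f_non if f_non > 0 else RATIO_INFINITE
    return stats
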