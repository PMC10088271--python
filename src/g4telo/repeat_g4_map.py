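"""Strand-aware intersection of PQS hits with repeat annotations.

Implements the bookkeeping behind per-repeat-class quadruplex statistics:
pairing each PQS with every overlapping repeat copy (bedtools-intersect
semantics: a PQS spanning two adjacent repeats yields two records),
sense/antisense orientation classification relative to the element's coding
strand, PQS density per 10 kbp with N-correction, and base-pair proportion
of PQS within repeat fragments.

Counting conventions: the *midpoint rule* assigns a PQS to a region for
density/partition counting (no double counting at region boundaries);
full-overlap base pairs are used for bp_proportion, which normalises by
sequence length rather than by hit count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .seqio import Feature, GenomicInterval
from .pqs_scan import PQSHit


class UndefinedDensityError(ValueError):
    """Region has zero effective (non-N) length."""


@dataclass(frozen=True)
class RepeatFeature:
    """One annotated element copy or fragment.

    ``interval.strand`` is the element's coding-strand orientation on the
    chromosome and must be '+' or '-'.
    """

    interval: GenomicInterval
    family: str
    clade: str = ""
    element_id: str = ""
    is_fragment: bool = False

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("repeat strand must be + or -")
        if not self.family:
            raise ValueError("repeat family must be non-empty")


def repeat_from_feature(feature: Feature) -> RepeatFeature:
    """Build a RepeatFeature from a parsed GFF/BED feature (verbatim attrs)."""
    attrs = feature.attributes
    return RepeatFeature(
        interval=feature.interval,
        family=attrs.get("family", attrs.get("Name", feature.type)),
        clade=attrs.get("clade", ""),
        element_id=attrs.get("element_id", attrs.get("ID", "")),
        is_fragment=attrs.get("is_fragment", "false").lower() in ("1", "true", "yes"),
    )


@dataclass(frozen=True)
class OrientationRecord:
    """A (PQS, repeat) overlap pair with relative orientation.

    ``sense`` means the G-rich strand of the PQS is the element's coding
    strand; ``antisense`` means it is the template strand.
    """

    pqs: PQSHit
    repeat: RepeatFeature
    relative_orientation: str
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.relative_orientation not in ("sense", "antisense"):
            raise ValueError("orientation must be sense or antisense")
        if self.overlap_bp < 1:
            raise ValueError("overlap must be >= 1 bp")


def intersect(
    hits: Sequence[PQSHit], repeats: Sequence[RepeatFeature]
) -> tuple[list[OrientationRecord], list[PQSHit]]:
    """Pair every PQS with every repeat it overlaps by >= 1 bp.

    Returns ``(records, unassigned)`` where ``unassigned`` are hits
    overlapping no repeat.  A PQS overlapping two repeats yields two records.
    """
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        iv = rep.interval
        trees.setdefault(iv.seqid, IntervalTree()).addi(iv.start, iv.end, rep)

    records: list[OrientationRecord] = []
    unassigned: list[PQSHit] = []
    for hit in hits:
        iv = hit.interval
        tree = trees.get(iv.seqid)
        overlaps = sorted(tree.overlap(iv.start, iv.end), key=lambda o: (o.begin, o.end)) if tree else []
        if not overlaps:
            unassigned.append(hit)
            continue
        for node in overlaps:
            rep: RepeatFeature = node.data
            orientation = "sense" if hit.strand == rep.interval.strand else "antisense"
            records.append(
                OrientationRecord(
                    pqs=hit,
                    repeat=rep,
                    relative_orientation=orientation,
                    overlap_bp=iv.overlap(rep.interval),
                )
            )
    return records, unassigned


def orientation_summary(records: Sequence[OrientationRecord]) -> pd.DataFrame:
    """Per-family counts keyed by (repeat genomic strand) x (orientation).

    Columns: ``(+, sense), (+, antisense), (-, sense), (-, antisense)``;
    cell values sum to the number of records per family.
    """
    if not records:
        raise ValueError("no orientation records to summarise")
    cells = [("+", "sense"), ("+", "antisense"), ("-", "sense"), ("-", "antisense")]
    counts: dict[str, dict[tuple[str, str], int]] = {}
    for rec in records:
        fam = counts.setdefault(rec.repeat.family, {c: 0 for c in cells})
        fam[(rec.repeat.interval.strand, rec.relative_orientation)] += 1
    table = pd.DataFrame.from_dict(counts, orient="index")
    table.columns = pd.MultiIndex.from_tuples(cells, names=["repeat_strand", "orientation"])
    table.index.name = "family"
    return table.sort_index()


def _masked_bp_in_region(region: GenomicInterval, n_mask: Iterable[GenomicInterval]) -> int:
    """Total masked bp within region, overlapping mask intervals merged."""
    clipped = sorted(
        (max(m.start, region.start), min(m.end, region.end))
        for m in n_mask
        if m.seqid == region.seqid and m.start < region.end and m.end > region.start
    )
    total = 0
    cur_s, cur_e = None, None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def density(
    hits: Sequence[PQSHit],
    region: GenomicInterval,
    n_mask: Sequence[GenomicInterval] = (),
) -> float:
    """PQS per 10 kbp of region, with N bases removed from the length.

    A hit counts iff its midpoint lies within the region (midpoint rule);
    the effective length is the region length minus masked (N) bases.
    """
    effective = len(region) - _masked_bp_in_region(region, n_mask)
    if effective <= 0:
        raise UndefinedDensityError("region has zero effective length after N removal")
    n_in = sum(
        1
        for h in hits
        if h.interval.seqid == region.seqid and region.start <= h.interval.midpoint < region.end
    )
    return 10000.0 * n_in / effective


def n_mask_from_sequence(seq: str, seqid: str) -> list[GenomicInterval]:
    """Intervals of N runs in a sequence, for density()'s n_mask argument."""
    mask: list[GenomicInterval] = []
    start = None
    for i, c in enumerate(seq):
        if c == "N":
            if start is None:
                start = i
        elif start is not None:
            mask.append(GenomicInterval(seqid, start, i))
            start = None
    if start is not None:
        mask.append(GenomicInterval(seqid, start, len(seq)))
    return mask


def bp_proportion(
    records: Sequence[OrientationRecord], fragments: Sequence[RepeatFeature]
) -> dict[str, float]:
    """Percent of fragment length covered by PQS, per family.

    Only fragments containing at least one PQS enter the denominator;
    families with no PQS-containing fragment are excluded from the output
    (rather than reported as zero).
    """
    frag_keys = {(f.interval, f.family) for f in fragments}
    overlap_by_family: dict[str, int] = {}
    containing: dict[str, set[GenomicInterval]] = {}
    for rec in records:
        key = (rec.repeat.interval, rec.repeat.family)
        if key not in frag_keys:
            continue
        overlap_by_family[rec.repeat.family] = (
            overlap_by_family.get(rec.repeat.family, 0) + rec.overlap_bp
        )
        containing.setdefault(rec.repeat.family, set()).add(rec.repeat.interval)
    out: dict[str, float] = {}
    for family, ivs in containing.items():
        total_len = sum(len(iv) for iv in ivs)
        out[family] = 100.0 * overlap_by_family[family] / total_len
    return out


def partition_summary(
    hits: Sequence[PQSHit],
    repeats: Sequence[RepeatFeature],
    genome_length: int,
) -> tuple[float, float]:
    """(percent of genome covered by repeats, percent of PQS inside repeats).

    Repeat coverage is over merged repeat intervals; a PQS is inside iff its
    midpoint falls in merged repeat space (midpoint rule, counted once even
    when overlapping several repeat copies).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    # merge repeat intervals per seqid
    merged: dict[str, list[tuple[int, int]]] = {}
    for rep in repeats:
        merged.setdefault(rep.interval.seqid, []).append((rep.interval.start, rep.interval.end))
    covered = 0
    merged_ivs: dict[str, list[tuple[int, int]]] = {}
    for seqid, ivs in merged.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged_ivs[seqid] = out
        covered += sum(e - s for s, e in out)
    repeat_pct = 100.0 * covered / genome_length
    if not hits:
        return repeat_pct, 0.0
    inside = 0
    for h in hits:
        mid = h.interval.midpoint
        for s, e in merged_ivs.get(h.interval.seqid, ()):
            if s <= mid < e:
                inside += 1
                break
    return repeat_pct, 100.0 * inside / len(hits)
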