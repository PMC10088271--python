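"""Potential quadruplex sequence (PQS) detection and scoring.

A PQS is four guanine runs separated by three short loops; the minimum run
length across the four tracts sets the number of stackable G-tetrads.  The
scanner enumerates every admissible placement of four G-runs on each strand,
scores it with an additive scheme, and reports non-overlapping maxima per
strand.

Scoring.  Let ``t`` be the minimum, over the four runs, of the longest
contiguous G stretch within the run, and ``l1..l3`` the loop lengths::

    score = tetrad_bonus*(t-1)
            - loop_penalty * sum(max(0, l_i - loop_free))
            - defect_penalty * n_defective_runs

A "defective" run carries exactly one single-base non-G bulge at an interior
position and must still contain at least ``min_run`` G's.  With the defaults
a canonical three-tetrad motif (e.g. GGGTGGGTGGGTGGG) scores 60 and clears
the default reporting threshold of 47, while a perfect two-tetrad motif
(score 30) does not.  The threshold follows the empirical score range below
which predicted quadruplexes stop agreeing well with G4-seq data.

Candidates never span an ``N``: assembly gaps must not create phantom loops.
The scanner is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from .seqio import Feature, FormatError, GenomicInterval, SeqRecord, read_fasta, revcomp, write_features


@dataclass(frozen=True)
class ScanParams:
    """Tunable constraints and score weights of the G-run scanner."""

    min_run: int = 3
    max_run: int = 7
    loop_min: int = 1
    loop_max: int = 12
    max_len: int = 50
    max_defective_runs: int = 1
    min_score: int = 47
    tetrad_bonus: int = 30
    loop_penalty: int = 2
    loop_free: int = 3
    defect_penalty: int = 10

    def __post_init__(self) -> None:
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")
        if self.loop_min < 1:
            raise ValueError("loop_min must be >= 1")
        if self.max_len < 4 * self.min_run + 3 * self.loop_min:
            raise ValueError("max_len cannot fit four minimal runs and three loops")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if self.max_defective_runs not in (0, 1):
            raise ValueError("max_defective_runs must be 0 or 1")


@dataclass(frozen=True)
class PQSHit:
    """One located quadruplex candidate.

    Coordinates are on the forward axis of the scanned sequence; ``strand``
    is the strand carrying the G-runs.  ``run_spans`` are the four G-run
    sub-intervals and ``motif`` the G-rich strand sequence 5'->3', both in
    the coordinate frame of the G-rich strand (for minus-strand hits the
    run spans index into ``motif``, not the forward axis).
    """

    interval: GenomicInterval
    score: int
    n_tetrads: int
    run_spans: tuple[tuple[int, int], ...]
    loop_lengths: tuple[int, int, int]
    n_defects: int
    motif: str

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class _RunSpan:
    """A candidate G-run: [start, end) on the scanned strand."""

    start: int
    end: int
    n_g: int
    max_stretch: int
    defective: bool


def _enumerate_run_spans(seq: str, params: ScanParams) -> list[_RunSpan]:
    """All sub-spans usable as one G-run, perfect or single-bulged.

    A span must begin and end with G (a bulge at an edge would merely extend
    a loop), contain ``min_run``..``max_run`` G's, and at most one interior
    non-G of length 1 which may not be N.
    """
    spans: list[_RunSpan] = []
    n = len(seq)
    for s in range(n):
        if seq[s] != "G":
            continue
        n_g = 0
        defects = 0
        first_part = 0  # G's before the bulge
        for e in range(s, n):
            c = seq[e]
            if c == "G":
                n_g += 1
            elif c == "N":
                break
            else:
                if defects == 1 or e == s:
                    break
                # tentative bulge; legal only if more G's follow
                defects = 1
                first_part = n_g
                continue
            if n_g > params.max_run:
                break
            if n_g >= params.min_run and seq[e] == "G":
                if defects == 0:
                    spans.append(_RunSpan(s, e + 1, n_g, n_g, False))
                else:
                    stretch = max(first_part, n_g - first_part)
                    spans.append(_RunSpan(s, e + 1, n_g, stretch, True))
    return spans


def enumerate_candidates(seq: str, params: ScanParams | None = None) -> list[PQSHit]:
    """Every admissible four-run placement scoring >= ``min_score``.

    Unfiltered by overlap; one candidate per distinct 4-tuple of run spans.
    Coordinates are on ``seq`` itself with strand '+'; use :func:`scan` for
    double-stranded scanning with overlap resolution.
    """
    params = params or ScanParams()
    seq = seq.upper()
    bad = set(seq) - {"A", "C", "G", "T", "N"}
    if bad:
        raise FormatError(f"illegal characters in sequence: {sorted(bad)}")
    spans = _enumerate_run_spans(seq, params)
    # index spans by start position for loop-bounded chaining
    by_start: dict[int, list[_RunSpan]] = {}
    for sp in spans:
        by_start.setdefault(sp.start, []).append(sp)

    has_n = "N" in seq
    hits: list[PQSHit] = []

    def extend(chain: list[_RunSpan]) -> None:
        last = chain[-1]
        if len(chain) == 4:
            first = chain[0]
            if last.end - first.start > params.max_len:
                return
            n_defects = sum(sp.defective for sp in chain)
            t = min(sp.max_stretch for sp in chain)
            loops = tuple(
                chain[i + 1].start - chain[i].end for i in range(3)
            )
            score = (
                params.tetrad_bonus * (t - 1)
                - params.loop_penalty * sum(max(0, l - params.loop_free) for l in loops)
                - params.defect_penalty * n_defects
            )
            if score < params.min_score:
                return
            motif = seq[first.start : last.end]
            if has_n and "N" in motif:
                return
            hits.append(
                PQSHit(
                    interval=GenomicInterval("seq", first.start, last.end, "+"),
                    score=score,
                    n_tetrads=t,
                    run_spans=tuple((sp.start, sp.end) for sp in chain),
                    loop_lengths=loops,  # type: ignore[arg-type]
                    n_defects=n_defects,
                    motif=motif,
                )
            )
            return
        budget_defects = params.max_defective_runs - sum(sp.defective for sp in chain)
        # next run must start within loop bounds and fit max_len
        for nxt_start in range(last.end + params.loop_min, last.end + params.loop_max + 1):
            for sp in by_start.get(nxt_start, ()):
                if sp.defective and budget_defects == 0:
                    continue
                if sp.end - chain[0].start > params.max_len:
                    continue
                chain.append(sp)
                extend(chain)
                chain.pop()

    for sp in spans:
        if sp.defective and params.max_defective_runs == 0:
            continue
        extend([sp])
    hits.sort(key=lambda h: (h.interval.start, h.interval.end, h.run_spans))
    return hits


def _greedy_select(candidates: list[PQSHit]) -> list[PQSHit]:
    """Non-overlapping maxima: keep best score; ties by leftmost start,
    then shortest, then lexicographically smallest motif."""
    ordered = sorted(
        candidates,
        key=lambda h: (-h.score, h.interval.start, len(h.interval), h.motif),
    )
    kept: list[PQSHit] = []
    for cand in ordered:
        if all(
            cand.interval.end <= k.interval.start or cand.interval.start >= k.interval.end
            for k in kept
        ):
            kept.append(cand)
    return kept


def scan(record: SeqRecord, params: ScanParams | None = None) -> list[PQSHit]:
    """Scan both strands of ``record`` and report non-overlapping PQS.

    Minus-strand candidates are found on the reverse complement and reported
    on the forward axis with ``strand='-'``; opposite-strand hits may overlap
    (strand-specific quadruplexes are counted separately downstream).  Output
    is sorted by (seqid, start, end, strand).
    """
    params = params or ScanParams()
    seq = record.sequence
    length = len(seq)

    # Overlap resolution happens in each strand's own 5'->3' frame, so the
    # leftmost-start tie-break is strand-symmetric; minus-strand winners are
    # mapped to the forward axis afterwards.
    fwd = [
        replace(h, interval=GenomicInterval(record.id, h.interval.start, h.interval.end, "+"))
        for h in _greedy_select(enumerate_candidates(seq, params))
    ]
    rev = [
        replace(
            h,
            interval=GenomicInterval(
                record.id, length - h.interval.end, length - h.interval.start, "-"
            ),
        )
        for h in _greedy_select(enumerate_candidates(revcomp(seq), params))
    ]
    hits = fwd + rev
    hits.sort(key=lambda h: (h.interval.seqid, h.interval.start, h.interval.end, h.strand))
    return hits


def hit_to_feature(hit: PQSHit) -> Feature:
    return Feature(
        interval=hit.interval,
        type="PQS",
        score=float(hit.score),
        attributes={
            "n_tetrads": str(hit.n_tetrads),
            "n_defects": str(hit.n_defects),
            "loops": ",".join(map(str, hit.loop_lengths)),
            "motif": hit.motif,
        },
    )


def scan_fasta(
    fasta_path: str | Path, out_path: str | Path, params: ScanParams | None = None
) -> list[PQSHit]:
    """Scan every record of a FASTA file and write hits as GFF3 (type PQS)."""
    hits: list[PQSHit] = []
    for record in read_fasta(fasta_path):
        hits.extend(scan(record, params))
    write_features([hit_to_feature(h) for h in hits], out_path, dialect="gff3")
    return hits
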