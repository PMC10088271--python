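"""Ground-truth synthetic data emulating telomeric retrotransposon arrays.

The generators produce every input the pipeline consumes, with a truth
annotation alongside: background DNA of controlled GC, retrotransposon-like
elements (5'UTR - gag - pol - 3'UTR - poly(A)) carrying planted quadruplex
motifs, head-to-tail arrays of such elements with the poly(A) tracts all
pointing one way, tandem-repeat arrays, and homologous CDS families evolved
under region-specific synonymous/nonsynonymous rates with optional codon
bias inside designated PQS loci.

Recovery guarantees: background is rejection-resampled until it contains no
accidental PQS at the scanner's reporting threshold, planted motifs are
flanked by non-G/non-C bases so they cannot merge with neighbouring runs,
and poly(A) spacers longer than the maximum loop keep candidates from
spanning element junctions.  Every generator is a pure function of its
configuration including the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .seqio import Feature, GenomicInterval, SeqRecord, revcomp
from .pqs_scan import PQSHit, ScanParams, scan
from .codon_selection import (
    CODON_TO_AA,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
)
from .conservation_bias import CodonMSA, ProteinMSA, thread_codons

_REGION_ORDER = ("utr5", "gag", "pol", "utr3")


class GenerationError(RuntimeError):
    """Rejection sampling failed to satisfy the recovery guarantees."""


@dataclass(frozen=True)
class ElementArch:
    """Lengths (bp) of the architectural parts of one element."""

    utr5: int = 300
    gag: int = 1500
    pol: int = 1500
    utr3: int = 300
    polya: int = 20

    def __post_init__(self) -> None:
        if min(self.utr5, self.gag, self.pol, self.utr3, self.polya) <= 0:
            raise ValueError("all architectural lengths must be positive")

    def region_span(self, name: str) -> tuple[int, int]:
        offset = 0
        for region in _REGION_ORDER:
            size = getattr(self, region)
            if region == name:
                return offset, offset + size
            offset += size
        raise KeyError(f"unknown region {name!r}")

    @property
    def total(self) -> int:
        return self.utr5 + self.gag + self.pol + self.utr3 + self.polya


@dataclass(frozen=True)
class PQSPlan:
    """A batch of motifs to plant: where, how many, which orientation."""

    region: str = "gag"
    count: int = 1
    relative_orientation: str = "antisense"
    n_tetrads: int = 3
    loop_lengths: tuple[int, ...] = (1, 1, 1)

    def __post_init__(self) -> None:
        if self.region not in _REGION_ORDER:
            raise ValueError(f"unknown region {self.region!r}")
        if self.relative_orientation not in ("sense", "antisense"):
            raise ValueError("orientation must be sense or antisense")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Element/array simulation parameters (see module docstring)."""

    seed: int = 0
    gc_background: float = 0.42
    element_arch: ElementArch = field(default_factory=ElementArch)
    pqs_plan: tuple[PQSPlan, ...] = (PQSPlan(),)
    array_n: int = 5
    array_strand: str = "-"
    family: str = "HetA-like"
    scan_params: ScanParams = field(default_factory=ScanParams)


@dataclass
class SyntheticTruth:
    """Sequence(s) plus the planted-feature annotation and parameter echo."""

    sequences: list[SeqRecord]
    features: list[Feature]
    params: object

    @property
    def pqs_features(self) -> list[Feature]:
        return [f for f in self.features if f.type == "PQS"]


# ---------------------------------------------------------------------------
# Background and motifs
# ---------------------------------------------------------------------------

def gen_background(
    length: int,
    gc: float,
    seed: int | np.random.Generator,
    scan_params: ScanParams | None = None,
    reject_pqs: bool = True,
    max_rounds: int = 60,
    seqid: str = "background",
) -> SeqRecord:
    """Random DNA with P(G)=P(C)=gc/2 and, by default, no PQS at threshold.

    Accidental quadruplex candidates are removed by locally resampling the
    offending windows and rescanning until the sequence is clean.  At
    extreme GC this cannot converge; disable with ``reject_pqs=False``.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = scan_params or ScanParams()
    bases = np.array(list("GCAT"))
    probs = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    seq = rng.choice(bases, size=length, p=probs)
    if reject_pqs:
        for _ in range(max_rounds):
            hits = scan(SeqRecord(seqid, "".join(seq)), params)
            if not hits:
                break
            for h in hits:
                iv = h.interval
                seq[iv.start : iv.end] = rng.choice(bases, size=len(iv), p=probs)
        else:
            raise GenerationError(
                f"could not clear background of PQS in {max_rounds} rounds (gc={gc})"
            )
    return SeqRecord(seqid, "".join(seq))


def make_pqs_motif(
    n_tetrads: int,
    loop_lengths: Sequence[int],
    loop_alphabet: str = "AT",
    rng: np.random.Generator | None = None,
    params: ScanParams | None = None,
) -> str:
    """Four perfect G-runs of ``n_tetrads`` separated by the given loops.

    Loop bases are drawn from ``loop_alphabet`` (G excluded so plants never
    merge with adjacent runs).  Warns if the motif scores below the
    reporting threshold of ``params``.
    """
    params = params or ScanParams()
    if n_tetrads < 2:
        raise ValueError("n_tetrads must be >= 2")
    if n_tetrads > params.max_run:
        raise ValueError("n_tetrads exceeds max_run")
    if len(loop_lengths) != 3:
        raise ValueError("exactly three loops required")
    if any(l < params.loop_min or l > params.loop_max for l in loop_lengths):
        raise ValueError("loop length out of scanner bounds")
    if "G" in loop_alphabet.upper():
        raise ValueError("loop alphabet must not contain G")
    run = "G" * n_tetrads
    parts = [run]
    for l in loop_lengths:
        if rng is None:
            loop = (loop_alphabet * l)[:l]
        else:
            loop = "".join(rng.choice(list(loop_alphabet), size=l))
        parts.append(loop)
        parts.append(run)
    motif = "".join(parts)
    if len(motif) > params.max_len:
        raise ValueError("motif exceeds max_len")
    score = params.tetrad_bonus * (n_tetrads - 1) - params.loop_penalty * sum(
        max(0, l - params.loop_free) for l in loop_lengths
    )
    if score < params.min_score:
        warnings.warn(
            f"planted motif scores {score}, below reporting threshold {params.min_score}",
            stacklevel=2,
        )
    return motif


# ---------------------------------------------------------------------------
# Elements and arrays
# ---------------------------------------------------------------------------

def _place_motifs(
    config: SimConfig, rng: np.random.Generator
) -> list[tuple[int, str, str]]:
    """Choose non-overlapping (start, oriented_sequence, strand) plants."""
    placements: list[tuple[int, int]] = []  # (start, end) incl. 1-bp flanks
    plants: list[tuple[int, str, str]] = []
    for plan in config.pqs_plan:
        lo, hi = config.element_arch.region_span(plan.region)
        for _ in range(plan.count):
            motif = make_pqs_motif(
                plan.n_tetrads, plan.loop_lengths, rng=rng, params=config.scan_params
            )
            inserted = motif if plan.relative_orientation == "sense" else revcomp(motif)
            span = len(inserted) + 2  # one non-G/C flank base each side
            if hi - lo < span:
                raise GenerationError(f"region {plan.region} too small for motif")
            for _attempt in range(200):
                start = int(rng.integers(lo, hi - span + 1))
                end = start + span
                if all(end <= s or start >= e for s, e in placements):
                    placements.append((start, end))
                    strand = "+" if plan.relative_orientation == "sense" else "-"
                    plants.append((start + 1, inserted, strand))
                    break
            else:
                raise GenerationError(
                    f"could not place {plan.count} motifs in region {plan.region}"
                )
    plants.sort()
    return plants


def gen_element(config: SimConfig, rng: np.random.Generator | None = None) -> SyntheticTruth:
    """One element: background + architecture + planted motifs, verified.

    Motifs requested antisense are planted as reverse complements on the
    coding strand (the element is emitted on '+'), so their G-runs sit on
    the template strand.  After assembly the element is rescanned and must
    yield exactly the planted hit set; offending background is locally
    resampled.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    arch = config.element_arch
    params = config.scan_params
    body_len = arch.total - arch.polya
    plants = _place_motifs(config, rng)

    bases = np.array(list("GCAT"))
    gc = config.gc_background
    probs = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    body = np.array(list(gen_background(body_len, gc, rng, params, reject_pqs=False).sequence))

    planted_ivs: list[tuple[int, int, str]] = []
    flank = np.array(list("AT"))
    for start, inserted, strand in plants:
        body[start - 1] = rng.choice(flank)
        body[start + len(inserted)] = rng.choice(flank)
        body[start : start + len(inserted)] = list(inserted)
        planted_ivs.append((start, start + len(inserted), strand))

    protected = np.zeros(body_len, dtype=bool)
    for s, e, _ in planted_ivs:
        protected[s - 1 : e + 1] = True

    eid = f"{config.family}_1"
    expected = {(s, e, strand) for s, e, strand in planted_ivs}
    for _round in range(60):
        hits = scan(SeqRecord(eid, "".join(body)), params)
        found = {(h.interval.start, h.interval.end, h.strand) for h in hits}
        if found == expected:
            break
        stray = found - expected
        if not stray:
            raise GenerationError("planted motif lost during assembly")
        for s, e, _strand in stray:
            window = np.arange(s, e)
            free = window[~protected[window]]
            if free.size == 0:
                raise GenerationError("stray hit overlaps only protected bases")
            body[free] = rng.choice(bases, size=free.size, p=probs)
    else:
        raise GenerationError("could not converge to exactly the planted hit set")

    sequence = "".join(body) + "A" * arch.polya
    features = [
        Feature(
            GenomicInterval(eid, 0, arch.total, "+"),
            type="repeat",
            attributes={"family": config.family, "clade": "Jockey", "element_id": eid},
        )
    ]
    for region in _REGION_ORDER:
        s, e = arch.region_span(region)
        features.append(
            Feature(GenomicInterval(eid, s, e, "+"), type=region, attributes={"element_id": eid})
        )
    features.append(
        Feature(
            GenomicInterval(eid, body_len, arch.total, "+"),
            type="polyA",
            attributes={"element_id": eid},
        )
    )
    for s, e, strand in planted_ivs:
        features.append(
            Feature(
                GenomicInterval(eid, s, e, strand),
                type="PQS",
                attributes={"element_id": eid, "planted": "true"},
            )
        )
    return SyntheticTruth([SeqRecord(eid, sequence)], features, config)


def gen_htt_array(
    element_truth: SyntheticTruth,
    n: int,
    array_strand: str = "-",
    seqid: str = "array",
) -> SyntheticTruth:
    """Head-to-tail array of ``n`` element copies on one genomic strand.

    Copies are concatenated in a single orientation, poly(A) tails all
    pointing the same way; for ``array_strand='-'`` the whole array is
    reverse-complemented so element coordinates land on the minus strand.
    The element's own poly(A) tract (longer than the maximum loop) prevents
    any quadruplex candidate from spanning a junction, so all planted PQS
    end up on one genomic strand.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if array_strand not in ("+", "-"):
        raise ValueError("array_strand must be + or -")
    config: SimConfig = element_truth.params  # type: ignore[assignment]
    if config.element_arch.polya <= config.scan_params.loop_max:
        raise ValueError("poly(A) tract must exceed loop_max to insulate junctions")
    unit = element_truth.sequences[0].sequence
    unit_len = len(unit)
    seq = unit * n
    features: list[Feature] = []
    for copy in range(n):
        offset = copy * unit_len
        for f in element_truth.features:
            iv = f.interval
            attrs = dict(f.attributes)
            if "element_id" in attrs:
                attrs["element_id"] = f"{attrs['element_id']}_c{copy + 1}"
            features.append(
                Feature(
                    GenomicInterval(seqid, iv.start + offset, iv.end + offset, iv.strand),
                    type=f.type,
                    score=f.score,
                    attributes=attrs,
                )
            )
    if array_strand == "-":
        total = len(seq)
        seq = revcomp(seq)
        flipped: list[Feature] = []
        for f in features:
            iv = f.interval
            strand = iv.strand
            if strand in ("+", "-"):
                strand = "-" if strand == "+" else "+"
            flipped.append(
                replace(
                    f,
                    interval=GenomicInterval(seqid, total - iv.end, total - iv.start, strand),
                )
            )
        features = flipped
    features.sort(key=lambda f: (f.interval.start, f.interval.end, f.type))
    return SyntheticTruth([SeqRecord(seqid, seq)], features, config)


def gen_tandem_array(
    monomer: str,
    n_copies: int,
    per_base_sub_rate: float,
    seed: int | np.random.Generator,
    seqid: str = "tandem",
) -> SyntheticTruth:
    """Tandem-repeat array: ``n_copies`` of ``monomer`` with substitutions.

    Each base of each copy mutates independently to a uniformly chosen
    different base with the stated probability.
    """
    monomer = monomer.upper()
    if len(monomer) < 10:
        raise ValueError("monomer must be >= 10 bp")
    if not 0.0 <= per_base_sub_rate < 1.0:
        raise ValueError("substitution rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = "ACGT"
    copies: list[str] = []
    features: list[Feature] = []
    pos = 0
    for i in range(n_copies):
        chars = list(monomer)
        if per_base_sub_rate > 0:
            mutate = rng.random(len(chars)) < per_base_sub_rate
            for j in np.flatnonzero(mutate):
                alternatives = bases.replace(chars[j], "") if chars[j] in bases else bases
                chars[j] = alternatives[int(rng.integers(len(alternatives)))]
        copies.append("".join(chars))
        features.append(
            Feature(
                GenomicInterval(seqid, pos, pos + len(monomer), "+"),
                type="tandem_monomer",
                attributes={"copy": str(i + 1)},
            )
        )
        pos += len(monomer)
    return SyntheticTruth(
        [SeqRecord(seqid, "".join(copies))],
        features,
        {"monomer": monomer, "n_copies": n_copies, "rate": per_base_sub_rate},
    )


# ---------------------------------------------------------------------------
# CDS families under region-specific selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OmegaRegion:
    """Codon-index interval with its nonsynonymous acceptance probability."""

    name: str
    start_codon: int
    end_codon: int
    omega: float

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.end_codon <= self.start_codon:
            raise ValueError("empty omega region")


@dataclass(frozen=True)
class CdsFamilyConfig:
    seed: int = 0
    ancestor_length_codons: int = 300
    n_seqs: int = 20
    expected_subs_per_codon: float = 0.3
    omega_regions: tuple[OmegaRegion, ...] = (
        OmegaRegion("A", 0, 150, 0.2),
        OmegaRegion("B", 150, 300, 1.0),
    )
    pqs_loci: tuple[tuple[int, int], ...] = ()  # codon-index intervals
    c3_multiplier: float = 1.0
    proline_multiplier: float = 1.0


@dataclass
class CdsFamilyTruth:
    records: list[SeqRecord]
    ancestor: SeqRecord
    config: CdsFamilyConfig


_AA_CHOICES = tuple(sorted(SYNONYMOUS_FAMILIES))  # 20 amino acids


def _sample_codon(
    rng: np.random.Generator, in_pqs: bool, config: CdsFamilyConfig
) -> str:
    aas = _AA_CHOICES
    weights = np.ones(len(aas))
    if in_pqs and config.proline_multiplier != 1.0:
        weights[aas.index("P")] *= config.proline_multiplier
    weights /= weights.sum()
    aa = aas[int(rng.choice(len(aas), p=weights))]
    family = SYNONYMOUS_FAMILIES[aa]
    c_ending = [c for c in family if c[2] == "C"]
    if in_pqs and config.c3_multiplier != 1.0 and c_ending:
        base_frac = len(c_ending) / len(family)
        p_c = min(1.0, config.c3_multiplier * base_frac)
        if rng.random() < p_c:
            return c_ending[int(rng.integers(len(c_ending)))]
        rest = [c for c in family if c[2] != "C"]
        return rest[int(rng.integers(len(rest)))]
    return family[int(rng.integers(len(family)))]


def gen_cds_family(config: CdsFamilyConfig) -> CdsFamilyTruth:
    """Ancestor CDS plus descendants evolved under region-specific selection.

    The ancestor is sampled codon-wise (uniform amino acids, uniform
    synonymous codons, with optional proline/third-position-C bias inside
    designated PQS loci).  Each descendant evolves independently: per codon,
    Poisson(rate) proposed single-base changes; a synonymous change is
    always accepted, a nonsynonymous one with probability omega of its
    region, and changes creating stops are rejected.  No indels.
    """
    rng = np.random.default_rng(config.seed)
    n_codons = config.ancestor_length_codons
    omega_of = np.ones(n_codons)
    for region in config.omega_regions:
        omega_of[region.start_codon : min(region.end_codon, n_codons)] = region.omega
    in_pqs = np.zeros(n_codons, dtype=bool)
    for s, e in config.pqs_loci:
        in_pqs[s:e] = True

    ancestor_codons = [_sample_codon(rng, bool(in_pqs[i]), config) for i in range(n_codons)]
    ancestor = SeqRecord("ancestor", "".join(ancestor_codons))

    bases = "ACGT"
    records: list[SeqRecord] = []
    for k in range(config.n_seqs):
        codons = list(ancestor_codons)
        n_events = rng.poisson(config.expected_subs_per_codon, size=n_codons)
        for idx in np.flatnonzero(n_events):
            for _ in range(int(n_events[idx])):
                codon = codons[idx]
                pos = int(rng.integers(3))
                alternatives = bases.replace(codon[pos], "")
                mutant = (
                    codon[:pos] + alternatives[int(rng.integers(3))] + codon[pos + 1 :]
                )
                if mutant in STOP_CODONS:
                    continue
                if CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
                    codons[idx] = mutant
                elif rng.random() < omega_of[idx]:
                    codons[idx] = mutant
        records.append(SeqRecord(f"seq{k + 1}", "".join(codons)))
    return CdsFamilyTruth(records=records, ancestor=ancestor, config=config)


def family_codon_msa(truth: CdsFamilyTruth) -> CodonMSA:
    """Trivial (indel-free) codon alignment of a simulated family."""
    ids = tuple(r.id for r in truth.records)
    aa_rows = tuple(str(Seq(r.sequence).translate()) for r in truth.records)
    protein = ProteinMSA(ids, aa_rows)
    return thread_codons(protein, {r.id: r.sequence for r in truth.records})
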