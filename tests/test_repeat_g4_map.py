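"""Strand-aware PQS/repeat intersection, density and bp-proportion."""

import pytest

from conftest import make_hit

from g4telo.repeat_g4_map import (
    RepeatFeature,
    UndefinedDensityError,
    bp_proportion,
    density,
    intersect,
    n_mask_from_sequence,
    orientation_summary,
    partition_summary,
)
from g4telo.seqio import GenomicInterval


def rep(seqid, start, end, strand, family="Het-A", **kw):
    return RepeatFeature(GenomicInterval(seqid, start, end, strand), family=family, **kw)


class TestIntersect:
    def test_sense_inside(self):
        records, unassigned = intersect(
            [make_hit("c", 100, 130, "+")], [rep("c", 0, 5000, "+")]
        )
        assert not unassigned
        (r,) = records
        assert r.relative_orientation == "sense"
        assert r.overlap_bp == 30

    def test_antisense_inside(self):
        records, _ = intersect([make_hit("c", 100, 130, "+")], [rep("c", 0, 5000, "-")])
        assert records[0].relative_orientation == "antisense"

    def test_straddling_two_repeats_two_records(self):
        hit = make_hit("c", 990, 1020, "+")
        records, _ = intersect(
            [hit], [rep("c", 0, 1000, "+"), rep("c", 1000, 2000, "+", family="TART-B")]
        )
        assert len(records) == 2
        assert sum(r.overlap_bp for r in records) == len(hit.interval)

    def test_unassigned_reported_separately(self):
        records, unassigned = intersect(
            [make_hit("c", 0, 30, "+"), make_hit("c", 500, 530, "+")],
            [rep("c", 400, 600, "+")],
        )
        assert len(records) == 1 and len(unassigned) == 1

    def test_record_conservation(self):
        """Per-family counts + unassigned equals intersect's own pairing."""
        hits = [make_hit("c", i * 50, i * 50 + 30, "+") for i in range(10)]
        repeats = [rep("c", 0, 120, "+"), rep("c", 100, 400, "-", family="TART-B")]
        records, unassigned = intersect(hits, repeats)
        table = orientation_summary(records)
        assert int(table.to_numpy().sum()) + len(unassigned) == len(records) + len(unassigned)
        assert len(records) + len(unassigned) >= len(hits)


class TestOrientationSummary:
    def test_single_cell(self):
        records, _ = intersect(
            [make_hit("c", i, i + 15, "+") for i in (10, 100, 200)],
            [rep("c", 0, 300, "-")],
        )
        table = orientation_summary(records)
        assert table.loc["Het-A", ("-", "antisense")] == 3
        assert table.to_numpy().sum() == 3

    def test_label_equivariance(self):
        """Flipping every strand label permutes the counters accordingly."""
        hits = [make_hit("c", 10, 25, "+"), make_hit("c", 50, 65, "-")]
        repeats = [rep("c", 0, 100, "+")]
        t1 = orientation_summary(intersect(hits, repeats)[0])
        flipped_hits = [make_hit("c", 10, 25, "-"), make_hit("c", 50, 65, "+")]
        flipped_reps = [rep("c", 0, 100, "-")]
        t2 = orientation_summary(intersect(flipped_hits, flipped_reps)[0])
        assert t1.loc["Het-A", ("+", "sense")] == t2.loc["Het-A", ("-", "sense")]
        assert t1.loc["Het-A", ("+", "antisense")] == t2.loc["Het-A", ("-", "antisense")]

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            orientation_summary([])


class TestDensity:
    def test_plain(self):
        hits = [make_hit("c", i * 1000, i * 1000 + 20, "+") for i in range(5)]
        assert density(hits, GenomicInterval("c", 0, 10000)) == 5.0

    def test_n_correction(self):
        hits = [make_hit("c", i * 1000, i * 1000 + 20, "+") for i in range(5)]
        mask = [GenomicInterval("c", 10000, 20000)]
        assert density(hits, GenomicInterval("c", 0, 20000), mask) == 5.0

    def test_n_mask_from_sequence(self):
        mask = n_mask_from_sequence("ACGNNNACGTN", "c")
        assert [(m.start, m.end) for m in mask] == [(3, 6), (10, 11)]

    def test_zero_effective_length(self):
        with pytest.raises(UndefinedDensityError):
            density([], GenomicInterval("c", 0, 100), [GenomicInterval("c", 0, 100)])

    def test_translation_invariance(self):
        hits = [make_hit("c", 100, 120, "+"), make_hit("c", 300, 330, "-")]
        d0 = density(hits, GenomicInterval("c", 0, 1000))
        shifted = [make_hit("c", 100 + 5000, 120 + 5000, "+"), make_hit("c", 5300, 5330, "-")]
        d1 = density(shifted, GenomicInterval("c", 5000, 6000))
        assert d0 == d1

    def test_strand_flip_invariance(self):
        hits = [make_hit("c", 100, 120, "+"), make_hit("c", 300, 330, "-")]
        flipped = [make_hit("c", 100, 120, "-"), make_hit("c", 300, 330, "+")]
        region = GenomicInterval("c", 0, 1000)
        assert density(hits, region) == density(flipped, region)

    def test_midpoint_rule_at_boundary(self):
        # midpoint 105 outside [0,100) -> not counted
        assert density([make_hit("c", 90, 120, "+")], GenomicInterval("c", 0, 100)) == 0.0


class TestBpProportion:
    def test_single_fragment(self):
        frag = rep("c", 0, 1000, "+", is_fragment=True)
        records, _ = intersect([make_hit("c", 100, 130, "+")], [frag])
        assert bp_proportion(records, [frag]) == {"Het-A": 3.0}

    def test_pqs_free_fragment_excluded(self):
        frags = [rep("c", 0, 1000, "+", is_fragment=True),
                 rep("c", 2000, 3000, "+", is_fragment=True)]
        records, _ = intersect([make_hit("c", 100, 150, "+")], frags)
        assert bp_proportion(records, frags) == {"Het-A": 5.0}

    def test_family_without_pqs_absent(self):
        frags = [rep("c", 0, 1000, "+", family="DOC")]
        assert bp_proportion([], frags) == {}

    def test_matches_direct_interval_sum(self, rng):
        """Randomised fixture equals an independent direct recomputation."""
        frags = [rep("c", i * 2000, i * 2000 + 1000, "+", family=f"F{i % 2}")
                 for i in range(6)]
        hits = [make_hit("c", int(s), int(s) + 25, "+")
                for s in rng.integers(0, 11000, size=40)]
        records, _ = intersect(hits, frags)
        got = bp_proportion(records, frags)
        # independent recomputation
        for family in got:
            f_frags = [f for f in frags if f.family == family]
            containing = [
                f for f in f_frags
                if any(h.interval.overlap(f.interval) > 0 for h in hits)
            ]
            total_overlap = sum(
                h.interval.overlap(f.interval) for f in containing for h in hits
            )
            expected = 100.0 * total_overlap / sum(len(f.interval) for f in containing)
            assert got[family] == pytest.approx(expected)
            assert 0.0 <= got[family] <= 100.0


class TestPartitionSummary:
    def test_no_repeats(self):
        assert partition_summary([make_hit("c", 0, 20, "+")], [], 1000) == (0.0, 0.0)

    def test_proportionality(self):
        repeats = [rep("c", 0, 500, "+")]
        hits = [make_hit("c", i * 100 + 10, i * 100 + 30, "+") for i in range(10)]
        rep_pct, pqs_pct = partition_summary(hits, repeats, 1000)
        assert rep_pct == 50.0
        assert pqs_pct == 50.0

    def test_overlapping_repeats_merged(self):
        repeats = [rep("c", 0, 300, "+"), rep("c", 200, 500, "-", family="X")]
        rep_pct, _ = partition_summary([make_hit("c", 250, 270, "+")], repeats, 1000)
        assert rep_pct == 50.0
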