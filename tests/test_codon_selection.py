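"""NG86 dN/dS machinery, delta-GC and PQS-locus codon statistics."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from _oracles import oracle_pathways

from g4telo.codon_selection import (
    CODON_TO_AA,
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
    SaturationError,
    codon_position_stats,
    delta_gc,
    dnds_alignment,
    gc_content,
    jukes_cantor,
    ng86_pairwise,
    ng86_site_counts,
    partition_by_pqs,
    synonymous_family_gc,
)
from g4telo.conservation_bias import RegionSpec
from g4telo.seqio import GenomicInterval
from g4telo.synthetic_data import family_codon_msa, gen_cds_family, CdsFamilyConfig, OmegaRegion


class TestSiteCounts:
    @pytest.mark.parametrize(
        "codon,S,N",
        [
            ("TTT", 1 / 3, 8 / 3),  # only TTC synonymous, at position 3
            ("GGG", 1.0, 2.0),      # third position fully degenerate
            ("ATG", 0.0, 3.0),      # Met has no synonyms
        ],
    )
    def test_hand_enumerated_codons(self, codon, S, N):
        s, n = ng86_site_counts(codon)
        assert s == pytest.approx(S)
        assert n == pytest.approx(N)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TAA")

    def test_s_plus_n_is_three_for_every_sense_codon(self):
        for codon in SENSE_CODONS:
            s, n = ng86_site_counts(codon)
            assert s + n == pytest.approx(3.0)
            assert 0.0 <= s <= 3.0


class TestPairwise:
    def test_identical_sequences(self):
        r = ng86_pairwise("ATGAAACCC", "ATGAAACCC")
        assert r.Sd == r.Nd == 0.0
        assert r.ds == r.dn == 0.0
        assert math.isnan(r.ratio)

    def test_hand_computed_synonymous_case(self):
        r = ng86_pairwise("TTTAAAGGG", "TTCAAAGGG")
        assert r.S_sites == pytest.approx(5 / 3)
        assert r.Sd == 1.0 and r.Nd == 0.0
        assert r.ps == pytest.approx(0.6)
        assert r.ds == pytest.approx(-0.75 * math.log(0.2), abs=1e-12)
        assert r.dn == 0.0
        assert r.ratio == 0.0

    def test_pure_nonsynonymous_infinite_ratio(self):
        r = ng86_pairwise("ATGAAA", "ATGAGA")  # Lys -> Arg
        assert r.Sd == 0.0 and r.Nd == 1.0
        assert r.ds == 0.0
        assert math.isinf(r.ratio)

    def test_gapped_and_n_codons_skipped(self):
        full = ng86_pairwise("TTTAAAGGG", "TTCAAAGGG")
        gapped = ng86_pairwise("TTT---AAAGGG", "TTCNNNAAAGGG")
        assert gapped.S_sites == full.S_sites
        assert gapped.Sd == full.Sd

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.75)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(st.sampled_from(SENSE_CODONS), st.sampled_from(SENSE_CODONS))
    def test_pathway_counts_match_recursive_oracle(self, ci, cj):
        """Pathway-averaged differences equal an independent recursive
        path walker over all stop-free mutational orderings."""
        from g4telo.codon_selection import _codon_pair_diffs

        sd, nd = _codon_pair_diffs(ci, cj)
        sd_exp, nd_exp = oracle_pathways(ci, cj)
        assert sd == pytest.approx(sd_exp)
        assert nd == pytest.approx(nd_exp)


class TestDnDsAlignment:
    def test_identical_rows_zero(self):
        fam = gen_cds_family(
            CdsFamilyConfig(seed=1, n_seqs=3, ancestor_length_codons=60,
                            expected_subs_per_codon=0.0,
                            omega_regions=(OmegaRegion("all", 0, 60, 1.0),))
        )
        msa = family_codon_msa(fam)
        (row,) = dnds_alignment(msa)
        assert row.mean_ds == 0.0 and row.mean_dn == 0.0
        assert row.n_undefined == row.n_pairs

    def test_two_rows_equal_single_pair(self):
        fam = gen_cds_family(
            CdsFamilyConfig(seed=2, n_seqs=2, ancestor_length_codons=100,
                            expected_subs_per_codon=0.3,
                            omega_regions=(OmegaRegion("all", 0, 100, 0.5),))
        )
        msa = family_codon_msa(fam)
        (row,) = dnds_alignment(msa)
        single = ng86_pairwise(fam.records[0].sequence, fam.records[1].sequence)
        assert row.mean_ds == pytest.approx(single.ds)
        assert row.mean_dn == pytest.approx(single.dn)

    def test_omega_zero_gives_negligible_dn(self):
        """Under omega=0 every accepted change is synonymous; pathway
        averaging over serially substituted codons (e.g. Leu TTA<->CTA)
        can still attribute a small nonsynonymous fraction, so dn is
        near-zero rather than exactly zero while ds is substantial."""
        fam = gen_cds_family(
            CdsFamilyConfig(seed=3, n_seqs=4, ancestor_length_codons=80,
                            expected_subs_per_codon=0.4,
                            omega_regions=(OmegaRegion("all", 0, 80, 0.0),))
        )
        msa = family_codon_msa(fam)
        (row,) = dnds_alignment(msa)
        assert row.mean_ds > 0.05
        assert row.mean_dn < 0.05 * row.mean_ds

    def test_monotone_jc(self):
        """ds is monotone increasing in ps on [0, 3/4)."""
        values = [jukes_cantor(p) for p in (0.0, 0.1, 0.3, 0.5, 0.7)]
        assert values == sorted(values)
        assert values[0] == 0.0


class TestDeltaGC:
    def test_proline_family_mean(self):
        assert synonymous_family_gc("P") == pytest.approx(10 / 12)

    def test_ccg_delta(self):
        assert delta_gc("CCG") == pytest.approx(1.0 - 10 / 12)

    def test_single_codon_family(self):
        assert delta_gc("ATG") == 0.0
        assert delta_gc("TGG") == 0.0

    def test_family_mean_delta_is_zero_for_every_aa(self):
        for aa, family in SYNONYMOUS_FAMILIES.items():
            mean = sum(delta_gc(c) for c in family) / len(family)
            assert mean == pytest.approx(0.0, abs=1e-12), aa

    def test_stop_rejected(self):
        with pytest.raises(ValueError):
            delta_gc("TGA")


class TestPartitionByPqs:
    CDS = "ATGAAACCCGGGTTTAAACCCGGGTTTAAA"  # 10 codons

    def test_interval_covering_codons(self):
        pqs, nonpqs = partition_by_pqs(self.CDS, [GenomicInterval("cds", 9, 18)])
        assert [s.position_index for s in pqs] == [3, 4, 5]
        assert len(pqs) + len(nonpqs) == 10

    def test_mid_codon_boundary_included(self):
        pqs, _ = partition_by_pqs(self.CDS, [GenomicInterval("cds", 9, 19)])
        assert [s.position_index for s in pqs] == [3, 4, 5, 6]

    def test_no_pqs(self):
        pqs, nonpqs = partition_by_pqs(self.CDS, [])
        assert pqs == [] and len(nonpqs) == 10

    def test_partition_exhaustive_disjoint(self):
        pqs, nonpqs = partition_by_pqs(self.CDS, [GenomicInterval("cds", 0, 5)])
        idx = sorted(s.position_index for s in pqs + nonpqs)
        assert idx == list(range(10))


class TestCodonPositionStats:
    def test_constructed_double_c3(self):
        from g4telo.codon_selection import CodonSite

        pqs = [CodonSite("AAC", "N", i, True) for i in range(10)]
        non = [CodonSite("AAC", "N", i, False) for i in range(5)] + [
            CodonSite("AAA", "K", i + 5, False) for i in range(5)
        ]
        stats = codon_position_stats(pqs, non)
        assert stats["C3_ratio"] == pytest.approx(2.0)

    def test_identical_composition_unit_ratios(self):
        from g4telo.codon_selection import CodonSite

        codons = ["CCC", "AAA", "GGC", "TTT"]
        pqs = [CodonSite(c, CODON_TO_AA[c], i, True) for i, c in enumerate(codons)]
        non = [CodonSite(c, CODON_TO_AA[c], i, False) for i, c in enumerate(codons)]
        stats = codon_position_stats(pqs, non, amino_acids=("P", "K"))
        assert stats["C3_ratio"] == 1.0
        assert stats["aa_freq_ratio(P)"] == 1.0

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            codon_position_stats([], [])


def test_gc_content_direct():
    assert gc_content("GCG") == pytest.approx(1.0)
    assert gc_content("ATA") == 0.0
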