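"""Composition, codon usage and codon-call logic on hand-countable cases."""

import math

import pytest

from mitoarch import (
    codon_position_composition,
    codon_usage,
    extract_codons,
    region_composition,
    round_percent,
)
from mitoarch.annotation_io import reverse_complement

from conftest import make_record


def single_gene_record(name, cds, strand="J", pad=10):
    """A record holding one gene flanked by G-runs (AT-free padding)."""
    j_strand = cds if strand == "J" else reverse_complement(cds)
    seq = "G" * pad + j_strand + "G" * pad
    return make_record(
        [(name, strand, pad + 1, pad + len(cds))], len(seq), sequence=seq
    )


class TestRegionComposition:
    def test_all_at_sequence(self):
        rec = make_record([("trnA", "J", 1, 4)], 4, sequence="ATAT")
        (prof,) = region_composition(rec, "genome")
        assert prof.at_fraction == 1.0

    def test_base_counts_sum_to_length_and_n_excluded(self):
        rec = make_record([("trnA", "J", 1, 8)], 8, sequence="ATGCNNAT")
        (prof,) = region_composition(rec, "genome")
        assert sum(prof.base_counts.values()) == prof.length == 8
        assert prof.at_fraction == pytest.approx(4 / 6)

    def test_per_gene_profile_uses_coding_strand(self):
        rec = single_gene_record("ND2", "ATGAAATAA", strand="N")
        (prof,) = region_composition(rec, ["ND2"])
        assert prof.base_counts["A"] == 6  # counts of the coding strand, not J
        assert prof.base_counts["T"] == 2

    def test_at_fraction_strand_symmetric(self):
        for cds in ("ATGAAATAA", "ATTCCGGTA", "GGGGGGTTT"):
            j = single_gene_record("ND3", cds, strand="J")
            n = single_gene_record("ND3", cds, strand="N")
            at_j = region_composition(j, ["ND3"])[0].at_fraction
            at_n = region_composition(n, ["ND3"])[0].at_fraction
            assert at_j == pytest.approx(at_n)

    def test_igs_pooling_excludes_control_region(self):
        # gene1 1-10, gap ATAT (11-14), gene2 15-24; CR after srRNA is all G
        seq = "G" * 10 + "ATAT" + "G" * 10 + "GGGG"
        rec = make_record(
            [("trnA", "J", 1, 10), ("srRNA", "N", 15, 24)], 28, sequence=seq
        )
        (prof,) = region_composition(rec, "igs")
        assert prof.length == 4 and prof.at_fraction == 1.0

    def test_missing_sequence_raises(self, atta):
        with pytest.raises(ValueError, match="sequence"):
            region_composition(atta, "genome")

    def test_empty_region_is_nan(self):
        rec = make_record([("trnA", "J", 1, 4)], 4, sequence="NNNN")
        (prof,) = region_composition(rec, "genome")
        assert math.isnan(prof.at_fraction)


class TestCodonPositions:
    def test_hand_counted_single_gene(self):
        # ATG AAA TAA -> pos1 {A,A,T}, pos2 {T,A,A}, pos3 {G,A,A}
        rec = single_gene_record("ND2", "ATGAAATAA")
        p1, p2, p3 = codon_position_composition(rec)
        assert p1.base_counts["A"] == 2 and p1.base_counts["T"] == 1
        assert p2.base_counts["A"] == 2 and p2.base_counts["T"] == 1
        assert p3.base_counts["A"] == 2 and p3.base_counts["G"] == 1
        assert p1.length == p2.length == p3.length == 3

    def test_incomplete_stop_contributes_partial_positions(self):
        # ATG AAA TA -> the trailing TA adds one base to pos1 and pos2 only
        rec = single_gene_record("ATP8", "ATGAAATA")
        p1, p2, p3 = codon_position_composition(rec)
        assert (p1.length, p2.length, p3.length) == (3, 3, 2)
        assert p1.base_counts["A"] == 2 and p1.base_counts["T"] == 1

    def test_unflagged_ragged_length_warns(self):
        # trailing G is not a stop prefix -> warning, base dropped
        rec = single_gene_record("ND2", "ATGAAATAAG")
        with pytest.warns(UserWarning, match="not an incomplete stop"):
            p1, p2, p3 = codon_position_composition(rec)
        assert (p1.length, p2.length, p3.length) == (3, 3, 3)

    def test_n_strand_gene_counted_on_coding_strand(self):
        j = single_gene_record("ND2", "ATGAAATAA", strand="J")
        n = single_gene_record("ND2", "ATGAAATAA", strand="N")
        for pj, pn in zip(codon_position_composition(j), codon_position_composition(n)):
            assert pj.base_counts == pn.base_counts


class TestCodonUsage:
    def test_hand_counted_example(self):
        rec = single_gene_record("ND2", "ATGATTATTTAA")
        table = codon_usage(rec)
        assert table.counts == {"ATG": 1, "ATT": 2, "TAA": 1}
        assert table.incomplete_codons_dropped == 0

    def test_counts_invariant_under_strand_placement(self):
        cds = "ATGATTCCGGGATACTTA" + "TAA"
        j = codon_usage(single_gene_record("COI", cds, strand="J"))
        n = codon_usage(single_gene_record("COI", cds, strand="N"))
        assert j.counts == n.counts

    def test_incomplete_stop_dropped_from_counts(self):
        rec = single_gene_record("ATP8", "ATGAAAT")
        table = codon_usage(rec)
        assert table.counts == {"ATG": 1, "AAA": 1}
        assert table.incomplete_codons_dropped == 1
        assert table.total == 7 // 3

    def test_table5_assignments(self):
        table = codon_usage(single_gene_record("ND2", "ATATGAAGATAA"))
        assert table.amino_acid("ATA") == "M"  # invertebrate mito: ATA=Met
        assert table.amino_acid("TGA") == "W"
        assert table.amino_acid("AGA") == "S"
        assert table.amino_acid("TAA") == "*"

    def test_ranking_breaks_ties_alphabetically(self):
        rec = single_gene_record("ND2", "TTAATTTTAATTGGCTAA")
        ranked = codon_usage(rec).ranked()
        assert [c for c, _, _ in ranked[:2]] == ["ATT", "TTA"]


class TestExtractCodons:
    def test_complete_stop(self):
        rec = single_gene_record("ND2", "ATGAAATAG")
        assert extract_codons(rec)["ND2"] == ("ATG", "TAG", True)

    def test_single_t_incomplete_stop(self):
        rec = single_gene_record("ATP8", "ATAAAAT")
        assert extract_codons(rec)["ATP8"] == ("ATA", "T", False)

    def test_ta_incomplete_stop(self):
        rec = single_gene_record("ATP8", "ATAAAATA")
        assert extract_codons(rec)["ATP8"] == ("ATA", "TA", False)

    def test_unusual_start_codon_warned_but_reported(self):
        rec = single_gene_record("ND2", "CCCAAATAA")
        with pytest.warns(UserWarning, match="unusual start"):
            codons = extract_codons(rec)
        assert codons["ND2"][0] == "CCC"

    def test_non_stop_final_triplet_warned(self):
        rec = single_gene_record("ND2", "ATGAAACCC")
        with pytest.warns(UserWarning, match="not a stop"):
            codons = extract_codons(rec)
        assert codons["ND2"] == ("ATG", "CCC", False)


class TestRounding:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.80849, 80.8), (0.0005, 0.1), (0.864, 86.4), (0.9715, 97.2), (1.0, 100.0)],
    )
    def test_round_half_up_one_decimal(self, fraction, expected):
        assert round_percent(fraction) == expected
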