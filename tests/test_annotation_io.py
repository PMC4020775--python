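"""Feature-table and GenBank parsing, validation, round trips."""

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from mitoarch import (
    GeneFeature,
    MitogenomeRecord,
    ValidationError,
    parse_feature_table,
    parse_genbank,
    write_feature_table,
)
from mitoarch.vocabulary import normalize_gene_name

from conftest import make_record


class TestGeneFeature:
    def test_length_from_inclusive_coordinates(self):
        assert GeneFeature("trnV", "N", 21, 89).length == 69
        assert GeneFeature("ND2", "J", 852, 1832).length == 981

    def test_single_base_feature_is_valid(self):
        assert GeneFeature("trnA", "J", 5, 5).length == 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(name="nonsense", strand="J", start=1, end=9),
            dict(name="trnA", strand="+", start=1, end=9),
            dict(name="trnA", strand="J", start=9, end=1),  # origin-spanning
            dict(name="ND2", strand="J", start=1, end=9, start_codon="AT"),
            dict(name="ND2", strand="J", start=1, end=9, stop_codon="TAAA"),
        ],
    )
    def test_invalid_features_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            GeneFeature(**kwargs)

    def test_short_stop_codon_flags_incomplete(self):
        assert GeneFeature("ATP8", "J", 1, 184, stop_codon="T").has_incomplete_stop
        assert not GeneFeature("ND2", "J", 1, 981, stop_codon="TAA").has_incomplete_stop


class TestRecordValidation:
    def test_duplicate_symbol_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            make_record([("trnA", "J", 1, 10), ("trnA", "J", 20, 30)], 100)

    def test_coordinate_beyond_length_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            make_record([("trnA", "J", 90, 120)], 100)

    def test_empty_record_is_valid(self):
        rec = MitogenomeRecord(genome_id="empty", length=1000)
        assert rec.features == []

    def test_features_sorted_by_start(self):
        rec = make_record([("trnM", "J", 50, 60), ("trnA", "J", 1, 10)], 100)
        assert [f.name for f in rec.features] == ["trnA", "trnM"]


class TestFeatureTableDialect:
    def test_parenthesized_position_encodes_n_strand(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "#length=2000\ngene\tposition\n"
            "trnV\t(21-89)\n"
            "ND2\t852-1832\n"
        )
        rec = parse_feature_table(p)
        trnv, nd2 = rec["trnV"], rec["ND2"]
        assert (trnv.strand, trnv.start, trnv.end, trnv.length) == ("N", 21, 89, 69)
        assert (nd2.strand, nd2.length) == ("J", 981)

    def test_round_trip_is_identity(self, atta, tmp_path):
        p = tmp_path / "out.tsv"
        write_feature_table(atta, p)
        again = parse_feature_table(p)
        assert again.genome_id == atta.genome_id
        assert again.length == atta.length
        assert again.circular == atta.circular
        assert again.features == atta.features

    def test_record_without_codons_round_trips(self, tmp_path):
        rec = make_record([("trnA", "J", 1, 10), ("trnM", "N", 20, 30)], 100)
        p = tmp_path / "r.tsv"
        write_feature_table(rec, p)
        assert parse_feature_table(p).features == rec.features

    def test_empty_record_round_trips(self, tmp_path):
        rec = MitogenomeRecord(genome_id="empty", length=1000)
        p = tmp_path / "e.tsv"
        write_feature_table(rec, p)
        again = parse_feature_table(p)
        assert again.features == [] and again.length == 1000

    def test_unknown_symbol_warned_and_skipped(self, tmp_path):
        p = tmp_path / "u.tsv"
        p.write_text("#length=100\ngene\tstrand\tstart\tend\nmysteryGene\tJ\t1\t10\n")
        with pytest.warns(UserWarning, match="mysteryGene"):
            rec = parse_feature_table(p)
        assert rec.features == []


class TestAttaFixture:
    def test_37_genes_23_majority_14_minority(self, atta):
        assert len(atta.features) == 37
        strands = [f.strand for f in atta.features]
        assert strands.count("J") == 23
        assert strands.count("N") == 14

    def test_sizes_recomputed_from_coordinates(self, atta):
        sizes = {f.name: f.length for f in atta.features}
        assert sizes["ND5"] == 1665
        assert sizes["lrRNA"] == 1426
        assert sizes["srRNA"] == 795
        assert sizes["trnS1"] == 61  # shortest tRNA
        assert sizes["trnR"] == 74  # longest tRNA
        assert sum(sizes.values()) == 14859

    def test_atp8_has_incomplete_stop_annotation(self, atta):
        assert atta["ATP8"].stop_codon == "T"
        assert atta["ATP8"].has_incomplete_stop


def _genbank_file(tmp_path, features, length=1000, topology="circular"):
    seq = Seq("ACGT" * (length // 4))
    rec = SeqRecord(seq, id="test1", name="test1", description="synthetic test record")
    rec.annotations.update(molecule_type="DNA", topology=topology)
    rec.features = features
    path = tmp_path / "t.gb"
    seqio_write([rec], path, "genbank")
    return path


class TestGenBank:
    def test_minimal_record_strands_and_coordinates(self, tmp_path):
        path = _genbank_file(
            tmp_path,
            [
                SeqFeature(SimpleLocation(9, 108, 1), type="CDS", qualifiers={"gene": ["ND2"]}),
                SeqFeature(
                    SimpleLocation(199, 269, -1), type="tRNA",
                    qualifiers={"product": ["tRNA-Val"]},
                ),
            ],
        )
        rec = parse_genbank(path)
        assert len(rec.features) == 2
        nd2, trnv = rec["ND2"], rec["trnV"]
        assert (nd2.strand, nd2.start, nd2.end) == ("J", 10, 108)
        assert (trnv.strand, trnv.start, trnv.end) == ("N", 200, 269)
        assert rec.length == 1000 and rec.circular

    def test_synonyms_map_genbank_names(self, tmp_path):
        path = _genbank_file(
            tmp_path,
            [
                SeqFeature(SimpleLocation(9, 108, 1), type="CDS", qualifiers={"gene": ["CO1"]}),
                SeqFeature(SimpleLocation(199, 298, 1), type="CDS", qualifiers={"gene": ["NAD4L"]}),
                SeqFeature(SimpleLocation(400, 500, -1), type="rRNA", qualifiers={"product": ["rrnL"]}),
            ],
        )
        rec = parse_genbank(path)
        assert {f.name for f in rec.features} == {"COI", "ND4L", "lrRNA"}

    def test_unmappable_names_skipped_with_warning(self, tmp_path):
        path = _genbank_file(
            tmp_path,
            [
                SeqFeature(SimpleLocation(9, 108, 1), type="CDS", qualifiers={"gene": ["ND2"]}),
                SeqFeature(SimpleLocation(200, 300, 1), type="CDS", qualifiers={"gene": ["ORF-foo"]}),
            ],
        )
        with pytest.warns(UserWarning, match="ORF-foo"):
            rec, skipped = parse_genbank(path, with_skipped=True)
        assert [f.name for f in rec.features] == ["ND2"]
        assert skipped == ["ORF-foo"]

    def test_join_features_rejected(self, tmp_path):
        loc = CompoundLocation([SimpleLocation(0, 30, 1), SimpleLocation(50, 80, 1)])
        path = _genbank_file(
            tmp_path, [SeqFeature(loc, type="CDS", qualifiers={"gene": ["ND2"]})]
        )
        with pytest.raises(ValidationError, match="join"):
            parse_genbank(path)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("CO1", "COI"), ("cox3", "COIII"), ("NAD2", "ND2"), ("nd4l", "ND4L"),
        ("rrnS", "srRNA"), ("16S ribosomal RNA", "lrRNA"),
        ("tRNA-Ser(UCN)", "trnS2"), ("trnL2", "trnL2"), ("Cytb", "Cytb"),
        ("completely unknown", None),
    ],
)
def test_name_normalization(raw, expected):
    assert normalize_gene_name(raw) == expected
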