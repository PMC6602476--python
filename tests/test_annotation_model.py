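"""Transcript model construction, coordinate maps and region sequences."""

import numpy as np
import pytest

from modannot import (AnnotationConfig, AnnotationIndex, TranscriptModel,
                      extract_region_sequences, load_annotation,
                      select_representative)
from modannot.annotation_model import (GtfParseError, derive_catalog,
                                       parse_gtf, reverse_complement)

from conftest import oracle_tx_map, plant, random_seq


def _model(tid="TX", gid="G", strand="+", exons=((100, 200),), cds=None,
           biotype="protein_coding"):
    return TranscriptModel(tid, gid, gid, biotype, "chr1", strand,
                           list(exons), list(cds) if cds else None)


class TestTranscriptModel:
    def test_toy_gene_region_partition(self, toy_index):
        m = toy_index.transcripts["TX1"]
        assert m.tx_length == 200
        assert m.utr5_range == (0, 50)
        assert m.cds_range == (50, 150)
        assert m.utr3_range == (150, 200)
        # partition: the three region lengths sum to the transcript length
        assert sum(hi - lo for lo, hi in
                   (m.utr5_range, m.cds_range, m.utr3_range)) == m.tx_length

    def test_noncoding_has_no_region_ranges(self):
        m = _model(cds=None, biotype="lincRNA")
        assert not m.is_coding
        assert m.utr5_range is None and m.cds_range is None

    def test_single_exon_has_no_introns_or_splice_sites(self):
        cat = derive_catalog(_model(), promoter_len=100, chrom_len=1000)
        assert cat.introns == []
        assert cat.splice_5prime_sites == [] == cat.splice_3prime_sites

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            _model(exons=[(100, 200), (150, 300)])

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(ValueError, match="CDS"):
            _model(exons=[(100, 200)], cds=[(250, 280)])


class TestCoordinateMap:
    def test_plus_strand_examples(self, toy_index):
        m = toy_index.transcripts["TX1"]
        assert m.genome_to_tx(150) == 50
        assert m.genome_to_tx(250) is None  # intronic
        assert m.genome_to_tx(300) == 100   # first base of exon 2

    def test_minus_strand_single_exon(self):
        m = _model(strand="-", exons=[(100, 200)])
        assert m.genome_to_tx(100) == 99
        assert m.genome_to_tx(199) == 0

    @pytest.mark.parametrize("strand,exons,cds", [
        ("+", [(100, 200), (300, 400)], [(150, 200), (300, 350)]),
        ("-", [(100, 200), (300, 400)], [(150, 200), (300, 350)]),
        ("-", [(10, 25), (40, 44), (60, 100)], None),
    ])
    def test_round_trip_and_oracle_equivalence(self, strand, exons, cds):
        m = _model(strand=strand, exons=exons, cds=cds)
        pairs = oracle_tx_map(m)
        assert len(pairs) == m.tx_length
        for g, t in pairs:
            assert m.genome_to_tx(g) == t
            assert m.tx_to_genome(t) == g

    def test_minus_strand_map_strictly_decreasing(self):
        m = _model(strand="-", exons=[(10, 30), (50, 70)])
        tx = [m.genome_to_tx(g) for g in range(10, 70)
              if m.genome_to_tx(g) is not None]
        # increasing genomic coordinate -> strictly decreasing transcript pos
        assert all(a > b for a, b in zip(tx, tx[1:]))


class TestRepresentativeSelection:
    def test_coding_beats_longer_noncoding(self):
        coding = _model("TC", exons=[(0, 500)], cds=[(90, 300)])
        nc = _model("TN", exons=[(1000, 1900)], biotype="lincRNA")
        assert select_representative([nc, coding]).transcript_id == "TC"

    def test_tie_broken_by_transcript_id(self):
        t1 = _model("TX1", exons=[(0, 500)], cds=[(90, 300)])
        t2 = _model("TX2", exons=[(1000, 1500)], cds=[(1090, 1300)])
        assert select_representative([t2, t1]).transcript_id == "TX1"

    def test_single_transcript_identity(self):
        t = _model("ONLY")
        assert select_representative([t]) is t


class TestFeatureCatalog:
    def test_minus_strand_promoter_above_tss(self):
        m = _model(strand="-", exons=[(1000, 2000)])
        cat = derive_catalog(m, promoter_len=300, chrom_len=5000)
        assert cat.promoter == (2000, 2300)
        assert cat.promoter[0] > m.tss
        assert cat.downstream == (700, 1000)

    def test_flank_clipped_at_chromosome_start(self):
        m = _model(exons=[(50, 300)])
        cat = derive_catalog(m, promoter_len=200, chrom_len=1000)
        assert cat.promoter == (0, 50)
        assert cat.promoter_clipped

    def test_intron_count_is_exons_minus_one(self):
        m = _model(exons=[(0, 10), (20, 30), (50, 60)])
        cat = derive_catalog(m, promoter_len=10, chrom_len=100)
        assert cat.introns == [(10, 20), (30, 50)]
        assert cat.splice_5prime_sites == [9, 19]
        assert cat.splice_3prime_sites == [10, 20]


class TestSequences:
    def test_cds_sequence_starts_with_start_codon(self, toy_index):
        seqs = extract_region_sequences(toy_index, "cds")
        assert len(seqs["TX1"]) == 100
        assert seqs["TX1"].startswith("ATG")

    def test_minus_strand_reverse_complement(self):
        m = _model(strand="-", exons=[(0, 4)])
        idx = AnnotationIndex([m], {"chr1": "AAAC"})
        assert idx.transcript_seq("TX") == "GTTT"

    def test_utr_of_noncoding_omitted(self):
        m = _model(biotype="lincRNA")
        idx = AnnotationIndex([m], {"chr1": random_seq(300)})
        assert extract_region_sequences(idx, "utr5") == {}

    def test_region_length_matches_range(self, toy_index):
        for region in ("utr5", "cds", "utr3", "tx"):
            seqs = extract_region_sequences(toy_index, region)
            m = toy_index.transcripts["TX1"]
            lo, hi = m.region_range(region)
            assert len(seqs["TX1"]) == hi - lo


class TestGtfIO:
    GTF = (
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_biotype "protein_coding";\n'
        'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1"; gene_biotype "protein_coding";\n'
        'chr1\tsrc\tCDS\t151\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        'chr1\tsrc\tCDS\t301\t350\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
    )

    def test_gtf_one_based_closed_conversion(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(self.GTF)
        models, skipped = parse_gtf(p)
        assert skipped == 0
        (m,) = models
        assert m.exons == [(100, 200), (300, 400)]
        assert m.tx_length == 200
        assert m.cds_range == (50, 150)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(self.GTF + "chr1\tonly\tthree\n")
        with pytest.raises(GtfParseError, match="line 5"):
            parse_gtf(p)

    def test_cds_outside_exons_skips_transcript(self, tmp_path):
        bad = ('chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "G2"; transcript_id "T2";\n'
               'chr1\tsrc\tCDS\t701\t760\t.\t+\t.\tgene_id "G2"; transcript_id "T2";\n')
        p = tmp_path / "skip.gtf"
        p.write_text(self.GTF + bad)
        models, skipped = parse_gtf(p)
        assert skipped == 1
        assert [m.transcript_id for m in models] == ["T1"]

    def test_missing_chromosome_in_fasta_is_hard_error(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(self.GTF)
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chrOther\n" + random_seq(500) + "\n")
        with pytest.raises(ValueError, match="chr1"):
            load_annotation(gtf, fasta)

    def test_biotype_fallback_to_gene_type_then_unknown(self, tmp_path):
        lines = (
            'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "GA"; transcript_id "TA"; gene_type "miRNA";\n'
            'chr1\tsrc\texon\t201\t300\t.\t+\t.\tgene_id "GB"; transcript_id "TB";\n'
        )
        p = tmp_path / "b.gtf"
        p.write_text(lines)
        models, _ = parse_gtf(p)
        by_id = {m.transcript_id: m.biotype for m in models}
        assert by_id == {"TA": "miRNA", "TB": "unknown"}


def test_reverse_complement_round_trip():
    s = random_seq(97, seed=5)
    assert reverse_complement(reverse_complement(s)) == s


def test_fixture_transcriptome_round_trip_identity(fixture_dir):
    """Genome<->transcript map is the identity on every exonic position of
    the generated transcriptome, and the UTR/CDS partition always holds."""
    index = load_annotation(fixture_dir["gtf"], fixture_dir["fasta"])
    assert index.skipped_transcripts == 0
    for model in index.units:
        for g, t in oracle_tx_map(model):
            assert model.genome_to_tx(g) == t
            assert model.tx_to_genome(t) == g
        if model.is_coding:
            u5, cds, u3 = model.utr5_range, model.cds_range, model.utr3_range
            assert u5[1] == cds[0] and cds[1] == u3[0]
            assert u3[1] == model.tx_length
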