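"""Metagene binning, boundary coverage with CI, heatmaps, feature density."""

import numpy as np
import pytest

from modannot import (AnnotationConfig, AnnotationIndex, Site, SiteSet,
                      TranscriptModel, assign_features, boundary_coverage,
                      boundary_heatmap, feature_coverage_summary, metagene)

from conftest import random_seq


def _coding_index(n_tx=1, utr5=100, cds=300, utr3=100, spacing=2000,
                  strand="+", promoter_len=100):
    """Single-exon coding transcripts laid out along one chromosome."""
    tx_len = utr5 + cds + utr3
    models = []
    for i in range(n_tx):
        start = 500 + i * spacing
        models.append(TranscriptModel(
            f"T{i}", f"G{i}", f"g{i}", "protein_coding", "chr1", strand,
            exons=[(start, start + tx_len)],
            cds=[(start + utr5, start + utr5 + cds)] if strand == "+"
            else [(start + utr3, start + utr3 + cds)]))
    chrom_len = 500 + n_tx * spacing + tx_len + 500
    return AnnotationIndex(models, {"chr1": random_seq(chrom_len, seed=3)},
                           config=AnnotationConfig(promoter_len=promoter_len))


def _sites_at_tx(index, tx_id, tx_positions, width=1):
    model = index.transcripts[tx_id]
    sites = []
    for i, tp in enumerate(tx_positions):
        g = model.tx_to_genome(tp)
        sites.append(Site("chr1", g - width // 2, g - width // 2 + width,
                          f"s{tx_id}_{i}", 0.0, model.strand))
    return sites


class TestMetagene:
    def test_single_site_lands_in_expected_bin(self):
        index = _coding_index(utr5=100, cds=300, utr3=100)
        sites = SiteSet(_sites_at_tx(index, "T0", [100 + 150]))  # cds offset 150
        prof = metagene(assign_features(sites, index), index, bins=100)
        assert prof.density[100 + 50] == 1.0  # floor(150/300*100)=50
        assert prof.counts.sum() == 1

    def test_region_boundary_bins(self):
        index = _coding_index(utr5=100, cds=300, utr3=100)
        m = index.transcripts["T0"]
        sites = SiteSet(_sites_at_tx(index, "T0",
                                     [100, 100 + 299, 400, m.tx_length - 1]))
        prof = metagene(assign_features(sites, index), index, bins=100)
        assert prof.density[100] == 1.0          # first base of CDS -> bin 0
        assert prof.density[199] == 1.0          # last base of CDS -> bin 99
        assert prof.density[200] == 1.0          # first base of UTR3
        assert prof.density[299] == 1.0          # last base of UTR3

    def test_short_region_excludes_transcript(self):
        index = _coding_index(utr5=40, cds=300, utr3=150)
        sites = SiteSet(_sites_at_tx(index, "T0", [50]))
        with pytest.raises(ValueError, match="bin-length"):
            metagene(assign_features(sites, index), index, bins=100)
        prof = metagene(assign_features(sites, index), index, bins=30)
        assert prof.n_excluded_short == 0
        assert prof.n_transcripts_used == 1

    def test_count_conservation(self, fixture_dir):
        from modannot import load_annotation, read_bed
        index = load_annotation(fixture_dir["gtf"], fixture_dir["fasta"])
        assignments = assign_features(read_bed(fixture_dir["bed"]), index)
        prof = metagene(assignments, index, bins=50)
        total = prof.density.sum() * prof.n_transcripts_used
        assert total == pytest.approx(prof.n_placed, abs=1e-9)
        assert prof.counts.sum() == prof.n_placed


class TestBoundaryCoverage:
    def test_no_sites_gives_zero_profile(self):
        index = _coding_index()
        prof = boundary_coverage(SiteSet([]), index, "stop_codon", 50)
        assert not prof.mean_cov.any()
        assert not prof.ci_high.any()

    def test_delta_at_stop_codon(self):
        index = _coding_index(utr5=100, cds=300, utr3=200)
        m = index.transcripts["T0"]
        stop = m.cds_range[1] - 1
        sites = SiteSet(_sites_at_tx(index, "T0", [stop]))
        prof = boundary_coverage(assign_features(sites, index), index,
                                 "stop_codon", 100)
        assert prof.mean_cov[100] == 1.0
        assert prof.mean_cov.sum() == 1.0

    def test_ci_hand_computed_for_four_transcripts(self):
        """Site at offset +10 in 2 of 4 transcripts: mean 0.5, SEM of
        {1,1,0,0} = 0.2887, CI = 0.5 +/- 0.566 clipped to [0, 1.0659]."""
        index = _coding_index(n_tx=4)
        sites = []
        for tid in ("T0", "T1"):
            m = index.transcripts[tid]
            sites += _sites_at_tx(index, tid, [m.cds_range[1] - 1 + 10])
        prof = boundary_coverage(assign_features(SiteSet(sites), index),
                                 index, "stop_codon", 100)
        j = 110  # offset +10
        assert prof.mean_cov[j] == pytest.approx(0.5)
        sem = np.std([1, 1, 0, 0], ddof=1) / 2
        assert sem == pytest.approx(0.28867513, abs=1e-8)
        assert prof.ci_high[j] == pytest.approx(0.5 + 1.96 * sem)
        assert prof.ci_low[j] == 0.0  # clipped at zero

    def test_single_unit_ci_collapses_to_mean(self):
        index = _coding_index(n_tx=1)
        m = index.transcripts["T0"]
        sites = SiteSet(_sites_at_tx(index, "T0", [m.cds_range[0]]))
        prof = boundary_coverage(assign_features(sites, index), index,
                                 "start_codon", 20)
        assert np.array_equal(prof.ci_low, prof.mean_cov)
        assert np.array_equal(prof.ci_high, prof.mean_cov)

    def test_full_interval_coverage_not_midpoint(self):
        index = _coding_index()
        m = index.transcripts["T0"]
        stop_g = m.tx_to_genome(m.cds_range[1] - 1)
        sites = SiteSet([Site("chr1", stop_g - 5, stop_g + 6, strand="+")])
        prof = boundary_coverage(sites, index, "stop_codon", 20)
        assert prof.mean_cov[20 - 5:20 + 6].sum() == 11  # every covered nt

    def test_flank_must_be_positive(self):
        index = _coding_index()
        with pytest.raises(ValueError, match="flank"):
            boundary_coverage(SiteSet([]), index, "TSS", 0)

    def test_splice_anchor_on_single_exon_transcriptome_is_empty(self):
        index = _coding_index()
        prof = boundary_coverage(SiteSet([]), index, "splice5", 10)
        assert prof.n_units == 0


class TestBoundaryHeatmap:
    def test_column_means_equal_coverage(self):
        index = _coding_index(n_tx=4)
        sites = []
        for tid in ("T0", "T2"):
            m = index.transcripts[tid]
            sites += _sites_at_tx(index, tid,
                                  [m.cds_range[0] + 3, m.cds_range[0] + 7])
        ss = SiteSet(sites)
        hm = boundary_heatmap(ss, index, "start_codon", 30)
        prof = boundary_coverage(ss, index, "start_codon", 30)
        np.testing.assert_array_equal(hm.to_numpy().mean(axis=0),
                                      prof.mean_cov)

    def test_single_transcript_single_row(self):
        index = _coding_index(n_tx=1)
        m = index.transcripts["T0"]
        ss = SiteSet(_sites_at_tx(index, "T0", [m.cds_range[0]]))
        hm = boundary_heatmap(ss, index, "start_codon", 10)
        prof = boundary_coverage(ss, index, "start_codon", 10)
        assert hm.shape == (1, 21)
        np.testing.assert_array_equal(hm.to_numpy()[0], prof.mean_cov)

    def test_rows_sorted_by_occupancy(self):
        index = _coding_index(n_tx=3)
        sites = []
        # T2 gets 3 covered positions, T0 gets 1, T1 gets 0
        m2 = index.transcripts["T2"]
        sites += _sites_at_tx(index, "T2", [m2.cds_range[0] + o
                                            for o in (1, 4, 8)])
        m0 = index.transcripts["T0"]
        sites += _sites_at_tx(index, "T0", [m0.cds_range[0] + 2])
        hm = boundary_heatmap(SiteSet(sites), index, "start_codon", 10)
        sums = hm.sum(axis=1).to_numpy()
        assert list(sums) == sorted(sums, reverse=True)
        assert hm.index[0].startswith("T2")


class TestFeatureCoverage:
    def test_density_arithmetic(self):
        index = _coding_index(n_tx=10, cds=1000)  # 10 kb of CDS total
        sites = []
        for i in range(10):
            m = index.transcripts[f"T{i}"]
            sites += _sites_at_tx(index, f"T{i}", [m.cds_range[0] + 17])
        df = feature_coverage_summary(
            assign_features(SiteSet(sites), index), index)
        row = df.set_index("category").loc["CDS"]
        assert row["feature_length_nt"] == 10_000
        assert row["density_per_kb"] == pytest.approx(1.0)

    def test_zero_count_zero_density(self):
        index = _coding_index()
        df = feature_coverage_summary([], index).set_index("category")
        assert (df["density_per_kb"] == 0).all()


def test_shift_equivariance():
    """Translating annotation and sites by a constant genomic offset leaves
    every profile unchanged."""
    shift = 1234
    profs = []
    for delta in (0, shift):
        model = TranscriptModel(
            "T", "G", "g", "protein_coding", "chr1", "+",
            exons=[(500 + delta, 700 + delta), (900 + delta, 1300 + delta)],
            cds=[(600 + delta, 700 + delta), (900 + delta, 1200 + delta)])
        index = AnnotationIndex([model],
                                {"chr1": random_seq(3000 + shift, seed=9)},
                                config=AnnotationConfig(promoter_len=100))
        sites = SiteSet([Site("chr1", 650 + delta, 660 + delta, strand="+"),
                         Site("chr1", 950 + delta, 951 + delta, strand="+")])
        a = assign_features(sites, index)
        profs.append((
            boundary_coverage(a, index, "stop_codon", 80).mean_cov,
            metagene(a, index, bins=50).density,
        ))
    np.testing.assert_array_equal(profs[0][0], profs[1][0])
    np.testing.assert_array_equal(profs[0][1], profs[1][1])
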