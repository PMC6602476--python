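"""Shared fixtures: hand-built toy transcript models, a generated synthetic
dataset, and an independent brute-force feature-assignment oracle."""

from __future__ import annotations

import numpy as np
import pytest

from modannot import (AnnotationConfig, AnnotationIndex, FixtureSpec,
                      TranscriptModel, write_fixture)
from modannot.annotation_model import PRIORITY_RANK
from modannot.site_io import midpoint


def random_seq(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def plant(seq: str, pos: int, sub: str) -> str:
    return seq[:pos] + sub + seq[pos + len(sub):]


@pytest.fixture
def toy_index() -> AnnotationIndex:
    """One plus-strand coding gene: exons [100,200)+[300,400), CDS
    [150,200)+[300,350); tx length 200, UTR5 50, CDS 100, UTR3 50.
    An ATG is planted at the CDS start (genomic 150)."""
    seq = plant(random_seq(600, seed=42), 150, "ATG")
    model = TranscriptModel(
        transcript_id="TX1", gene_id="G1", gene_name="gene1",
        biotype="protein_coding", chrom="chr1", strand="+",
        exons=[(100, 200), (300, 400)], cds=[(150, 200), (300, 350)])
    return AnnotationIndex([model], {"chr1": seq},
                           config=AnnotationConfig(promoter_len=50))


@pytest.fixture
def two_gene_index() -> AnnotationIndex:
    """Gene A (coding, + strand) whose intron is overlapped by the CDS of
    gene B (coding, + strand), plus a minus-strand lincRNA gene C."""
    seq = random_seq(3000, seed=7)
    a = TranscriptModel("TXA", "GA", "geneA", "protein_coding", "chr1", "+",
                        exons=[(200, 400), (900, 1100)],
                        cds=[(300, 400), (900, 1000)])
    b = TranscriptModel("TXB", "GB", "geneB", "protein_coding", "chr1", "+",
                        exons=[(500, 800)], cds=[(560, 740)])
    c = TranscriptModel("TXC", "GC", "geneC", "lincRNA", "chr1", "-",
                        exons=[(1500, 1700), (1900, 2000)])
    return AnnotationIndex([a, b, c], {"chr1": seq},
                           config=AnnotationConfig(promoter_len=100))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> dict:
    """Small written fixture bundle shared by IO-level tests."""
    outdir = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(n_genes=20, n_sites=400, seed=11)
    paths = write_fixture(spec, outdir)
    paths["spec_obj"] = spec
    return paths


# -- independent oracle ---------------------------------------------------------


def oracle_categories_at(index: AnnotationIndex, chrom: str, gpos: int,
                         site_strand: str) -> list[tuple]:
    """Every (rank, category, gene_id) whose feature covers one genomic
    position, derived per transcript from first principles (coordinate map
    and strand arithmetic), independent of the package's interval index."""
    out = []
    for model in index.units:
        if model.chrom != chrom:
            continue
        if site_strand in "+-" and model.strand != site_strand:
            continue
        cats = []
        tp = model.genome_to_tx(gpos)
        if tp is not None:
            if model.is_coding:
                if model.cds_range[0] <= tp < model.cds_range[1]:
                    cats.append("CDS")
                elif tp < model.cds_range[0]:
                    cats.append("UTR5")
                else:
                    cats.append("UTR3")
            else:
                cats.append("exon_nc")
        elif model.gstart <= gpos < model.gend:
            cats.append("intron")
        plen = index.config.promoter_len
        chrom_len = index.chrom_sizes[chrom]
        if model.strand == "+":
            prom = (max(0, model.tss - plen), model.tss)
            down = (model.tes + 1, min(chrom_len, model.tes + 1 + plen))
        else:
            prom = (model.tss + 1, min(chrom_len, model.tss + 1 + plen))
            down = (max(0, model.tes - plen), model.tes)
        if prom[0] <= gpos < prom[1]:
            cats.append("promoter")
        if down[0] <= gpos < down[1]:
            cats.append("downstream")
        out.extend((PRIORITY_RANK[c], c, model.gene_id) for c in cats)
    return out


def oracle_assign_category(index: AnnotationIndex, site) -> str:
    """Brute-force priority resolution: enumerate every overlapping
    (position, feature) pair across the site's full interval and take the
    highest-priority category."""
    hits = []
    for gpos in range(site.start, site.end):
        hits.extend(oracle_categories_at(index, site.chrom, gpos, site.strand))
    if not hits:
        return "intergenic"
    return min(hits)[1]


def oracle_tx_map(model: TranscriptModel) -> list[tuple[int, int]]:
    """All (genomic, transcript) position pairs, enumerated exon by exon."""
    pairs = []
    tpos = 0
    for s, e in model.exons:
        span = range(s, e) if model.strand == "+" else range(e - 1, s - 1, -1)
        for g in span:
            pairs.append((g, tpos))
            tpos += 1
    return pairs
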