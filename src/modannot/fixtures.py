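"""Deterministic synthetic test data: toy genome, annotation and site sets.

Generates a single-chromosome toy genome (~200 kb by default) with multi-exon
coding and non-coding genes on both strands, valid start/stop codons at CDS
termini (CDS records include the stop codon), and modification sites drawn
from a configurable placement model -- either Gaussian around a translation
anchor (emulating the stop-codon-proximal density of m6A peaks) or
per-region Poisson rates.  A ground-truth sidecar table records each site's
true category and anchor offset so tests never re-derive truth from the
generator's internals.  The same seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .annotation_model import (AnnotationIndex, AnnotationConfig,
                               TranscriptModel, _tx_range_to_genomic,
                               reverse_complement)
from .enrichment import IUPAC, motif_offset
from .site_io import Site, SiteSet, write_bed

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class FixtureSpec:
    """Parameters of the synthetic transcriptome and site placement.

    Length parameters are inclusive integer ranges drawn uniformly.  Site
    placement is either an anchor name ("stop_codon" / "start_codon") with a
    Gaussian offset (``placement_sd`` nt), or a dict of per-region rates in
    sites per kilobase (keys among utr5/cds/utr3/intron/promoter/downstream).
    """

    n_genes: int = 50
    seed: int = 1
    chrom: str = "chrS"
    coding_frac: float = 0.8
    noncoding_biotype: str = "lincRNA"
    strand_minus_frac: float = 0.5
    utr5_len: tuple[int, int] = (120, 300)
    cds_len: tuple[int, int] = (300, 900)      # rounded to a codon multiple
    utr3_len: tuple[int, int] = (200, 600)
    nc_len: tuple[int, int] = (400, 1200)
    intron_len: tuple[int, int] = (100, 400)
    n_exons: tuple[int, int] = (1, 5)
    gene_gap: tuple[int, int] = (400, 900)
    overlap_frac: float = 0.0                  # fraction of loci forced to
                                               # overlap the previous gene
    n_sites: int = 2000
    site_placement: Union[str, dict] = "stop_codon"
    placement_sd: float = 30.0
    site_width: int = 1
    site_strand: str = "tx"                    # "tx" or "none"
    planted_motif: Optional[str] = None
    motif_modified_offset: Optional[int] = None
    promoter_len: int = 1000

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 <= self.coding_frac <= 1:
            raise ValueError("coding_frac must be a fraction")
        if self.site_width < 1:
            raise ValueError("site_width must be >= 1")


@dataclass
class Transcriptome:
    """In-memory synthetic genome: mutable sequence plus transcript models."""

    chrom: str
    seq: bytearray
    models: list[TranscriptModel]

    @property
    def seqs(self) -> dict[str, str]:
        return {self.chrom: self.seq.decode()}

    def index(self, config: Optional[AnnotationConfig] = None) -> AnnotationIndex:
        return AnnotationIndex(self.models, self.seqs, config=config)


def _rand_seq(rng: np.random.Generator, n: int) -> bytes:
    return rng.choice(_BASES, size=n).tobytes()


def _split_lengths(rng: np.random.Generator, total: int, parts: int,
                   minimum: int = 30) -> list[int]:
    """Split ``total`` into ``parts`` pieces each >= minimum."""
    parts = max(1, min(parts, total // minimum))
    if parts == 1:
        return [total]
    extra = rng.multinomial(total - parts * minimum, [1.0 / parts] * parts)
    return [minimum + int(e) for e in extra]


def make_transcriptome(spec: FixtureSpec) -> Transcriptome:
    """Generate the toy genome and one transcript per gene.

    Loci are laid out left to right with random gaps; with probability
    ``overlap_frac`` a locus is instead placed overlapping the previous one
    (sequence in the shared window belongs to the later gene -- fine for
    interval logic, which is what overlapping fixtures exercise).
    """
    rng = np.random.default_rng(spec.seed)
    infeasible = [(name, rng_) for name, rng_ in
                  (("utr5_len", spec.utr5_len), ("cds_len", spec.cds_len),
                   ("utr3_len", spec.utr3_len), ("intron_len", spec.intron_len))
                  if rng_[0] < 1 or rng_[1] < rng_[0]]
    if infeasible:
        raise ValueError(f"infeasible length ranges: {infeasible}")

    loci: list[tuple[int, bytes, TranscriptModel]] = []
    cursor = spec.promoter_len + 200
    prev_span: Optional[tuple[int, int]] = None

    for gi in range(spec.n_genes):
        gene_id = f"G{gi + 1:04d}"
        tx_id = f"T{gi + 1:04d}"
        coding = bool(rng.random() < spec.coding_frac)
        strand = "-" if rng.random() < spec.strand_minus_frac else "+"

        if coding:
            utr5 = int(rng.integers(spec.utr5_len[0], spec.utr5_len[1] + 1))
            cds = int(rng.integers(spec.cds_len[0], spec.cds_len[1] + 1))
            cds -= cds % 3
            utr3 = int(rng.integers(spec.utr3_len[0], spec.utr3_len[1] + 1))
            tx_len = utr5 + cds + utr3
        else:
            tx_len = int(rng.integers(spec.nc_len[0], spec.nc_len[1] + 1))
            utr5 = cds = utr3 = 0

        tx_seq = bytearray(_rand_seq(rng, tx_len))
        if coding:
            tx_seq[utr5:utr5 + 3] = b"ATG"
            tx_seq[utr5 + cds - 3:utr5 + cds] = b"TAA"

        n_ex = int(rng.integers(spec.n_exons[0], spec.n_exons[1] + 1))
        exon_lens = _split_lengths(rng, tx_len, n_ex)
        intron_lens = [int(rng.integers(spec.intron_len[0],
                                        spec.intron_len[1] + 1))
                       for _ in range(len(exon_lens) - 1)]

        # locus sequence laid out in transcript orientation
        locus = bytearray()
        exon_local: list[tuple[int, int]] = []
        ti = 0
        for k, el in enumerate(exon_lens):
            exon_local.append((len(locus), len(locus) + el))
            locus += tx_seq[ti:ti + el]
            ti += el
            if k < len(intron_lens):
                locus += _rand_seq(rng, intron_lens[k])
        locus_len = len(locus)

        if strand == "-":
            locus = bytearray(reverse_complement(locus.decode()).encode())
            exon_local = [(locus_len - e, locus_len - s)
                          for s, e in exon_local]

        if (prev_span is not None and spec.overlap_frac > 0
                and rng.random() < spec.overlap_frac):
            start = max(spec.promoter_len,
                        prev_span[0] + (prev_span[1] - prev_span[0]) // 2)
        else:
            start = cursor + int(rng.integers(spec.gene_gap[0],
                                              spec.gene_gap[1] + 1))
        exons = [(start + s, start + e) for s, e in exon_local]

        model = TranscriptModel(
            transcript_id=tx_id, gene_id=gene_id, gene_name=f"gene{gi + 1}",
            biotype="protein_coding" if coding else spec.noncoding_biotype,
            chrom=spec.chrom, strand=strand, exons=exons, cds=None)
        if coding:
            cds_giv = _tx_range_to_genomic(model, utr5, utr5 + cds)
            model = TranscriptModel(
                transcript_id=tx_id, gene_id=gene_id,
                gene_name=f"gene{gi + 1}",
                biotype="protein_coding", chrom=spec.chrom, strand=strand,
                exons=exons, cds=cds_giv)

        loci.append((start, bytes(locus), model))
        span_end = start + locus_len
        prev_span = (start, span_end)
        cursor = max(cursor, span_end)

    chrom_len = cursor + spec.promoter_len + 200
    seq = bytearray(_rand_seq(rng, chrom_len))
    for start, locus, _ in loci:
        seq[start:start + len(locus)] = locus
    return Transcriptome(spec.chrom, seq, [m for _, _, m in loci])


def _true_category(model: TranscriptModel, tpos: int) -> str:
    if not model.is_coding:
        return "exon_nc"
    if model.cds_range[0] <= tpos < model.cds_range[1]:
        return "CDS"
    if tpos < model.cds_range[0]:
        return "UTR5"
    return "UTR3"


def _instantiate_iupac(rng: np.random.Generator, motif: str) -> str:
    return "".join(IUPAC[c][int(rng.integers(len(IUPAC[c])))]
                   for c in motif.upper())


def _plant_motif(txome: Transcriptome, model: TranscriptModel, tpos: int,
                 motif: str, off: int, rng: np.random.Generator,
                 guard: set[int]) -> bool:
    """Write a concrete motif instance so its modified base sits at tpos.
    Returns False if the motif window is not contiguous in the genome
    (crosses a splice junction or transcript end) or would overwrite an
    already planted instance."""
    lo = tpos - off
    hi = lo + len(motif)
    if lo < 0 or hi > model.tx_length:
        return False
    gpos = [model.tx_to_genome(t) for t in range(lo, hi)]
    step = -1 if model.strand == "-" else 1
    if any(b - a != step for a, b in zip(gpos, gpos[1:])):
        return False
    if any(g in guard for g in gpos):
        return False
    guard.update(gpos)
    inst = _instantiate_iupac(rng, motif)
    if model.strand == "-":
        gstart = gpos[-1]
        txome.seq[gstart:gstart + len(motif)] = \
            reverse_complement(inst).encode()
    else:
        txome.seq[gpos[0]:gpos[0] + len(motif)] = inst.encode()
    return True


def make_sites(spec: FixtureSpec, txome: Transcriptome
               ) -> tuple[SiteSet, pd.DataFrame]:
    """Draw sites per the placement model; returns (sites, ground truth).

    Anchor placement skips non-coding genes (no translation anchors).  Sites
    are unique by (chrom, start, end, strand); colliding draws are retried.
    When ``planted_motif`` is set the genome window under each site is
    rewritten to contain a concrete motif instance centred on the modified
    base, and sites whose motif window would cross a splice junction are
    redrawn.
    """
    rng = np.random.default_rng(spec.seed + 1)
    coding = [m for m in txome.models if m.is_coding]
    if isinstance(spec.site_placement, str) and not coding:
        raise ValueError("anchor placement needs at least one coding gene")
    moff = (motif_offset(spec.planted_motif, spec.motif_modified_offset)
            if spec.planted_motif else 0)

    sites: list[Site] = []
    truth_rows: list[dict] = []
    used: set[tuple] = set()
    motif_guard: set[int] = set()
    half = spec.site_width // 2

    def commit(model: TranscriptModel, tpos: int, category: str,
               anchor: str, offset) -> bool:
        g = model.tx_to_genome(tpos)
        start = g - half
        end = start + spec.site_width
        if start < 0 or end > len(txome.seq):
            return False
        strand = model.strand if spec.site_strand == "tx" else "."
        key = (txome.chrom, start, end, strand)
        if key in used:
            return False
        if spec.planted_motif and not _plant_motif(
                txome, model, tpos, spec.planted_motif, moff, rng,
                motif_guard):
            return False
        used.add(key)
        name = f"site{len(sites) + 1:05d}"
        sites.append(Site(txome.chrom, start, end, name, 1.0, strand))
        truth_rows.append({
            "name": name, "chrom": txome.chrom, "start": start, "end": end,
            "strand": strand, "gene_id": model.gene_id,
            "transcript_id": model.transcript_id, "category": category,
            "anchor": anchor, "anchor_offset": offset, "tx_pos": tpos,
        })
        return True

    if isinstance(spec.site_placement, str):
        anchor = spec.site_placement
        if anchor not in ("stop_codon", "start_codon"):
            raise ValueError(f"unknown anchor placement {anchor!r}")
        placed = 0
        attempts = 0
        max_attempts = spec.n_sites * 50
        while placed < spec.n_sites and attempts < max_attempts:
            attempts += 1
            model = coding[int(rng.integers(len(coding)))]
            apos = (model.cds_range[1] - 1 if anchor == "stop_codon"
                    else model.cds_range[0])
            offset = int(round(rng.normal(0.0, spec.placement_sd)))
            tpos = min(max(apos + offset, 0), model.tx_length - 1)
            if commit(model, tpos, _true_category(model, tpos), anchor,
                      tpos - apos):
                placed += 1
    else:
        genomic_cats = {"intron", "promoter", "downstream"}
        index = txome.index(AnnotationConfig(promoter_len=spec.promoter_len))
        for model in txome.models:
            cat = index.catalogs.get(model.transcript_id)
            for region, rate in sorted(spec.site_placement.items()):
                if region in ("utr5", "cds", "utr3"):
                    rng_t = model.region_range(region)
                    if rng_t is None:
                        continue
                    lo, hi = rng_t
                    n = rng.poisson(rate * (hi - lo) / 1000.0)
                    for _ in range(int(n)):
                        tpos = int(rng.integers(lo, hi))
                        commit(model, tpos, _true_category(model, tpos),
                               region, tpos - lo)
                elif region == "exon_nc" and not model.is_coding:
                    n = rng.poisson(rate * model.tx_length / 1000.0)
                    for _ in range(int(n)):
                        tpos = int(rng.integers(0, model.tx_length))
                        commit(model, tpos, "exon_nc", region, tpos)
                elif region in genomic_cats and cat is not None:
                    if region == "intron":
                        chunks = cat.introns
                    elif region == "promoter":
                        chunks = [cat.promoter]
                    else:
                        chunks = [cat.downstream]
                    for gs, ge in chunks:
                        if ge <= gs:
                            continue
                        n = rng.poisson(rate * (ge - gs) / 1000.0)
                        for _ in range(int(n)):
                            g = int(rng.integers(gs, ge))
                            start = g - half
                            end = start + spec.site_width
                            strand = (model.strand if spec.site_strand == "tx"
                                      else ".")
                            key = (txome.chrom, start, end, strand)
                            if start < 0 or key in used:
                                continue
                            used.add(key)
                            name = f"site{len(sites) + 1:05d}"
                            sites.append(Site(txome.chrom, start, end, name,
                                              1.0, strand))
                            truth_rows.append({
                                "name": name, "chrom": txome.chrom,
                                "start": start, "end": end, "strand": strand,
                                "gene_id": model.gene_id,
                                "transcript_id": model.transcript_id,
                                "category": region, "anchor": region,
                                "anchor_offset": g - gs, "tx_pos": -1,
                            })

    truth = pd.DataFrame(truth_rows)
    return SiteSet(sites, source_label="fixture"), truth


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in seqs:
            fh.write(f">{chrom}\n")
            s = seqs[chrom]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def write_gtf(models: list[TranscriptModel], path: str | Path) -> None:
    """Emit exon + CDS records (1-based closed) for the generated models."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (f'gene_id "{m.gene_id}"; transcript_id '
                     f'"{m.transcript_id}"; gene_name "{m.gene_name}"; '
                     f'gene_biotype "{m.biotype}";')
            records = [("exon", s, e) for s, e in sorted(m.exons)]
            if m.cds:
                records += [("CDS", s, e) for s, e in sorted(m.cds)]
            for feature, s, e in records:
                fh.write("\t".join([
                    m.chrom, "modannot_fixture", feature,
                    str(s + 1), str(e), ".", m.strand, ".", attrs]) + "\n")


def make_gmt(models: list[TranscriptModel], truth: pd.DataFrame,
             seed: int, n_random_sets: int = 5, set_size: int = 10
             ) -> dict[str, tuple[str, list[str]]]:
    """Toy gene-set collection: one set of truly modified genes plus random
    sets, so over-representation of the modified list is recoverable."""
    rng = np.random.default_rng(seed + 2)
    universe = sorted({m.gene_id for m in models})
    modified = sorted(truth["gene_id"].unique()) if len(truth) else []
    sets: dict[str, tuple[str, list[str]]] = {}
    if modified:
        sets["SET_MODIFIED"] = ("synthetic: genes carrying planted sites",
                                modified)
    for i in range(n_random_sets):
        size = min(set_size, len(universe))
        members = sorted(rng.choice(universe, size=size, replace=False))
        sets[f"SET_RND{i + 1}"] = ("synthetic: random gene set",
                                   [str(g) for g in members])
    return sets


def write_gmt(sets: dict[str, tuple[str, list[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, genes) in sets.items():
            fh.write("\t".join([set_id, desc] + list(genes)) + "\n")


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full fixture bundle into a directory.

    Files: genome.fa, annotation.gtf, sites.bed, truth.tsv, genes.txt
    (a gene-case list: half of the modified genes), sets.gmt, spec.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    txome = make_transcriptome(spec)
    sites, truth = make_sites(spec, txome)  # may plant motifs into the genome

    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "bed": outdir / "sites.bed",
        "truth": outdir / "truth.tsv",
        "genes": outdir / "genes.txt",
        "gmt": outdir / "sets.gmt",
        "spec": outdir / "spec.json",
    }
    write_fasta(txome.seqs, paths["fasta"])
    write_gtf(txome.models, paths["gtf"])
    write_bed(sites, paths["bed"])
    truth.to_csv(paths["truth"], sep="\t", index=False)

    modified = sorted(truth["gene_id"].unique()) if len(truth) else []
    gene_list = modified[: max(1, len(modified) // 2)]
    paths["genes"].write_text("".join(g + "\n" for g in gene_list))
    write_gmt(make_gmt(txome.models, truth, spec.seed), paths["gmt"])

    spec_dict = {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in spec.__dict__.items()}
    paths["spec"].write_text(json.dumps(spec_dict, indent=2) + "\n")
    return paths
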