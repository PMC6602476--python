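"""Motif and gene-set enrichment, and motif-guided peak refinement.

k-mer enrichment is presence/absence: for each k-mer, the number of
foreground windows containing it is compared against a seeded,
feature-category-matched background via the hypergeometric upper tail
(equivalently a one-sided Fisher test on the 2x2 presence table), with
Benjamini-Hochberg adjustment within each k.  Gene-set enrichment over GMT
collections uses the same hypergeometric tail on set overlaps.

Peak refinement turns wide peaks into candidate single-nucleotide sites by
scanning an IUPAC consensus (e.g. RRACH for m6A, GAAGAAG for m1A) over the
peak's transcript-projected sequence and emitting the modified base of every
match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation_model import (AnnotationIndex, CATEGORY_INTERGENIC,
                               TranscriptModel)
from .assignment import FeatureAssignment, assign_features, resolve_site
from .site_io import Site, SiteSet, midpoint

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# default position of the modified base inside known consensus motifs
MOTIF_OFFSETS = {"RRACH": 2, "GAAGAAG": 3}


def iupac_to_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC consensus to an overlapping-match DNA regex."""
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in {motif!r}")
        exp = IUPAC[ch]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    # lookahead so overlapping occurrences are all found
    return re.compile(f"(?=({''.join(parts)}))")


def motif_offset(motif: str, offset: Optional[int] = None) -> int:
    if offset is not None:
        return offset
    return MOTIF_OFFSETS.get(motif.upper(), len(motif) // 2)


# -- flank sequence extraction -------------------------------------------------


def extract_flank_sequences(
        data: Union[SiteSet, Sequence[FeatureAssignment]],
        index: AnnotationIndex, window: int = 21) -> list[str]:
    """Genomic windows of ``window`` nt centered on each site midpoint,
    uppercase, oriented by the host transcript's strand (site strand when
    there is no host).  Windows truncated by a chromosome end are returned
    short; k-mer counting skips sequences shorter than k."""
    if isinstance(data, SiteSet):
        data = assign_features(data, index)
    out = []
    half = window // 2
    for a in data:
        s = a.site
        mid = midpoint(s)
        if a.transcript_id is not None:
            strand = index.transcripts[a.transcript_id].strand
        else:
            strand = s.strand if s.strand in "+-" else "+"
        seq = index.genomic_window(s.chrom, mid - half, mid - half + window,
                                   strand)
        out.append(seq)
    return out


def sample_background(assignments: Sequence[FeatureAssignment],
                      index: AnnotationIndex, window: int = 21,
                      seed: int = 1) -> list[str]:
    """Background windows matched to the foreground's feature-category
    composition: for each foreground site a random position is drawn
    uniformly (length-weighted) from feature chunks of the same category,
    and the window extracted on the feature's strand.  Seeded and
    reproducible."""
    rng = np.random.default_rng(seed)

    chunks_by_cat: dict[str, list[tuple[str, str, int, int]]] = {}
    for model in index.units:
        for hit in index._chunks_for(model):
            chunks_by_cat.setdefault(hit.category, []).append(
                (model.chrom, model.strand, hit.start, hit.end))

    half = window // 2
    out: list[str] = []
    for a in assignments:
        cat = a.category
        chunks = chunks_by_cat.get(cat)
        if cat == CATEGORY_INTERGENIC or not chunks:
            chrom = rng.choice(sorted(index.chrom_sizes))
            pos = int(rng.integers(0, index.chrom_sizes[chrom]))
            strand = "+"
        else:
            weights = np.array([e - s for _, _, s, e in chunks], dtype=float)
            i = int(rng.choice(len(chunks), p=weights / weights.sum()))
            chrom, strand, s, e = chunks[i]
            pos = int(rng.integers(s, e))
        out.append(index.genomic_window(chrom, pos - half, pos - half + window,
                                        strand))
    return out


# -- k-mer enrichment ----------------------------------------------------------


@dataclass
class KmerEnrichmentResult:
    kmer: str
    k: int
    fg_count: int
    fg_total: int
    bg_count: int
    bg_total: int
    log2_enrichment: float
    p: float
    q: float = float("nan")


def hypergeom_upper_tail(x: int, N: int, K: int, n: int) -> float:
    """P[X >= x] for X ~ Hypergeom(N population, K successes, n draws)."""
    return float(hypergeom.sf(x - 1, N, K, n))


def _kmer_presence(seqs: Sequence[str], k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        seq = seq.upper().replace("U", "T")
        if len(seq) < k:
            continue
        total += 1
        for kmer in {seq[i:i + k] for i in range(len(seq) - k + 1)}:
            if "N" in kmer:
                continue
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts, total


def kmer_enrichment(fg: Sequence[str], bg: Sequence[str],
                    k_values: Sequence[int] = (6, 7, 8),
                    ) -> list[KmerEnrichmentResult]:
    """Rank k-mers by foreground-vs-background presence enrichment.

    For each k-mer: hypergeometric upper-tail p of observing >= fg_count
    containing sequences among the fg_total draws from the pooled
    fg+bg sequence population; BH q within each k; results sorted by
    (p, -log2_enrichment, kmer).
    """
    if not fg:
        raise ValueError("empty foreground sequence set")
    results: list[KmerEnrichmentResult] = []
    for k in k_values:
        fg_counts, fg_total = _kmer_presence(fg, k)
        bg_counts, bg_total = _kmer_presence(bg, k)
        if fg_total == 0:
            continue
        rows = []
        for kmer in sorted(set(fg_counts) | set(bg_counts)):
            a, b = fg_counts.get(kmer, 0), bg_counts.get(kmer, 0)
            p = hypergeom_upper_tail(a, fg_total + bg_total, a + b, fg_total)
            log2 = float(np.log2(((a + 0.5) / (fg_total + 1.0))
                                 / ((b + 0.5) / (bg_total + 1.0))))
            rows.append(KmerEnrichmentResult(kmer, k, a, fg_total, b,
                                             bg_total, log2, p))
        if rows:
            qs = multipletests([r.p for r in rows], method="fdr_bh")[1]
            for r, q in zip(rows, qs):
                r.q = float(q)
        results.extend(rows)
    results.sort(key=lambda r: (r.p, -r.log2_enrichment, r.kmer))
    return results


def enrichment_frame(results: Sequence[KmerEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def top_motifs(results: Sequence[KmerEnrichmentResult], n: int = 5,
               k: Optional[int] = None) -> list[KmerEnrichmentResult]:
    """Top-n enriched k-mers (optionally restricted to one k)."""
    pool = [r for r in results if k is None or r.k == k]
    return pool[:n]


# -- peak refinement -----------------------------------------------------------


def refine_peaks_to_sites(peaks: SiteSet, index: AnnotationIndex,
                          motif: str, offset: Optional[int] = None) -> SiteSet:
    """Predict single-nucleotide sites inside peaks from an IUPAC consensus.

    Each peak is projected onto its host transcript's spliced sequence; every
    motif match yields one width-1 site at the modified base (offset 2 for
    RRACH, 3 for GAAGAAG, center otherwise, or an explicit ``offset``),
    mapped back to genomic coordinates.  Peaks with no exonic projection or
    no match contribute nothing.
    """
    pattern = iupac_to_regex(motif)
    off = motif_offset(motif, offset)
    if not 0 <= off < len(motif):
        raise ValueError("modified-base offset outside motif")
    out: list[Site] = []
    for peak in peaks:
        a = resolve_site(peak, index)
        if a.transcript_id is None:
            continue
        model = index.transcripts[a.transcript_id]
        tx_positions = [tp for tp in (model.genome_to_tx(g)
                                      for g in range(peak.start, peak.end)
                                      if model.chrom == peak.chrom)
                        if tp is not None]
        if not tx_positions:
            continue
        lo, hi = min(tx_positions), max(tx_positions) + 1
        seq = index.transcript_seq(model.transcript_id)[lo:hi]
        for m in pattern.finditer(seq):
            tpos = lo + m.start() + off
            g = model.tx_to_genome(tpos)
            if not peak.start <= g < peak.end:
                continue
            out.append(Site(peak.chrom, g, g + 1,
                            name=f"{peak.name}:{motif}@{tpos}",
                            score=peak.score, strand=model.strand))
    return SiteSet(out, source_label=f"{peaks.source_label}:{motif}").dedup()


# -- gene-set enrichment ---------------------------------------------------------


@dataclass
class GeneSetEnrichmentRow:
    set_id: str
    set_name: str
    overlap: int
    set_size: int
    universe: int
    query_size: int
    p: float
    q: float = float("nan")
    genes: tuple[str, ...] = ()


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT collection: set_id <tab> description <tab> genes..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT needs >=3 tab-separated "
                    "fields")
            sets[fields[0]] = (fields[1], [g for g in fields[2:] if g])
    if not sets:
        raise ValueError(f"{path}: empty GMT collection")
    return sets


def geneset_enrichment(query: Sequence[str],
                       gmt: dict[str, tuple[str, list[str]]],
                       universe: Sequence[str],
                       drop_zero_overlap: bool = False,
                       ) -> list[GeneSetEnrichmentRow]:
    """Hypergeometric over-representation of a gene list in GMT sets.

    Sets and query are intersected with the universe first; query genes
    outside the universe are dropped.  p = P[X >= overlap] for
    X ~ Hypergeom(N=|universe|, K=|set|, n=|query|); BH across all tested
    sets.  Zero-overlap sets are reported with p = 1 unless dropped.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if not gmt:
        raise ValueError("empty gene-set collection")
    q_genes = set(query) & uni
    rows: list[GeneSetEnrichmentRow] = []
    for set_id in sorted(gmt):
        name, members = gmt[set_id]
        set_genes = set(members) & uni
        if not set_genes:
            continue
        overlap_genes = sorted(set_genes & q_genes)
        x = len(overlap_genes)
        if x == 0 and drop_zero_overlap:
            continue
        p = hypergeom_upper_tail(x, len(uni), len(set_genes), len(q_genes))
        rows.append(GeneSetEnrichmentRow(
            set_id=set_id, set_name=name, overlap=x,
            set_size=len(set_genes), universe=len(uni),
            query_size=len(q_genes), p=p, genes=tuple(overlap_genes)))
    if rows:
        qs = multipletests([r.p for r in rows], method="fdr_bh")[1]
        for r, qv in zip(rows, qs):
            r.q = float(qv)
    rows.sort(key=lambda r: (r.p, r.set_id))
    return rows


def geneset_frame(rows: Sequence[GeneSetEnrichmentRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        d = dict(r.__dict__)
        d["genes"] = ",".join(d["genes"])
        records.append(d)
    return pd.DataFrame(records)
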