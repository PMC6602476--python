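"""Resolve each site to one gene-feature category and one biotype.

A site interval may overlap many annotated features (the full interval is
used for overlap, not the midpoint).  The winner is the highest-priority
category among all overlaps:

    CDS > 3'UTR > 5'UTR > non-coding exon > intron > promoter > downstream

with no overlap at all yielding ``intergenic``.  Ties within a category are
broken by the feature chunk whose midpoint is nearest the site midpoint,
then by smallest gene_id, then transcript_id, so assignment is deterministic.
Sites with unknown strand (".") match features on both strands; when the
top-priority candidates span both strands a ``both_strand_hit`` flag is set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .annotation_model import (
    AnnotationIndex,
    CATEGORY_INTERGENIC,
    EXONIC_CATEGORIES,
    FeatureHit,
    PRIORITY_ORDER,
)
from .site_io import Site, SiteSet, midpoint


@dataclass
class FeatureAssignment:
    """One site's resolved category, host gene and transcript position."""

    site: Site
    category: str
    biotype: Optional[str] = None
    gene_id: Optional[str] = None
    transcript_id: Optional[str] = None
    tx_pos: Optional[int] = None          # transcript offset of site midpoint
    both_strand_hit: bool = False

    @property
    def is_intergenic(self) -> bool:
        return self.category == CATEGORY_INTERGENIC


def _strand_ok(site_strand: str, feat_strand: str) -> bool:
    return site_strand == "." or site_strand == feat_strand


def resolve_site(site: Site, index: AnnotationIndex) -> FeatureAssignment:
    """Assign one site (see module docstring for the priority rule)."""
    hits = [h for h in index.query_features(site.chrom, site.start, site.end)
            if _strand_ok(site.strand, h.strand)]
    if not hits:
        return FeatureAssignment(site, CATEGORY_INTERGENIC)

    best_rank = min(h.rank for h in hits)
    top = [h for h in hits if h.rank == best_rank]
    smid = midpoint(site)

    def tie_key(h: FeatureHit):
        feat_mid = (h.start + h.end) // 2
        return (abs(feat_mid - smid), h.gene_id, h.transcript_id)

    winner = min(top, key=tie_key)
    model = index.transcripts[winner.transcript_id]
    tx_pos = (model.genome_to_tx(smid)
              if winner.category in EXONIC_CATEGORIES else None)
    return FeatureAssignment(
        site=site,
        category=winner.category,
        biotype=index.genes[winner.gene_id].biotype,
        gene_id=winner.gene_id,
        transcript_id=winner.transcript_id,
        tx_pos=tx_pos,
        both_strand_hit=len({h.strand for h in top}) > 1,
    )


def assign_features(sites: SiteSet, index: AnnotationIndex
                    ) -> list[FeatureAssignment]:
    """Assign every site in the set; sites on chromosomes absent from the
    annotation fall through to intergenic (no features to overlap)."""
    return [resolve_site(s, index) for s in sites]


def category_counts(assignments: Sequence[FeatureAssignment]) -> pd.DataFrame:
    """Count table over the full category vocabulary (order = priority,
    then intergenic); counts always sum to the number of input sites."""
    order = list(PRIORITY_ORDER) + [CATEGORY_INTERGENIC]
    counts = {c: 0 for c in order}
    for a in assignments:
        counts[a.category] += 1
    total = len(assignments)
    df = pd.DataFrame({
        "category": order,
        "count": [counts[c] for c in order],
    })
    df["fraction"] = df["count"] / total if total else 0.0
    return df


def biotype_distribution(assignments: Sequence[FeatureAssignment]
                         ) -> pd.DataFrame:
    """Counts and fractions per host-gene biotype; intergenic sites are
    tallied under their own label.  Fractions sum to 1."""
    counts: dict[str, int] = {}
    for a in assignments:
        label = a.biotype if not a.is_intergenic else CATEGORY_INTERGENIC
        counts[label] = counts.get(label, 0) + 1
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(rows, columns=["biotype", "count"])
    df["fraction"] = df["count"] / total if total else 0.0
    return df


def modified_gene_list(assignments: Sequence[FeatureAssignment]
                       ) -> pd.DataFrame:
    """Unique genes hosting >=1 non-intergenic site, with per-gene totals
    and per-category breakdowns."""
    per_gene: dict[str, dict[str, int]] = {}
    for a in assignments:
        if a.is_intergenic:
            continue
        rec = per_gene.setdefault(a.gene_id, {c: 0 for c in PRIORITY_ORDER})
        rec[a.category] += 1
    rows = []
    for gid in sorted(per_gene):
        rec = per_gene[gid]
        row = {"gene_id": gid, "n_sites": sum(rec.values())}
        row.update(rec)
        rows.append(row)
    columns = ["gene_id", "n_sites"] + list(PRIORITY_ORDER)
    return pd.DataFrame(rows, columns=columns)


def assignments_frame(assignments: Sequence[FeatureAssignment]) -> pd.DataFrame:
    """Per-site table (BED columns + resolved annotation) for TSV output."""
    rows = []
    for a in assignments:
        s = a.site
        rows.append({
            "chrom": s.chrom, "start": s.start, "end": s.end,
            "name": s.name, "score": s.score, "strand": s.strand,
            "category": a.category,
            "biotype": a.biotype or ".",
            "gene_id": a.gene_id or ".",
            "transcript_id": a.transcript_id or ".",
            "tx_pos": a.tx_pos if a.tx_pos is not None else ".",
            "both_strand_hit": int(a.both_strand_hit),
        })
    columns = ["chrom", "start", "end", "name", "score", "strand",
               "category", "biotype", "gene_id", "transcript_id", "tx_pos",
               "both_strand_hit"]
    return pd.DataFrame(rows, columns=columns)
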