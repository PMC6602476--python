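"""Positional density computations.

Two distinct semantics, used deliberately:

* metagene uses site **midpoints** (count semantics): each exonic site
  contributes one count to one bin of a length-normalized transcript model
  (5'UTR / CDS / 3'UTR, 100 equal-size bins per region by default, regions
  shorter than the bin count excluded);

* boundary coverage uses the **full site interval** (coverage semantics):
  for each anchor (TSS, TES, translation start/end, 5'/3' splice junction) a
  0/1 occupancy vector over offsets -flank..+flank is averaged over anchor
  instances, with a 95% confidence band mean +/- 1.96 x SEM per offset.

Offset 0 is the anchor base; upstream (negative offsets) is 5' of the anchor
in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation_model import AnnotationIndex, TranscriptModel
from .assignment import FeatureAssignment
from .site_io import Site, SiteSet

ANCHORS = ("TSS", "TES", "start_codon", "stop_codon", "splice5", "splice3")
_REGION_ORDER = ("utr5", "cds", "utr3")


@dataclass
class MetageneProfile:
    """Binned site-midpoint density over concatenated mRNA regions."""

    region_labels: tuple[str, ...]
    bins_per_region: int
    counts: np.ndarray          # raw midpoint counts per bin
    density: np.ndarray         # counts / n_transcripts_used
    n_transcripts_used: int
    n_excluded_short: int
    n_placed: int

    def to_frame(self) -> pd.DataFrame:
        nb = self.bins_per_region
        return pd.DataFrame({
            "bin": np.arange(len(self.density)),
            "region": [self.region_labels[i // nb]
                       for i in range(len(self.density))],
            "bin_in_region": [i % nb for i in range(len(self.density))],
            "count": self.counts,
            "density": self.density,
        })

    def smoothed(self, window: int) -> np.ndarray:
        """Optional presentation smoothing: centered moving average."""
        if window <= 1:
            return self.density.copy()
        kernel = np.ones(window) / window
        return np.convolve(self.density, kernel, mode="same")


@dataclass
class BoundaryProfile:
    """Per-nucleotide mean coverage around an anchor, with 95% CI band."""

    anchor: str
    offsets: np.ndarray
    mean_cov: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_units: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.offsets,
            "mean": self.mean_cov,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n": self.n_units,
        })


def _as_sites(data: Union[SiteSet, Sequence[FeatureAssignment]]) -> list[Site]:
    if isinstance(data, SiteSet):
        return list(data.sites)
    return [a.site for a in data]


def _site_tree(sites: Sequence[Site]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, s.strand)
    return trees


def _covered(trees: dict[str, IntervalTree], chrom: str, gpos: int,
             strand: str) -> bool:
    tree = trees.get(chrom)
    if tree is None:
        return False
    for iv in tree.at(gpos):
        if iv.data == "." or strand == "." or iv.data == strand:
            return True
    return False


# -- metagene -----------------------------------------------------------------


def metagene(assignments: Sequence[FeatureAssignment], index: AnnotationIndex,
             bins: int = 100,
             regions: Sequence[str] = _REGION_ORDER) -> MetageneProfile:
    """Bin exonic site midpoints over a length-normalized transcript model.

    Eligible transcripts are the coding unit transcripts whose every
    requested region is at least ``bins`` nt long; shorter ones are excluded
    and counted.  Within a region of length L, a midpoint at offset p lands
    in bin floor(p / L * bins); regions are concatenated 5'->3', each with
    equal visual width.  Density is the per-bin count divided by the number
    of eligible transcripts.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    regions = tuple(r for r in _REGION_ORDER if r in set(regions))
    if not regions:
        raise ValueError("no valid regions requested")

    eligible: dict[str, TranscriptModel] = {}
    n_excluded = 0
    for model in index.units:
        if not model.is_coding:
            continue
        lens = [model.region_range(r)[1] - model.region_range(r)[0]
                for r in regions]
        if all(length >= bins for length in lens):
            eligible[model.transcript_id] = model
        else:
            n_excluded += 1
    if not eligible:
        raise ValueError("no transcripts pass bin-length filter")

    counts = np.zeros(bins * len(regions), dtype=float)
    n_placed = 0
    for a in assignments:
        if a.tx_pos is None or a.transcript_id not in eligible:
            continue
        model = eligible[a.transcript_id]
        for ri, region in enumerate(regions):
            lo, hi = model.region_range(region)
            if lo <= a.tx_pos < hi:
                b = int((a.tx_pos - lo) / (hi - lo) * bins)
                counts[ri * bins + b] += 1
                n_placed += 1
                break

    n_used = len(eligible)
    return MetageneProfile(
        region_labels=regions,
        bins_per_region=bins,
        counts=counts,
        density=counts / n_used,
        n_transcripts_used=n_used,
        n_excluded_short=n_excluded,
        n_placed=n_placed,
    )


# -- boundary coverage ----------------------------------------------------------


def _anchor_instances(index: AnnotationIndex, anchor: str
                      ) -> list[tuple[TranscriptModel, str, int]]:
    """(model, space, position) per anchor instance; space is "genomic" for
    TSS/TES (position on the chromosome) or "tx" (transcript offset)."""
    if anchor not in ANCHORS:
        raise ValueError(f"unknown anchor {anchor!r}; choose from {ANCHORS}")
    out: list[tuple[TranscriptModel, str, int]] = []
    for model in index.units:
        cat = index.catalogs[model.transcript_id]
        if anchor == "TSS":
            out.append((model, "genomic", model.tss))
        elif anchor == "TES":
            out.append((model, "genomic", model.tes))
        elif anchor == "start_codon":
            if cat.start_codon_pos is not None:
                out.append((model, "tx", cat.start_codon_pos))
        elif anchor == "stop_codon":
            if cat.stop_codon_pos is not None:
                out.append((model, "tx", cat.stop_codon_pos))
        elif anchor == "splice5":
            out.extend((model, "tx", p) for p in cat.splice_5prime_sites)
        elif anchor == "splice3":
            out.extend((model, "tx", p) for p in cat.splice_3prime_sites)
    return out


def boundary_matrix(data: Union[SiteSet, Sequence[FeatureAssignment]],
                    index: AnnotationIndex, anchor: str, flank: int,
                    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Instances x offsets 0/1 occupancy matrix (unsorted row order).

    Returns (matrix, offsets, row_labels).  Offsets outside the transcript
    or chromosome count as uncovered.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    sites = _as_sites(data)
    trees = _site_tree(sites)
    instances = _anchor_instances(index, anchor)
    offsets = np.arange(-flank, flank + 1)
    mat = np.zeros((len(instances), len(offsets)), dtype=np.int8)
    for i, (model, space, pos) in enumerate(instances):
        chrom, strand = model.chrom, model.strand
        chrom_len = index.chrom_sizes.get(chrom, 0)
        for j, off in enumerate(offsets):
            if space == "tx":
                p = pos + off
                if not 0 <= p < model.tx_length:
                    continue
                g = model.tx_to_genome(p)
            else:
                g = pos + off if strand == "+" else pos - off
                if not 0 <= g < chrom_len:
                    continue
            if _covered(trees, chrom, g, strand):
                mat[i, j] = 1
    labels = [f"{m.transcript_id}@{p}" for m, _, p in instances]
    return mat, offsets, labels


def boundary_coverage(data: Union[SiteSet, Sequence[FeatureAssignment]],
                      index: AnnotationIndex, anchor: str,
                      flank: int) -> BoundaryProfile:
    """Mean per-nucleotide site coverage around an anchor with 95% CI.

    CI = mean +/- 1.96 x SEM per offset, SEM = sd(ddof=1)/sqrt(n); with a
    single anchor instance SEM is defined as 0 so the band collapses to the
    mean.  The lower band is clipped at 0 (coverage cannot be negative).
    """
    mat, offsets, _ = boundary_matrix(data, index, anchor, flank)
    n = mat.shape[0]
    if n == 0:
        empty = np.zeros(2 * flank + 1)
        return BoundaryProfile(anchor, offsets, empty, empty.copy(),
                               empty.copy(), 0)
    mean = mat.mean(axis=0)
    if n > 1:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    half = 1.96 * sem
    return BoundaryProfile(
        anchor=anchor, offsets=offsets, mean_cov=mean,
        ci_low=np.clip(mean - half, 0.0, None), ci_high=mean + half,
        n_units=n,
    )


def boundary_heatmap(data: Union[SiteSet, Sequence[FeatureAssignment]],
                     index: AnnotationIndex, anchor: str, flank: int,
                     sort_rows: bool = True) -> pd.DataFrame:
    """Occupancy heatmap (anchor instances x offsets).

    Rows are sorted by total occupancy descending (stable, so equal-sum rows
    keep anchor order); column means equal ``boundary_coverage`` exactly.
    """
    mat, offsets, labels = boundary_matrix(data, index, anchor, flank)
    df = pd.DataFrame(mat, index=labels, columns=offsets)
    if sort_rows and len(df):
        order = np.argsort(-mat.sum(axis=1), kind="stable")
        df = df.iloc[order]
    return df


# -- feature coverage summary ---------------------------------------------------


def feature_coverage_summary(assignments: Sequence[FeatureAssignment],
                             index: AnnotationIndex) -> pd.DataFrame:
    """Per-category site count, total feature length over unit transcripts,
    and density in sites per kilobase."""
    from .annotation_model import (CATEGORY_CDS, CATEGORY_DOWNSTREAM,
                                   CATEGORY_EXON_NC, CATEGORY_INTRON,
                                   CATEGORY_PROMOTER, CATEGORY_UTR3,
                                   CATEGORY_UTR5, PRIORITY_ORDER)

    lengths = {c: 0 for c in PRIORITY_ORDER}
    for model in index.units:
        cat = index.catalogs[model.transcript_id]
        if model.is_coding:
            for region, key in (("cds", CATEGORY_CDS), ("utr5", CATEGORY_UTR5),
                                ("utr3", CATEGORY_UTR3)):
                lo, hi = model.region_range(region)
                lengths[key] += hi - lo
        else:
            lengths[CATEGORY_EXON_NC] += model.tx_length
        lengths[CATEGORY_INTRON] += sum(e - s for s, e in cat.introns)
        lengths[CATEGORY_PROMOTER] += cat.promoter[1] - cat.promoter[0]
        lengths[CATEGORY_DOWNSTREAM] += cat.downstream[1] - cat.downstream[0]

    counts = {c: 0 for c in PRIORITY_ORDER}
    for a in assignments:
        if a.category in counts:
            counts[a.category] += 1

    rows = []
    for c in PRIORITY_ORDER:
        kb = lengths[c] / 1000.0
        rows.append({
            "category": c,
            "count": counts[c],
            "feature_length_nt": lengths[c],
            "density_per_kb": counts[c] / kb if kb > 0 else 0.0,
        })
    return pd.DataFrame(rows)
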