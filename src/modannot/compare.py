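"""Group-case and gene-case comparison layers over the single-case outputs.

The group case runs assignment and profiles per sample, computes pairwise
site overlaps, and combines the groups (interval intersection or union) into
the set used for shared annotations.  The gene case splits one sample's
assignments into a user gene list versus background and contrasts category
distributions, metagene profiles and gene characteristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_model import AnnotationIndex
from .assignment import (FeatureAssignment, assign_features, category_counts,
                         modified_gene_list)
from .characteristics import compare_characteristics, compute_characteristics
from .profiles import MetageneProfile, metagene
from .site_io import SiteSet, set_algebra


@dataclass
class GroupComparison:
    labels: list[str]
    per_group_assignments: list[list[FeatureAssignment]]
    overlap_matrix: pd.DataFrame       # symmetric; diagonal = group sizes
    category_contrast: pd.DataFrame    # count/fraction per category x group
    combined: SiteSet
    combined_mode: str
    metagenes: dict[str, MetageneProfile] = field(default_factory=dict)


def _pairwise_overlap(a: SiteSet, b: SiteSet) -> int:
    """Number of overlapping site pairs between two sets (symmetric)."""
    count = 0
    bs = sorted(b.sites, key=lambda s: (s.chrom, s.start))
    for s in a.sites:
        for t in bs:
            if (s.chrom == t.chrom and s.start < t.end and t.start < s.end
                    and (s.strand == "." or t.strand == "."
                         or s.strand == t.strand)):
                count += 1
    return count


def group_compare(site_sets: Sequence[SiteSet], index: AnnotationIndex,
                  mode: str = "union",
                  labels: Optional[Sequence[str]] = None,
                  metagene_bins: int = 100) -> GroupComparison:
    """Annotate and contrast >=2 site sets.

    Emits per-group category counts/fractions side by side, all pairwise
    overlap counts, per-group metagene profiles, and the combined set
    (interval union or intersection chain) used for shared annotation.
    """
    if len(site_sets) < 2:
        raise ValueError("group comparison needs at least 2 site sets")
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown combine mode {mode!r}")
    labels = list(labels) if labels else [
        ss.source_label or f"group{i + 1}" for i, ss in enumerate(site_sets)]
    if len(labels) != len(site_sets):
        raise ValueError("labels/groups length mismatch")

    per_group = [assign_features(ss, index) for ss in site_sets]

    n = len(site_sets)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        mat[i, i] = len(site_sets[i])
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _pairwise_overlap(site_sets[i],
                                                      site_sets[j])
    overlap = pd.DataFrame(mat, index=labels, columns=labels)

    contrast_parts = []
    for label, assigns in zip(labels, per_group):
        cc = category_counts(assigns).set_index("category")
        cc.columns = pd.MultiIndex.from_product([[label], cc.columns])
        contrast_parts.append(cc)
    contrast = pd.concat(contrast_parts, axis=1)

    combined = reduce(lambda a, b: set_algebra(a, b, mode), site_sets)

    metagenes = {}
    for label, assigns in zip(labels, per_group):
        try:
            metagenes[label] = metagene(assigns, index, bins=metagene_bins)
        except ValueError:
            pass  # e.g. toy annotation with no bin-eligible transcript

    return GroupComparison(
        labels=labels, per_group_assignments=per_group,
        overlap_matrix=overlap, category_contrast=contrast,
        combined=combined, combined_mode=mode, metagenes=metagenes)


@dataclass
class GeneCaseReport:
    matched_genes: list[str]
    unmatched_ids: list[str]
    in_list: list[FeatureAssignment]
    background: list[FeatureAssignment]
    category_contrast: pd.DataFrame
    gene_table: pd.DataFrame
    characteristics_comparison: pd.DataFrame
    metagene_in_list: Optional[MetageneProfile] = None
    metagene_background: Optional[MetageneProfile] = None


def match_gene_ids(ids: Sequence[str], index: AnnotationIndex
                   ) -> tuple[list[str], list[str]]:
    """Resolve user identifiers to annotation gene_ids: exact gene_id match
    first, then gene_name; case-sensitive.  Returns (gene_ids, unmatched)."""
    by_name: dict[str, str] = {}
    for gid, rec in index.genes.items():
        by_name.setdefault(rec.gene_name, gid)
    matched, unmatched = [], []
    for raw in ids:
        if raw in index.genes:
            matched.append(raw)
        elif raw in by_name:
            matched.append(by_name[raw])
        else:
            unmatched.append(raw)
    return sorted(set(matched)), unmatched


def gene_case(assignments: Sequence[FeatureAssignment],
              gene_list: Sequence[str], index: AnnotationIndex,
              metagene_bins: int = 100) -> GeneCaseReport:
    """Contrast sites on a user gene list against all other genes.

    Splits assignments into in-list vs background by host gene, then builds
    side-by-side category distributions, metagene profiles per subset, and a
    gene-characteristics comparison (list genes vs the rest of the
    annotation).
    """
    matched, unmatched = match_gene_ids(gene_list, index)
    if not matched:
        examples = list(index.genes)[:3]
        names = [index.genes[g].gene_name for g in examples]
        raise ValueError(
            "no gene list entries matched the annotation; accepted ID "
            f"namespaces are gene_id (e.g. {examples}) and gene_name "
            f"(e.g. {names})")

    in_set = set(matched)
    in_list = [a for a in assignments if a.gene_id in in_set]
    background = [a for a in assignments
                  if a.gene_id is not None and a.gene_id not in in_set]

    parts = []
    for label, assigns in (("in_list", in_list), ("background", background)):
        cc = category_counts(assigns).set_index("category")
        cc.columns = pd.MultiIndex.from_product([[label], cc.columns])
        parts.append(cc)
    contrast = pd.concat(parts, axis=1)

    table = compute_characteristics(index)
    bg_genes = set(table["gene_id"]) - in_set
    if bg_genes:
        char_cmp = compare_characteristics(in_set, bg_genes, table)
    else:
        char_cmp = pd.DataFrame()

    def safe_metagene(assigns):
        try:
            return metagene(assigns, index, bins=metagene_bins)
        except ValueError:
            return None

    return GeneCaseReport(
        matched_genes=matched, unmatched_ids=unmatched,
        in_list=in_list, background=background,
        category_contrast=contrast,
        gene_table=modified_gene_list(list(assignments)),
        characteristics_comparison=char_cmp,
        metagene_in_list=safe_metagene(in_list),
        metagene_background=safe_metagene(background),
    )
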