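"""Per-region gene characteristics and foreground/background comparison.

For each unit transcript and region (5'UTR, CDS, 3'UTR, whole transcript)
the table holds sequence length, GC fraction, and an optional secondary
structure score.  Structure scoring (e.g. minimum free energy) is a pluggable
backend -- either a Python callable ``seq -> float`` or a shell command
template run once per sequence -- so the comparison machinery is testable
without a thermodynamic folder installed.

Group comparison uses the two-sided Mann-Whitney U test (exact for groups of
<= 8 without ties, normal approximation with tie correction otherwise) with
Benjamini-Hochberg adjustment across every comparison in the report.
"""

from __future__ import annotations

import shlex
import subprocess
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_model import AnnotationIndex

REGIONS = ("utr5", "cds", "utr3", "tx")
StructureBackend = Union[Callable[[str], float], str, None]


def gc_fraction(seq: str) -> float:
    """GC fraction of a sequence; 0.0 for an empty sequence."""
    if not seq:
        return 0.0
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def _run_structure_backend(backend: StructureBackend, seq: str
                           ) -> Optional[float]:
    if backend is None:
        return None
    if callable(backend):
        return float(backend(seq))
    # command template: sequence on stdin, one float on stdout (first token
    # of the last non-empty line, so RNAfold-style output also works)
    proc = subprocess.run(shlex.split(backend), input=seq + "\n",
                          capture_output=True, text=True, check=True)
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    token = lines[-1].split()[0].strip("()")
    return float(token)


def compute_characteristics(index: AnnotationIndex,
                            regions: Sequence[str] = REGIONS,
                            structure_backend: StructureBackend = None,
                            ) -> pd.DataFrame:
    """Length / GC / optional structure score per unit transcript and region.

    Regions absent on a transcript (UTRs of non-coding genes, zero-length
    UTRs) are omitted.
    """
    rows = []
    for model in index.units:
        for region in regions:
            rng = model.region_range(region)
            if rng is None or rng[1] <= rng[0]:
                continue
            seq = index.transcript_seq(model.transcript_id)[rng[0]:rng[1]]
            rows.append({
                "gene_id": model.gene_id,
                "transcript_id": model.transcript_id,
                "region": region,
                "length": len(seq),
                "gc": gc_fraction(seq),
                "structure_score": _run_structure_backend(structure_backend,
                                                          seq),
            })
    return pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "region", "length", "gc",
                       "structure_score"])


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value; exact when both groups are small
    (n <= 8) and tie-free, else normal approximation with tie correction."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) \
        else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def compare_characteristics(foreground: Iterable[str],
                            background: Optional[Iterable[str]],
                            table: pd.DataFrame) -> pd.DataFrame:
    """Compare characteristic distributions between two gene groups.

    ``foreground`` is a set of gene_ids; ``background`` defaults to all other
    genes in the table.  One row per (region, characteristic) with group
    medians, effect direction (by median), Mann-Whitney p and BH q across the
    whole report.  Reversing the groups flips the direction and keeps p.
    """
    fg = set(foreground)
    universe = set(table["gene_id"])
    if not fg & universe:
        raise ValueError("foreground contains no genes present in the table")
    bg = set(background) if background is not None else universe - fg
    if not bg:
        raise ValueError("background is empty (foreground == universe?)")

    characteristics = ["length", "gc"]
    if table["structure_score"].notna().any():
        characteristics.append("structure_score")

    rows = []
    for region in table["region"].unique():
        sub = table[table["region"] == region]
        fg_rows = sub[sub["gene_id"].isin(fg)]
        bg_rows = sub[sub["gene_id"].isin(bg)]
        if fg_rows.empty or bg_rows.empty:
            continue
        for char in characteristics:
            x = fg_rows[char].dropna().to_numpy()
            y = bg_rows[char].dropna().to_numpy()
            if len(x) == 0 or len(y) == 0:
                continue
            med_fg, med_bg = float(np.median(x)), float(np.median(y))
            if med_fg > med_bg:
                direction = "greater"
            elif med_fg < med_bg:
                direction = "less"
            else:
                direction = "none"
            rows.append({
                "region": region, "characteristic": char,
                "n_fg": len(x), "n_bg": len(y),
                "median_fg": med_fg, "median_bg": med_bg,
                "direction": direction,
                "p": mann_whitney(x, y),
            })
    report = pd.DataFrame(
        rows, columns=["region", "characteristic", "n_fg", "n_bg",
                       "median_fg", "median_bg", "direction", "p"])
    if len(report):
        report["q"] = multipletests(report["p"], method="fdr_bh")[1]
    else:
        report["q"] = []
    return report
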