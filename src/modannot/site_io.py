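"""Reading, validating and writing modification-site sets in BED.

Accepts plain, gzip-compressed, or single-member zip BED with 3-6 columns.
Missing name/score/strand columns are filled with ".", 0, ".".  Track,
browser and comment lines are skipped; malformed data lines are rejected and
counted rather than aborting the run.
"""

from __future__ import annotations

import gzip
import io
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

logger = logging.getLogger("modannot")


class BedParseError(ValueError):
    pass


@dataclass(frozen=True)
class Site:
    """One modification site or peak: 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if self.start >= self.end:
            raise ValueError(f"start {self.start} >= end {self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)


def midpoint(site: Site) -> int:
    """Genomic midpoint, floor((start+end)/2); a width-1 site returns its own
    position.  Wide peaks are placed at this single position in all
    positional (metagene / boundary-distance) computations."""
    return (site.start + site.end) // 2


@dataclass
class SiteSet:
    """Validated, sorted collection of sites from one sample."""

    sites: list[Site]
    source_label: str = ""
    skipped: int = 0
    duplicates_removed: int = 0

    def __post_init__(self) -> None:
        self.sites = sorted(self.sites,
                            key=lambda s: (s.chrom, s.start, s.end, s.strand))

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[Site]:
        return iter(self.sites)

    @property
    def is_single_nucleotide(self) -> bool:
        return all(s.width == 1 for s in self.sites)

    def dedup(self) -> "SiteSet":
        seen: set = set()
        keep: list[Site] = []
        for s in self.sites:
            k = s.key()
            if k in seen:
                continue
            seen.add(k)
            keep.append(s)
        removed = len(self.sites) - len(keep)
        if removed:
            logger.warning("%s: removed %d duplicate site(s)",
                           self.source_label or "site set", removed)
        return SiteSet(keep, source_label=self.source_label,
                       skipped=self.skipped,
                       duplicates_removed=self.duplicates_removed + removed)


def _open_text(path: Path) -> io.TextIOBase:
    suffix = path.suffix.lower()
    if suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    if suffix == ".zip":
        zf = zipfile.ZipFile(path)
        members = [n for n in zf.namelist() if not n.endswith("/")]
        if len(members) != 1:
            raise BedParseError(
                f"{path}: zip archive must contain exactly one file, "
                f"found {len(members)}")
        return io.TextIOWrapper(zf.open(members[0]))
    return open(path)


def read_bed(path: str | Path, dedup: bool = True) -> SiteSet:
    """Parse a BED3-BED6 file (optionally .gz / .zip) into a SiteSet.

    Data lines with fewer than 3 columns raise; lines with start >= end or
    non-integer coordinates are rejected and tallied in ``skipped``.
    Duplicate (chrom, start, end, strand) records are dropped by default.
    """
    path = Path(path)
    sites: list[Site] = []
    skipped = 0
    n_data_lines = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if (not line.strip() or line.startswith("#")
                    or line.startswith(("track", "browser"))):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: BED needs >=3 columns, "
                    f"got {len(fields)}")
            n_data_lines += 1
            try:
                start, end = int(fields[1]), int(fields[2])
                if start < 0 or start >= end:
                    raise ValueError
                name = fields[3] if len(fields) > 3 and fields[3] else "."
                score = float(fields[4]) if len(fields) > 4 and fields[4] not in (".", "") else 0.0
                strand = fields[5] if len(fields) > 5 and fields[5] else "."
                sites.append(Site(fields[0], start, end, name, score, strand))
            except ValueError:
                skipped += 1
                logger.warning("%s: line %d rejected: %r", path, lineno, line)
    if n_data_lines == 0:
        raise BedParseError(f"{path}: no BED records found")
    out = SiteSet(sites, source_label=path.name, skipped=skipped)
    return out.dedup() if dedup else out


def write_bed(sites: Iterable[Site], path: str | Path,
              extra_columns: Optional[dict[str, list]] = None) -> None:
    """Write BED6; ``extra_columns`` appends documented extension columns
    (e.g. the resolved feature category in column 7)."""
    site_list = list(sites)
    extras = extra_columns or {}
    for values in extras.values():
        if len(values) != len(site_list):
            raise ValueError("extra column length mismatch")
    with open(path, "w") as fh:
        for i, s in enumerate(site_list):
            row = [s.chrom, str(s.start), str(s.end), s.name,
                   f"{s.score:g}", s.strand]
            row.extend(str(extras[k][i]) for k in extras)
            fh.write("\t".join(row) + "\n")


def _strands_compatible(a: str, b: str) -> bool:
    # overlap respects strand only when both strands are known
    return a == "." or b == "." or a == b


def _overlaps(a: Site, b: Site) -> bool:
    return (a.chrom == b.chrom and a.start < b.end and b.start < a.end
            and _strands_compatible(a.strand, b.strand))


def set_algebra(a: SiteSet, b: SiteSet, op: str) -> SiteSet:
    """Interval intersection/union of two site sets.

    ``intersection`` returns the sites of ``a`` that overlap (>=1 nt, strand
    aware when both strands known) at least one site of ``b``.  ``union``
    returns the merged interval set; merged records take the common strand if
    all contributors agree, else ".".
    """
    if op == "intersection":
        b_sorted = sorted(b.sites, key=lambda s: (s.chrom, s.start))
        hits = [s for s in a.sites
                if any(_overlaps(s, t) for t in b_sorted)]
        return SiteSet(hits, source_label=f"{a.source_label}&{b.source_label}")
    if op == "union":
        merged: list[Site] = []
        pool = sorted(list(a.sites) + list(b.sites),
                      key=lambda s: (s.chrom, s.start, s.end))
        for s in pool:
            if merged:
                last = merged[-1]
                if (last.chrom == s.chrom and s.start < last.end
                        and _strands_compatible(last.strand, s.strand)):
                    strand = last.strand if last.strand == s.strand else "."
                    merged[-1] = Site(last.chrom, last.start,
                                      max(last.end, s.end),
                                      last.name, max(last.score, s.score),
                                      strand)
                    continue
            merged.append(s)
        return SiteSet(merged, source_label=f"{a.source_label}|{b.source_label}")
    raise ValueError(f"unknown set operation {op!r}")
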