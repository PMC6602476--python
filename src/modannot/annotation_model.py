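"""Transcript models built from GTF + FASTA.

Parses gene annotation (GTF, Ensembl/GENCODE dialects) and genome sequence
(FASTA) into per-transcript models with a genome<->transcript coordinate map,
selects one representative transcript per gene, and derives the gene features
the rest of the pipeline consumes: 5'UTR / CDS / 3'UTR ranges in transcript
coordinates, introns, promoter and downstream flanks, splice-junction and
start/stop-codon anchor positions.

Coordinate conventions
----------------------
GTF records are 1-based closed; they are converted on ingest and everything
internal is 0-based half-open.  Transcript coordinates run 5'->3' in
transcript orientation (position 0 is the first transcribed base).
"""

from __future__ import annotations

import json
import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger("modannot")

# Feature categories, highest priority first.  A site overlapping several
# features is resolved to the lowest rank.  "exon_nc" covers exonic overlap
# of non-coding transcripts; "intergenic" means no overlap at all.
CATEGORY_CDS = "CDS"
CATEGORY_UTR3 = "UTR3"
CATEGORY_UTR5 = "UTR5"
CATEGORY_EXON_NC = "exon_nc"
CATEGORY_INTRON = "intron"
CATEGORY_PROMOTER = "promoter"
CATEGORY_DOWNSTREAM = "downstream"
CATEGORY_INTERGENIC = "intergenic"

PRIORITY_ORDER: tuple[str, ...] = (
    CATEGORY_CDS,
    CATEGORY_UTR3,
    CATEGORY_UTR5,
    CATEGORY_EXON_NC,
    CATEGORY_INTRON,
    CATEGORY_PROMOTER,
    CATEGORY_DOWNSTREAM,
)
PRIORITY_RANK: dict[str, int] = {c: i for i, c in enumerate(PRIORITY_ORDER)}
EXONIC_CATEGORIES = frozenset(
    {CATEGORY_CDS, CATEGORY_UTR5, CATEGORY_UTR3, CATEGORY_EXON_NC}
)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AnnotationConfig:
    """Flank and isoform parameters for feature derivation.

    All lengths are nucleotides.  ``flank_tss`` is the half-window around
    transcription start/end sites in boundary-coverage plots, ``flank_codon``
    around translation start/end, ``flank_splice`` around splice junctions.
    ``promoter_len`` sets both the promoter (upstream of TSS) and downstream
    (past TES) genomic feature extents.
    """

    flank_tss: int = 1000
    flank_codon: int = 100
    flank_splice: int = 100
    promoter_len: int = 1000
    isoform_mode: str = "representative"  # or "all"

    @classmethod
    def from_file(cls, path: str | Path) -> "AnnotationConfig":
        """Read a config from JSON or flat ``key=value`` lines."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                data[key.strip()] = value.strip()
        kwargs = {}
        for f in ("flank_tss", "flank_codon", "flank_splice", "promoter_len"):
            if f in data:
                kwargs[f] = int(data[f])
        if "isoform_mode" in data:
            kwargs["isoform_mode"] = str(data["isoform_mode"])
        return cls(**kwargs)


class GtfParseError(ValueError):
    """Malformed GTF input; message carries the offending line number."""


@dataclass
class TranscriptModel:
    """One transcript: exon/CDS structure plus the coordinate map.

    ``exons`` are genomic 0-based half-open intervals ordered 5'->3' in
    transcript orientation (descending genomic start on the minus strand).
    ``utr5_range``/``cds_range``/``utr3_range`` are transcript-coordinate
    half-open intervals; absent (None) for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: Optional[list[tuple[int, int]]] = None
    tx_length: int = 0
    utr5_range: Optional[tuple[int, int]] = None
    cds_range: Optional[tuple[int, int]] = None
    utr3_range: Optional[tuple[int, int]] = None
    # cumulative exon-start offsets in transcript space, parallel to exons
    _cum: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        gsorted = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(gsorted, gsorted[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {gsorted}")
        self.exons = gsorted if self.strand == "+" else gsorted[::-1]
        self._cum = []
        total = 0
        for s, e in self.exons:
            self._cum.append(total)
            total += e - s
        self.tx_length = total
        if self.cds is not None:
            self.cds = sorted(self.cds)
            lo = self.genome_to_tx(self.cds[0][0])
            hi = self.genome_to_tx(self.cds[-1][1] - 1)
            if lo is None or hi is None:
                raise ValueError(
                    f"{self.transcript_id}: CDS outside exon union")
            cds_start, cds_end = min(lo, hi), max(lo, hi) + 1
            cds_len = sum(e - s for s, e in self.cds)
            if cds_end - cds_start != cds_len:
                raise ValueError(
                    f"{self.transcript_id}: CDS not contiguous in "
                    "transcript space")
            self.cds_range = (cds_start, cds_end)
            self.utr5_range = (0, cds_start)
            self.utr3_range = (cds_end, self.tx_length)

    # -- coordinate map -----------------------------------------------------

    def genome_to_tx(self, gpos: int) -> Optional[int]:
        """Transcript offset of a genomic position, or None if intronic or
        outside the transcript."""
        for (s, e), off in zip(self.exons, self._cum):
            if s <= gpos < e:
                if self.strand == "+":
                    return off + (gpos - s)
                return off + (e - 1 - gpos)
        return None

    def tx_to_genome(self, tpos: int) -> int:
        """Genomic position of a transcript offset (inverse of
        :meth:`genome_to_tx`)."""
        if not 0 <= tpos < self.tx_length:
            raise IndexError(
                f"transcript position {tpos} outside [0,{self.tx_length})")
        i = bisect_right(self._cum, tpos) - 1
        s, e = self.exons[i]
        within = tpos - self._cum[i]
        return s + within if self.strand == "+" else e - 1 - within

    # -- derived positions --------------------------------------------------

    @property
    def is_coding(self) -> bool:
        return self.cds is not None

    @property
    def gstart(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def gend(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def tss(self) -> int:
        """Genomic position of the first transcribed base."""
        return self.gstart if self.strand == "+" else self.gend - 1

    @property
    def tes(self) -> int:
        """Genomic position of the last transcribed base."""
        return self.gend - 1 if self.strand == "+" else self.gstart

    def region_range(self, region: str) -> Optional[tuple[int, int]]:
        """Transcript-coordinate range of utr5/cds/utr3/tx, or None."""
        if region == "tx":
            return (0, self.tx_length)
        rng = {"utr5": self.utr5_range, "cds": self.cds_range,
               "utr3": self.utr3_range}.get(region)
        if region not in ("utr5", "cds", "utr3"):
            raise ValueError(f"unknown region {region!r}")
        return rng


@dataclass
class FeatureCatalog:
    """Per-transcript derived features (genomic flanks, introns, anchors)."""

    transcript_id: str
    promoter: tuple[int, int]
    promoter_clipped: bool
    downstream: tuple[int, int]
    downstream_clipped: bool
    introns: list[tuple[int, int]]
    splice_5prime_sites: list[int]   # tx coord of last base of upstream exon
    splice_3prime_sites: list[int]   # tx coord of first base of downstream exon
    start_codon_pos: Optional[int]   # tx coord of first CDS base
    stop_codon_pos: Optional[int]    # tx coord of last CDS base
    promoter_len: int


def derive_catalog(model: TranscriptModel, promoter_len: int,
                   chrom_len: Optional[int] = None) -> FeatureCatalog:
    """Derive promoter/downstream flanks, introns and anchor positions.

    Flanks are clipped at chromosome boundaries (flagged), never dropped.
    On the minus strand the promoter lies at higher genomic coordinates
    than the TSS.
    """
    tss, tes = model.tss, model.tes
    if model.strand == "+":
        prom = (tss - promoter_len, tss)
        down = (tes + 1, tes + 1 + promoter_len)
    else:
        prom = (tss + 1, tss + 1 + promoter_len)
        down = (tes - promoter_len, tes)

    def clip(iv: tuple[int, int]) -> tuple[tuple[int, int], bool]:
        s, e = iv
        cs = max(0, s)
        ce = min(e, chrom_len) if chrom_len is not None else e
        return (cs, max(cs, ce)), (cs, ce) != (s, e)

    prom, prom_clipped = clip(prom)
    down, down_clipped = clip(down)

    gsorted = sorted(model.exons)
    introns = [(e1, s2) for (_, e1), (s2, _) in zip(gsorted, gsorted[1:])]

    cum = 0
    splice5, splice3 = [], []
    for s, e in model.exons[:-1]:
        cum += e - s
        splice5.append(cum - 1)
        splice3.append(cum)

    start_codon = stop_codon = None
    if model.cds_range is not None:
        start_codon = model.cds_range[0]
        stop_codon = model.cds_range[1] - 1

    return FeatureCatalog(
        transcript_id=model.transcript_id,
        promoter=prom, promoter_clipped=prom_clipped,
        downstream=down, downstream_clipped=down_clipped,
        introns=introns,
        splice_5prime_sites=splice5, splice_3prime_sites=splice3,
        start_codon_pos=start_codon, stop_codon_pos=stop_codon,
        promoter_len=promoter_len,
    )


class FeatureHit(NamedTuple):
    """One feature chunk in the genome-wide overlap index."""

    category: str
    rank: int
    gene_id: str
    transcript_id: str
    strand: str
    start: int
    end: int


@dataclass
class GeneRecord:
    gene_id: str
    gene_name: str
    biotype: str
    transcript_ids: list[str]


def select_representative(transcripts: Sequence[TranscriptModel]) -> TranscriptModel:
    """Deterministic per-gene isoform choice: coding preferred, then longest
    transcript, ties broken by lexicographically smallest transcript_id."""
    if not transcripts:
        raise ValueError("gene has no transcripts")
    return min(transcripts,
               key=lambda t: (not t.is_coding, -t.tx_length, t.transcript_id))


class _FastaAdapter:
    """Uniform uppercase substring access over pyfaidx or a plain dict."""

    def __init__(self, source) -> None:
        self._source = source

    def __contains__(self, chrom: str) -> bool:
        if isinstance(self._source, Mapping):
            return chrom in self._source
        return chrom in self._source.keys()

    def keys(self):
        return list(self._source.keys())

    def length(self, chrom: str) -> int:
        return len(self._source[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        start = max(0, start)
        end = min(end, self.length(chrom))
        if end <= start:
            return ""
        chunk = self._source[chrom][start:end]
        return str(chunk).upper()


class AnnotationIndex:
    """All transcript models plus overlap/lookup structures.

    ``units`` are the transcripts actually profiled: one representative per
    gene by default, or every transcript in ``isoform_mode="all"``.  The
    feature interval index covers units only, so every site resolves against
    the same isoform set used for profiles.
    """

    def __init__(self, models: Iterable[TranscriptModel], seqs,
                 config: Optional[AnnotationConfig] = None,
                 skipped_transcripts: int = 0) -> None:
        self.config = config or AnnotationConfig()
        self.seqs = _FastaAdapter(seqs)
        self.skipped_transcripts = skipped_transcripts
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, GeneRecord] = {}
        for m in models:
            if m.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {m.transcript_id}")
            self.transcripts[m.transcript_id] = m
            rec = self.genes.get(m.gene_id)
            if rec is None:
                self.genes[m.gene_id] = GeneRecord(
                    m.gene_id, m.gene_name, m.biotype, [m.transcript_id])
            else:
                rec.transcript_ids.append(m.transcript_id)

        missing = sorted({m.chrom for m in self.transcripts.values()
                          if m.chrom not in self.seqs})
        if missing:
            raise ValueError(
                "FASTA is missing chromosomes used by the annotation: "
                + ", ".join(missing))
        self.chrom_sizes = {c: self.seqs.length(c) for c in self.seqs.keys()}

        self.representative: dict[str, str] = {}
        for gid, rec in self.genes.items():
            models_g = [self.transcripts[t] for t in rec.transcript_ids]
            self.representative[gid] = select_representative(models_g).transcript_id

        if self.config.isoform_mode == "all":
            unit_ids = sorted(self.transcripts)
        else:
            unit_ids = sorted(self.representative.values())
        self.units: list[TranscriptModel] = [self.transcripts[t] for t in unit_ids]

        self.catalogs: dict[str, FeatureCatalog] = {
            m.transcript_id: derive_catalog(
                m, self.config.promoter_len, self.chrom_sizes.get(m.chrom))
            for m in self.units
        }
        self._tx_seq_cache: dict[str, str] = {}
        self._build_feature_index()

    # -- feature index ------------------------------------------------------

    def _chunks_for(self, model: TranscriptModel) -> list[FeatureHit]:
        """Genomic chunks of every feature category for one unit transcript."""
        cat = self.catalogs[model.transcript_id]
        out: list[FeatureHit] = []

        def add(category: str, start: int, end: int) -> None:
            if end > start:
                out.append(FeatureHit(category, PRIORITY_RANK[category],
                                      model.gene_id, model.transcript_id,
                                      model.strand, start, end))

        if model.is_coding:
            for region, category in (("cds", CATEGORY_CDS),
                                     ("utr5", CATEGORY_UTR5),
                                     ("utr3", CATEGORY_UTR3)):
                lo, hi = model.region_range(region)
                for gs, ge in _tx_range_to_genomic(model, lo, hi):
                    add(category, gs, ge)
        else:
            for gs, ge in sorted(model.exons):
                add(CATEGORY_EXON_NC, gs, ge)
        for gs, ge in cat.introns:
            add(CATEGORY_INTRON, gs, ge)
        add(CATEGORY_PROMOTER, *cat.promoter)
        add(CATEGORY_DOWNSTREAM, *cat.downstream)
        return out

    def _build_feature_index(self) -> None:
        self.feature_tree: dict[str, IntervalTree] = {}
        for model in self.units:
            tree = self.feature_tree.setdefault(model.chrom, IntervalTree())
            for hit in self._chunks_for(model):
                tree.addi(hit.start, hit.end, hit)

    def query_features(self, chrom: str, start: int, end: int) -> list[FeatureHit]:
        """All feature chunks overlapping [start, end) on a chromosome."""
        tree = self.feature_tree.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    # -- sequences ----------------------------------------------------------

    def transcript_seq(self, transcript_id: str) -> str:
        """Spliced, strand-corrected transcript sequence (5'->3')."""
        cached = self._tx_seq_cache.get(transcript_id)
        if cached is not None:
            return cached
        m = self.transcripts[transcript_id]
        parts = []
        for s, e in m.exons:
            chunk = self.seqs.fetch(m.chrom, s, e)
            parts.append(chunk if m.strand == "+" else reverse_complement(chunk))
        seq = "".join(parts)
        self._tx_seq_cache[transcript_id] = seq
        return seq

    def genomic_window(self, chrom: str, start: int, end: int,
                       strand: str = "+") -> str:
        seq = self.seqs.fetch(chrom, start, end)
        return seq if strand != "-" else reverse_complement(seq)

    def invalidate_seq_cache(self) -> None:
        self._tx_seq_cache.clear()


def _tx_range_to_genomic(model: TranscriptModel, lo: int, hi: int
                         ) -> list[tuple[int, int]]:
    """Genomic intervals covering transcript range [lo, hi)."""
    out: list[tuple[int, int]] = []
    for (s, e), off in zip(model.exons, model._cum):
        length = e - s
        a, b = max(lo, off), min(hi, off + length)
        if a >= b:
            continue
        if model.strand == "+":
            out.append((s + (a - off), s + (b - off)))
        else:
            out.append((e - (b - off), e - (a - off)))
    return sorted(out)


# -- GTF parsing -------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"|(\w+)\s+([^;\s]+)')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for m in _ATTR_RE.finditer(attr_field):
        if m.group(1):
            attrs.setdefault(m.group(1), m.group(2))
        else:
            attrs.setdefault(m.group(3), m.group(4))
    return attrs


def parse_gtf(gtf_path: str | Path) -> tuple[list[TranscriptModel], int]:
    """Parse exon and CDS records into transcript models.

    Returns (models, n_skipped) where n_skipped counts transcripts dropped
    because their CDS falls outside the exon union.  Raises
    :class:`GtfParseError` with a line number on malformed lines.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)  # to 0-based half-open
            except ValueError as exc:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: invalid interval "
                    f"{start_s}-{end_s}")
            attrs = _parse_attributes(attr)
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id")
            if not tid or not gid:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: missing gene_id/transcript_id")
            biotype = (attrs.get("transcript_biotype")
                       or attrs.get("gene_biotype")
                       or attrs.get("gene_type")
                       or "unknown")
            info = meta.setdefault(tid, {
                "gene_id": gid,
                "gene_name": attrs.get("gene_name", gid),
                "biotype": biotype,
                "chrom": chrom,
                "strand": strand,
            })
            if info["chrom"] != chrom or info["strand"] != strand:
                raise GtfParseError(
                    f"{gtf_path}: line {lineno}: transcript {tid} spans "
                    "multiple chromosomes/strands")
            (exons if feature == "exon" else cds).setdefault(tid, []).append(
                (start, end))

    models: list[TranscriptModel] = []
    skipped = 0
    for tid, info in meta.items():
        if tid not in exons:
            logger.warning("transcript %s has CDS but no exon records; skipped", tid)
            skipped += 1
            continue
        try:
            models.append(TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                gene_name=info["gene_name"],
                biotype=info["biotype"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=exons[tid],
                cds=cds.get(tid),
            ))
        except ValueError as exc:
            logger.warning("transcript %s skipped: %s", tid, exc)
            skipped += 1
    return models, skipped


def load_annotation(gtf_path: str | Path, fasta_path: str | Path,
                    config: Optional[AnnotationConfig] = None) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from a GTF and a genome FASTA.

    Chromosome naming must be consistent between the two files; a mismatch
    raises with the list of missing chromosomes.
    """
    import pyfaidx

    models, skipped = parse_gtf(gtf_path)
    fasta = pyfaidx.Fasta(str(fasta_path))
    return AnnotationIndex(models, fasta, config=config,
                           skipped_transcripts=skipped)


def extract_region_sequences(index: AnnotationIndex, region: str
                             ) -> dict[str, str]:
    """Spliced, strand-corrected sequence of one region per unit transcript.

    ``region`` is one of utr5/cds/utr3/tx.  Transcripts lacking the region
    (non-coding, or zero-length UTR) are omitted.
    """
    out: dict[str, str] = {}
    for model in index.units:
        rng = model.region_range(region)
        if rng is None or rng[1] <= rng[0]:
            continue
        seq = index.transcript_seq(model.transcript_id)
        out[model.transcript_id] = seq[rng[0]:rng[1]]
    return out
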