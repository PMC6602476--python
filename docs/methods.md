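# Methods

## Transcript models and coordinates

GTF records (1-based closed) are converted on ingest to 0-based half-open
intervals; all internal coordinates and all TSV outputs use that convention
(stated in each file's header). Transcript coordinates run 5'→3' in
transcript orientation. Each transcript model holds its exon structure, an
invertible genome↔transcript map (identity on exonic positions, absent on
intronic ones), and — for coding transcripts — the 5'UTR/CDS/3'UTR partition
in transcript coordinates, which always sums to the transcript length.

One **representative transcript per gene** is used for every positional
computation: coding isoforms are preferred over non-coding, then the longest
transcript, with ties broken by lexicographically smallest transcript id.
The rationale is that each site should contribute one position to one
metagene axis; averaging over isoforms would double-count sites and blur
boundaries. `isoform_mode="all"` switches to profiling every transcript.

GTF dialects are handled permissively: attributes may be quoted or bare; the
biotype is taken from `transcript_biotype`, then `gene_biotype`, then
`gene_type` (GENCODE), else `"unknown"`. Transcripts whose CDS falls outside
their exon union are skipped and counted; a chromosome present in the GTF
but missing from the FASTA is a hard error listing the mismatches.

### Derived features and anchors

* **Promoter / downstream**: fixed-length genomic flanks (default 1000 nt,
  `promoter_len`) upstream of the TSS and past the TES in transcript
  orientation; clipped at chromosome ends and flagged, never dropped. On the
  minus strand the promoter lies at higher genomic coordinates than the TSS.
* **Introns**: gaps between consecutive exons (count = exons − 1).
* **Translation anchors**: start = first CDS base, end = last CDS base, in
  transcript coordinates. The synthetic GTF writes CDS records that include
  the stop codon, so the translation-end anchor is the final stop-codon
  base; with annotations whose CDS excludes the stop codon the anchor is the
  last coding base — a 3-nt convention difference that profile users should
  keep in mind.
* **Splice anchors**: the 5' (donor) anchor is the transcript position of
  the last base of the upstream exon; the 3' (acceptor) anchor is the first
  base of the downstream exon.

## Site input

BED3–BED6 (plain, gzip, or single-member zip). Missing name/score/strand
columns are filled with `.`, 0, `.`; track/browser/comment lines are
ignored; data lines with invalid coordinates are rejected and counted rather
than aborting; fewer than three columns or an empty file is an error.
Duplicate `(chrom, start, end, strand)` records are dropped by default (with
a logged count) so densities are not inflated by resubmitted rows.

Wide peaks and point sites are both supported with deliberately different
semantics: **feature assignment and boundary coverage use the full
interval**, while **metagene and flank-sequence extraction use the interval
midpoint** `floor((start+end)/2)`, which keeps bin counts integral.

## Priority resolution

A site may overlap many features (including features of several genes). The
resolved category is the highest-priority one among all strand-compatible
overlaps:

```
CDS > 3'UTR > 5'UTR > exon_nc > intron > promoter > downstream
```

with no overlap yielding `intergenic`. `exon_nc` (exon of a non-coding
transcript) is an explicit category here: such a site has a host gene, so it
can be neither intergenic nor any mRNA region; it is ranked between 5'UTR
and intron and feeds the biotype table through its host gene. Ties within a
category are broken deterministically: nearest feature-chunk midpoint to the
site midpoint, then smallest gene id, then transcript id. Strandless sites
(`.`) match both strands; when the top-priority candidates span both strands
a `both_strand_hit` flag is recorded. Sites on chromosomes absent from the
annotation resolve to intergenic.

Category counts always sum to the number of input sites (conservation), and
the implementation is tested for exact agreement with a brute-force
enumerate-every-overlap-and-rank oracle on randomized overlapping
annotations.

## Profiles

**Metagene** (default 100 bins per region over 5'UTR, CDS, 3'UTR): eligible
transcripts are the coding representatives whose every requested region is
at least as long as the bin count; shorter ones are excluded and counted. A
midpoint at offset p in a region of length L lands in bin `floor(p/L·B)`;
density is the per-bin count divided by the number of eligible transcripts,
so `Σ density × n_transcripts_used` equals the number of placed midpoints
exactly. Regions get equal visual width (the binning is per-feature
equal-size); a moving-average smoother is available but off by default so
raw values stay testable.

**Boundary coverage**: for each anchor instance, a 0/1 vector over offsets
−f..+f (anchor at 0; negative = 5' in transcript orientation) marks
positions covered by any strand-compatible site interval; positions outside
the transcript or chromosome count as uncovered. The profile is the mean
over all anchor instances (denominator = all representative transcripts
carrying the anchor, not only covered ones) with a 95% band
mean ± 1.96·sd/√n per offset, sd with one delta degree of freedom, lower
band clipped at 0, and SEM defined as 0 when n = 1 (the band collapses to
the mean rather than dividing by zero). Heatmaps are the underlying
instance × offset matrices, rows sorted by total occupancy (stable), whose
column means equal the coverage profile exactly.

**Feature coverage summary**: per category, the site count, the total
feature length over representative transcripts, and the density in sites
per kilobase.

## Gene characteristics

Length and GC fraction per region (5'UTR/CDS/3'UTR/whole transcript) per
representative transcript. Secondary-structure scoring (e.g. minimum free
energy) is a plug point: a Python callable `seq → float` or a shell command
template reading the sequence on stdin and printing one number (an RNAfold
style last-line `(… MFE)` output also parses); no folding engine is bundled
and the score column is absent unless a backend is configured. Group
comparisons use the two-sided Mann–Whitney U test — exact when both groups
have ≤ 8 tie-free observations, normal approximation with tie correction
otherwise (the identical-distribution degenerate case returns p = 1) — with
direction by group medians and BH adjustment across every row of the report.
Reversing the groups flips the direction and preserves p.

## Enrichment

**Motifs.** Foreground sequences are fixed windows (default 21 nt) centered
on site midpoints, oriented by the host transcript strand; the background
draws, per foreground site, one position uniformly (length-weighted) from
feature chunks of the same resolved category and extracts the same window —
matching the foreground's feature composition rather than the naked genome,
so enrichment is not dominated by coding-sequence base composition. The
sampler is seeded and reproducible. For each k (defaults 6/7/8 in the CLI;
any set can be requested), k-mer presence/absence per sequence is compared
by the hypergeometric upper tail on the pooled sequence population
(equivalently one-sided Fisher), with a +0.5/+1 pseudocount log2 enrichment
for ranking display, BH within each k, and results ordered by (p,
−log2 enrichment). Sequences shorter than k (e.g. clipped at a chromosome
end) are excluded from that k's totals. The reported motif list is the top
five overall. A known caveat at small scale: windows overlapping around the
same anchor share flanking sequence, so locus-specific k-mers can rank
alongside a planted consensus; the category-matched background does not
model this positional clustering.

**Peak refinement.** An IUPAC consensus is scanned (with overlaps) over each
peak's transcript-projected spliced sequence; every match emits one width-1
genomic site at the modified base — offset 2 in RRACH, offset 3 in GAAGAAG,
`floor(len/2)` for other motifs, all overridable. Output sites are always
contained in the input peak. Peaks with no exonic projection contribute
nothing.

**Gene sets.** GMT collections are intersected with the universe (all
annotated genes by default); per set, p = P[X ≥ overlap] for X ~
Hypergeom(|universe|, |set|, |query|), BH across all tested sets;
zero-overlap sets report p = 1 under the upper-tail convention unless
filtered. The implementation is checked against exact rational-arithmetic
enumeration.

## Group and gene cases

The group case runs assignment and profiles per sample, reports all pairwise
site-overlap counts (symmetric matrix, diagonal = group sizes), side-by-side
category fractions, per-group metagenes, and a combined set by interval
union or intersection that feeds shared annotation. The gene case matches
user identifiers against gene ids then gene names (case-sensitive,
unmatched ids reported), splits assignments into in-list versus background
genes, and mirrors the group-case outputs plus a characteristics comparison
of list genes against the rest of the annotation. Category-fraction
contrasts are descriptive by default (no test), matching how such summaries
are normally read.

## Synthetic data generator

The generator emulates the geometry of a modification dataset, not its
sequencing noise: a single ~200 kb chromosome with 50 genes by default
(80% coding, half on the minus strand, 1–5 exons, uniform region lengths:
5'UTR 120–300 nt, CDS 300–900 nt rounded to codons with planted ATG/TAA
termini, 3'UTR 200–600 nt, introns 100–400 nt), and sites drawn either
Gaussian around a translation anchor (default: stop codon, sd 30 nt,
2000 single-nucleotide sites — the canonical stop-codon-proximal geometry of
m6A data) or from per-region Poisson rates. Ground truth (category, anchor
offset, host gene) is emitted as a sidecar table so tests assert against the
file, never the generator's internals. The same seed yields byte-identical
outputs. Optional features: forced gene overlap (for priority-rule stress
tests), IUPAC motif planting under every site (instances instantiated
randomly per site, kept non-overlapping so each site's window verifiably
contains an intact centered instance — which caps the number of placeable
sites under very dense placement), gene lists and GMT collections including
the set of truly modified genes.

What it does **not** emulate — and therefore what passing tests do not show
about real data: read-level coverage and peak-caller artifacts, expression-
dependent site detectability, realistic exon/intron length and GC
distributions, isoform diversity (one transcript per gene), overlapping-gene
sequence content (in overlap windows the later locus wins), and chromosome-
scale composition.

## Numerical conventions and edge cases

* SEM with a single unit is 0; CI bands clip at 0 from below.
* Empty site sets propagate as empty tables/zero profiles, not errors;
  "no transcripts pass bin-length filter" and "empty foreground" are errors
  because the requested statistic is undefined.
* Metagene and boundary windows silently treat positions beyond transcript
  or chromosome ends as uncovered.
* Hypergeometric tails come from scipy (`hypergeom.sf(x−1, …)`); BH from
  statsmodels. Exact Mann–Whitney only without ties and n ≤ 8 per group.
* All randomness (background sampling, fixture generation) flows through
  explicit integer seeds; default seed 1.
* Problem sizes used in tests and the acceptance script (50-gene toy genome,
  ≤ 2000 sites, 200 three-gene randomized annotations for the oracle check)
  were chosen so the full pipeline exercises every code path at desk scale.

## Known limitations

* One representative isoform per gene is an approximation; `all` mode exists
  but averages are then isoform-weighted, not gene-weighted.
* The argmax of a raw boundary-coverage profile is a noisy mode estimator
  when the number of anchor instances is small and center coverage
  saturates; prefer the metagene peak location or a smoothed profile when
  locating enrichment maxima at toy scale.
* The motif background matches feature-category composition but not GC or
  positional clustering; locus-shared k-mers can co-rank with genuine
  consensus motifs in small foregrounds.
* No normalization against input/control libraries, no quantitative
  methylation levels, no differential testing between conditions — the tool
  annotates and compares given site sets.
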