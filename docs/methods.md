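# Methods

`chipnet` reimplements, as a tested library and pipeline, an integrative
analysis of transcription-factor genomics in the early zebrafish embryo:
where Smad2 (the Nodal effector) and Eomesodermin a (Eomesa) bind the
genome, which genes those binding events plausibly regulate, how far the
Smad2-directed network is conserved across vertebrates, and whether
binding classes predict transcriptional responsiveness. This note records
the models, conventions, defaults, and numerical choices, and what the
synthetic fixtures do and do not establish.

## Coordinate and interval conventions

All internal coordinates are 0-based half-open (BED convention); GTF/GFF
input (1-based inclusive) is converted on read, so BED files round-trip
bit-exactly. Interval overlap is defined as at least `min_overlap` shared
base pairs (default 1 bp; the minimal reading of "binding at the same
coordinates", configurable for sensitivity analysis). A peak's midpoint
is `floor((start + end) / 2)`.

Replicate-consensus peaks are connected components of the overlap
relation over the pooled replicate peaks; a component containing at least
one peak from each replicate emits one consensus interval spanning the
component's union, with height equal to the maximum member height. The
union-span policy is a design choice (an intersection policy would give
narrower peaks and slightly different downstream counts); it is recorded
in outputs so the two can be compared. With `min_overlap` > 1, intervals
narrower than `min_overlap` can never overlap anything by enough bases,
so they are singleton components and are excluded up front — this is what
makes a single left-to-right sweep exact.

Peak heights are reads per million (RPM), and the low/medium/high classes
use factor-specific inclusive boundaries: Smad2 low <= 1.5 < medium <= 3 <
high; Eomesa low <= 1 < medium <= 1.5 < high (Eomesa reads are split over
many more peaks, hence the lower scale). The stated ranges do not pin the
boundary points themselves; the inclusive-on-the-left convention used here
is documented and overridable.

## Proximal binding

A peak is proximal to a gene when the peak interval intersects the closed
window [TSS - W, TSS + W], W = 10 kb by default. The TSS is strand-aware
(gene start on +, gene end - 1 on -). Whole-interval intersection is the
inclusive reading of "binding within 10 kb"; a midpoint mode is available
as a config switch. One consequence worth noting: in interval mode a wide
peak whose edge clips the window is assigned even though its midpoint
distance can exceed W by up to half the peak width, so the signed
midpoint-based distance bound is W + width/2, not W (midpoint mode
restores the strict bound). Signed distances are strand-oriented: negative
means upstream of the gene. The relation is many-to-many: one peak can be
proximal to several genes and vice versa.

TSS distance profiles count each peak once, against its nearest TSS on
the same chromosome; equidistant genes are tie-broken by lexicographic
gene id (this affects profiles only, never assignment). Peaks on
chromosomes without genes, or farther than the profile span, are
excluded.

## Co-occupancy classes

Peak level: an A peak is shared when it overlaps at least one B peak.
Gene level, over a fixed gene universe:

- `common` — the gene has proximal peaks of both factors and at least one
  proximal A/B pair overlap each other;
- `uncommon` — proximal peaks of both factors, but no overlapping pair;
- `A_only` / `B_only` — proximal peaks of one factor only;
- `none` — no proximal peak of either factor.

`common` wins over `uncommon` when a gene has both overlapping and
non-overlapping pairs, matching the gene-level framing in which common
and uncommon are exclusive labels. `|common| + |uncommon|` always equals
the number of genes proximal to both factors.

## Motif scanning

A JASPAR position frequency matrix is regularised with a pseudocount
distributed by background frequency and converted to log2 odds:

    M[b, j] = log2((counts[b, j] + pc * bg[b]) / (col_total[j] + pc) / bg[b])

with `pc = 0.8` and uniform background by default (both configurable).
Window scores are rescaled to a relative score
`(raw - min) / (max - min)` in [0, 1], where min and max are the lowest
and highest scores the matrix can produce; the default hit threshold is a
relative score of 0.80 (TFBS-suite convention). Both strands are scanned;
reverse-strand windows are scored with the reverse-complemented matrix
and reported at their forward-strand offset. Windows containing N are
skipped, not scored. The consensus string always attains relative score
exactly 1.0 because its score is assembled from the same per-column
maxima, in the same order, as the maximum itself.

Per-peak best hits break relative-score ties by smaller offset, then +
strand. Centrality is measured as the mean |motif centre - peak midpoint|
of best hits, reported alongside the same statistic under uniform
re-randomisation of hit positions within their peaks (100 draws by
default); centrally planted motifs sit far below this null. Between-set
enrichment of hit rates uses the Pearson chi-square on the 2x2
with/without table, with fold reported as the ratio of hit rates.

A numerical subtlety: forward and reverse strand scores sum the same
column values in opposite orders, so hits lying within ~1e-9 of the
relative threshold can be admitted on one strand-orientation of a
sequence and not its reverse complement. Tests of the strand-mirror
property therefore exclude hits inside that margin; analyses should not
interpret threshold-grazing hits as strand-specific.

## Cross-species conservation

Foreign-species bound gene sets are projected onto reference gene ids via
an ortholog table of (source, target, homology type) records. All three
homology types (one2one, one2many, many2many) are included by default —
the "orthologues and possible orthologues" reading — with an optional
restriction to one2one for sensitivity analysis. Projection is a set
union (duplicates collapse; genes reachable from multiple foreign genes
count once); inputs with no ortholog are dropped from overlap analysis
but counted and reported. Venn partitions over 2-4 named sets report all
2^k - 1 disjoint membership patterns; a gene's conservation class is the
number of non-reference species whose projected set contains it.

## Association statistics

Responsive gene sets come from differential-expression tables thresholded
at P <= 0.02 (microarray) or P <= 0.05 (RNA-seq), split by the sign of the
log2 fold change; genes with log2fc exactly 0 join neither set.
Binding-class-vs-responsiveness association uses the Pearson chi-square
on the 2x2 table over the gene universe, without Yates continuity
correction (counts here are large, and the plain statistic is the stated
convention); the focal cell is class-and-responsive, so fold enrichment
above 1 means the class is enriched for responsive genes, and the sample
odds ratio ad/bc is reported alongside. Degenerate tables (any zero
marginal — e.g. a universe in which every gene is responsive) are an
error, not a silent 0. Term-set fold enrichment is
(hits/|set|)/(|term|/|universe|) with a two-sided Fisher exact P, since
term sets can be small. No multiple-testing correction is applied by
default (raw P values are reported); callers batching many tests can
apply Benjamini-Hochberg themselves.

ChIP-qPCR arithmetic: percent input = 100 * E^(adjusted input Ct - target
Ct), where the input Ct is adjusted for its dilution and the
amplification efficiency E defaults to 2.0 (configurable); fold
enrichment is percent-input of the ChIP over the IgG control.

## Synthetic data: what it emulates and what it does not

The generators produce a coupled genome / annotation / peak / motif /
ortholog / expression bundle with every planted label recorded in a
truth JSON. A single root seed fans out to per-component child seeds
through fixed numpy `SeedSequence` spawn keys, so components regenerate
independently and reruns are byte-identical.

Defaults (the simulated study conditions): uniform-random DNA; genes 2-6
kb, non-overlapping, random strand; proximal peaks centred at a random
gene's TSS + N(0, 3 kb), background peaks uniform on gene-free space;
peak widths uniform 200-800 bp; cofactor sharing probability 0.4 per base
peak (matching the observed two-factor co-occurrence rate) with partner
centres jittered by N(0, 100 bp) but clamped to guarantee overlap;
motif instances planted in half the peaks at N(0, 50 bp) from the
midpoint; three foreign species with conservation fractions 0.5/0.4/0.3
and 10% one2many fan-out; responsiveness odds ratio 4 for the common
class over a 15% base rate. The default bundle is desk-scale — two 2-Mb
chromosomes, 300 genes, 250 + ~350 peaks — so the full pipeline and test
suite run in seconds; proportions, not genome-scale magnitudes, are what
carry over.

Peaks of one factor are placed without mutual overlap (a peak caller
merges overlapping enrichment into a single call), by rejection sampling;
cofactor partners additionally avoid base peaks other than their own, and
independent extras avoid all base peaks. This is what makes the planted
shared fraction identifiable: the sharing measured by `share_peaks`
equals the planted labels exactly, and the recovered fraction is binomial
around the planted value. The geometric expectation of background peaks
landing proximal by chance (gene-free space intersected with TSS windows
extended by the mean peak half-width) is recorded in the truth record.

What the synthetic data does not emulate: read-level noise (FASTQ,
fragment sizes, shifts), mappability and GC biases, realistic genome
composition or repeat structure, correlated peak heights, isoform-level
annotation, or dependence between conservation and responsiveness.
Passing tests therefore demonstrate that the implementation computes the
defined quantities correctly and recovers planted parameters under clean
conditions — not that the defaults are tuned to any particular organism's
noise regime.

## Pipeline and reproducibility

The pipeline is driven by a flat YAML config validated before any stage
runs (every missing file and unknown parameter is listed at once). Stages
execute in dependency order: replicate consensus (when replicate inputs
are given) -> proximal assignment -> peak sharing and gene classes ->
motif scanning and enrichment -> ortholog projection, Venn and
conservation classes -> responsive sets and association tests. Each stage
writes TSV outputs, and the JSON report carries the input manifest with
SHA-256 checksums, the full parameter echo, and every stage summary;
reruns on identical inputs produce identical reports apart from the
timestamp field. All analysis defaults (10 kb window, P thresholds 0.02
and 0.05, relative motif threshold 0.80, pseudocount 0.8, 1 bp overlap)
live in a single `AnalysisConfig` so each appears exactly once.

`scripts/acceptance.py --seed S --out results.json` regenerates a bundle,
runs the pipeline, and recomputes the recovery rates (100 replicates
each for the shared-fraction, odds-ratio and motif-centrality checks),
the closed-form statistics, and a 1,000-replicate chi-square type-I-error
measurement, writing everything as JSON.

## Known limitations

- Genome-scale benchmark counts require the original supplementary peak
  tables, the Ensembl release 64 annotation, and external GEO peak sets;
  those comparisons are out of scope for the bundled tests, and the exact
  integer counts are sensitive to the unstated overlap threshold and
  interval-vs-midpoint window convention (both exposed as parameters
  here).
- Motif hit fractions depend on the relative-score threshold, which the
  original scanning convention does not pin down; comparisons across peak
  sets (orderings, enrichment) are stable across thresholds 0.75-0.90,
  absolute fractions are not.
- The qPCR percent-input formula assumes a single dilution-adjusted input
  and perfect doubling unless an efficiency is supplied.
- `tss_distance_profile` ignores peaks on chromosomes with no annotated
  gene rather than searching other chromosomes.
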