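# Methods

`fusionsig` post-processes gene-level differential-expression (DE) result
tables from a fusion-protein induction experiment: several stably
transfected cell lines, each induced and compared against one
mock-transfected control with a count-based DE tool (three biological
replicates per condition, geometric-mean/median-of-ratios normalization).
The package does not re-derive the DE statistics; it consumes the per-gene
output (mean normalized reads per condition, log2 fold change, p-value) and
performs the downstream signature analyses described below.

## Signature filtering

A gene enters the **up signature** when its induced-condition mean reads
clear the read floor, its p-value is below the ceiling and its log2 fold
change exceeds the positive floor; the **down signature** mirrors this on
the mock condition's reads and the negative fold-change floor. Defaults
(the *strict* preset): read floor 10 (inclusive), p < 0.05 (raw p, not FDR;
an adjusted-p column can be switched in via `use_adjusted_p`), |log2FC| > 2
(strict inequality, i.e. beyond 4-fold). The source conventions for these
cut-offs are ambiguous between "more than 10" and "a minimum of 10", and
between `>` and `>=` on the fold change; both inclusivities are explicit
`Thresholds` fields so either reading is a one-flag change. The *circos*
preset (|log2FC| >= 1, inclusive) is the looser variant used for
per-chromosome track counting and for the chromatin cross-tabulation.
Records with unparseable mandatory numerics, and records with zero reads in
both conditions, never pass any filter.

"Total reads" of a signature sums the direction-relevant condition's mean
reads over members — induced for up, mock for down — mirroring each
filter's read floor; a combined up+down total adds the two. This is a
definitional choice (the source material does not state which condition is
summed) and is isolated in `summarize`/`combined_total_reads`.

Volcano classification labels each record with finite log2FC and p as
up-/down-significant (|log2FC| > 2 and −log10 p > 5) or not significant;
p = 0 is capped at −log10 p = 300.

## Gene-type classification (DAGT)

Seven classes: protein-coding (PCG), pseudogene (PG), non-annotated (NA),
lincRNA (LINC), microRNA (MIR), snoRNA (SNO), mitochondrial (MT). No
published rule table exists for this decomposition, so the package states
one explicitly and makes it overridable (YAML rule table): an annotated
biotype always wins (any `*pseudogene*` biotype → PG, including processed,
unprocessed and unitary); otherwise symbol heuristics apply in order —
`MT-` prefix or chromosome MT → MT, `MIR\d` → MIR, `LINC\d` → LINC,
`SNOR[DA]?\d` → SNO, accession-style symbols (`LOC\d+`, `AC012345.1`-style
clone accessions, `RP11-` clones, bare Ensembl ids) → NA, a trailing
`P<number>` on an otherwise symbol-like string → PG, anything else → PCG.
A record with neither symbol nor biotype is NA ("non-annotated" is
operationalized as exactly this accession-like/missing case, matching its
use as the PG/NA composite alongside pseudogenes). The composite **PG/NA**
class used by the chromatin cross-tab is PG ∪ NA.

## Chromosome-usage fingerprint (GUDC)

For a signature S within an expressed background B (genes with non-zero
reads in at least one condition), the fingerprint is, per canonical
chromosome c (1–22, X, Y, MT):

    delta(c) = 100·|S_c|/|S| − 100·|B_c|/|B|   [percentage points]

The background's own chromosome distribution is the default reference —
"deviation from the mean" is read as deviation from what is expressed at
all, so fingerprints are insensitive to the annotation's chromosome sizes.
A uniform reference (equal share per chromosome) is available via
`reference="uniform"` as the alternative reading. Deltas sum to zero by
construction; an empty signature reports all-zero deltas by convention;
genes on unplaced scaffolds are excluded and counted. Y and MT are reported
but flagged low-count. Because the source analysis provides no uncertainty
scale, `fingerprint_null` adds one: the empirical quantile envelope of
delta under uniform resampling of same-sized signatures from the
background (plus the envelope of max |delta| across chromosomes, the
statistic relevant when scanning all chromosomes for a peak).

## De novo / shut-down transcription (DAGE)

De novo induced: mock mean reads exactly 0 and induced reads > 0;
shut-down: the converse. Genes at 0/0 are unexpressed and belong to
neither set. The zero-read pattern is the authoritative rule; the
`log2var` discriminator — ln(fold change)/ln 2, with exact reciprocal
antisymmetry — is carried as a fast audit flag (a missing/non-finite table
log2FC marks the same candidates). The definition operates on condition
means because the consumed tables are mean-level; with per-replicate
columns, "all replicates zero" would be the stricter variant. Set read
masses follow the expressed condition: induced reads for de novo sets,
mock reads for shut-down sets. `intersect_significant` overlaps a
transition set with the matching-direction signature, optionally
restricted to one gene-type class (default protein-coding), sorted for
stable output.

## Comparative set algebra

Gene identity is always `gene_id` (symbols collide). Venn decomposition
(2–3 sets) returns exclusive regions summing to the union; shared vs
idiosyncratic is the 2-set special case. The heatmap matrix takes the
deduplicated union of the given signatures' members (protein-coding by
default), one column per cell line, values = that line's log2FC, explicit
fill (default 0, flagged) where a line lacks the gene. Clustering itself
is presentation: the plot layer uses Euclidean distance with average
linkage, the analysis layer only builds the matrix.

## Chromatin-accessibility integration

ATAC inputs are gene-indexed DESeq2-style tables (peak-to-gene assignment
is upstream and out of scope). Accessibility signatures keep regions with
induced mean reads > 2 (exclusive), p < 0.05 and |log2| >= 1 (the ±2
variant is a parameter), split by log2 sign into accessible (> 0) and
non-accessible (< 0); log2 = 0 joins neither. The cross-tab assigns every
expression-signature gene exactly one chromatin category (accessible /
non-accessible / no-data when absent from the ATAC signatures) and one
class (PCG vs PG/NA; the minor non-coding classes fold into PG/NA by
default so that the cells partition each signature). The expression side
uses the circos preset by default because the published cross-tab counts
are far larger than the strict signature sizes — an interpretive choice,
configurable. Circos track data counts, per chromosome, deregulated genes
(|log2FC| >= 1, p < 0.05, by sign) and accessibility changes (p < 0.05, by
log2 sign).

## Synthetic data generator

The generator emulates the statistical shape of the experiment so every
stage is testable without sequencing data: per-gene negative-binomial
counts (variance μ + αμ², Gamma–Poisson sampling) for 3 mock vs 3 induced
replicates; per-gene baselines log-normal with mean 200 reads and log-scale
spread 0.6 (a realistic several-decade dynamic range); planted up/down
genes as multiplicative shifts of the induced mean (defaults 8× and 1/8 —
comfortably beyond the 4-fold threshold, as the study's strong responders
are); de novo genes as *structural* zeros in mock (not sampled) with
induced mean 50, shut-down genes the converse, so transition detection has
an exact target; biotypes and chromosomes drawn from census-like
proportions (60% PCG, 16% PG, 10% NA, 9% LINC, …; human per-chromosome
gene shares), with symbols styled per class so the heuristic fallback is
exercisable without the biotype column; and a linked ATAC table in which
each planted up gene becomes clearly accessible with probability π
(`accessibility_link`, default 0.8) while all other genes draw from a null.
One master seed spawns independent child streams for annotation, counts
and accessibility, so each sub-table is reproducible on its own.

`simple_de` closes the loop for end-to-end tests: geometric-mean
(median-of-ratios) size factors, condition-mean log2FC, Welch's t-test on
log2(normalized + 1), BH adjustment. It is deliberately *not* a
shrinkage-based DE tool. With the default pseudocount 0, a gene expressed
in exactly one condition gets a finite fold change from a 0.5 pseudocount
on both means — mirroring how count-based DE tools emit large finite
estimates for structural zeros, which is precisely what the zero-read
discriminator exploits — and a gene with no reads anywhere gets none.

What the generator does **not** model: library-size imbalance between
samples, gene-length or GC effects, correlated genes, dispersion trends,
partial (sub-replicate) dropout, or peak-level ATAC structure. Passing
tests therefore demonstrate the correctness of the filtering, counting and
set logic under the stated statistical assumptions — not robustness to
real-data pathologies such as batch effects or annotation errors.

## Problem sizes and validation strategy

The packaged analyses and acceptance checks run on a six-line synthetic
cohort of 2,000 genes per line whose planted up/down sizes keep the
original study pattern (single construct ≪ co-expression; 9/1, 20/1,
98/48, 61/8, 5/1, 66/7) at one-tenth scale, plus 15 de novo and 8
shut-down genes per line — sizes chosen so the full suite runs in seconds
while every count remains large enough to be meaningful. Published example
counts from the original tables (signature sizes, overlap counts,
cross-tab cells) are not asserted verbatim because those deposited tables
are not redistributable with the package; instead each computation is
verified against planted truth or a brute-force oracle on the synthetic
cohort, and the ingestion layer accepts the deposited tables' shape via
`column_map` so the same pipeline runs on them unchanged.

Numerical/degenerate-input choices worth knowing: p-values outside [0,1]
mark a record incomplete; empty signatures are valid everywhere (all-zero
summaries, zero-delta fingerprints, empty matrices); chromosome
normalization is total and idempotent (`chr1`→`1`, `chrM`→`MT`, scaffolds
→`other`); Venn with more than three sets is a hard error rather than an
approximation; the strong-effect recovery score removes planted structural
transitions from the up/down predictions before computing precision, since
those genes clear the thresholds legitimately and are claimed by the
transition detector instead.

## Known limitations

- The classification rule table is a convention, not ground truth; real
  annotations contain symbols that defeat any heuristic (biotype input is
  strongly preferred).
- `simple_de` p-values are anti-conservative for very low counts; the
  generator's planted effects are large enough that this does not matter
  for recovery tests, but the routine should not be used for real data.
- The chromatin link model is gene-level Bernoulli; it cannot express
  partially accessible loci or distance-weighted peak assignment.
- Fingerprints are chromosome-level only; no arm or cytoband resolution.
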