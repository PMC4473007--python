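# Methods

## Coordinate conventions

All coordinates are 0-based, half-open `[start, end)`. A transcription start
site is stored as the half-open *boundary* coordinate of the 5′ end
(`txStart` for + genes, `txEnd` for − genes). This makes strand-symmetric
arithmetic exact: mirroring the genome (reversing all coordinates and
strands) maps every TSS boundary onto a TSS boundary, and the profile
modules are tested to be invariant under that transformation.

## Read processing

Reads carry `(chrom, start, end, strand, multimap)`. Multi-mapping reads are
discarded; positional duplicates — more than one read at the same
`(chrom, start, strand)` key — are collapsed to one, treating exact 5′-position
copies as PCR amplification artifacts. The surviving record's multimap flag
is the logical AND of the copies' flags, which makes deduplication and
multi-mapper removal commute (a tested invariant). Each read is then
extended in its 3′ direction to the estimated fragment length (default
190 bp) and fragments are assigned to non-overlapping windows (default
200 bp) by **midpoint**. Midpoint assignment keeps window counts integer and
conserved (each fragment counts exactly once), which the island caller's
Poisson model requires; per-bp fractional coverage is available as an
alternative summarization method for browser-style tracks but is not used
for calling. Per-million normalization multiplies every window by
10⁶ / (filtered unique reads in the sample) and is guarded against double
application.

## Island caller

Null model: reads fall uniformly over the mappable genome, so window counts
are Poisson with rate λ = N·W / (f·G), where f is the *effective genome
fraction* (default 0.74, a common mammalian mappability default; set f = 1
for fully mappable synthetic genomes — on such genomes the 0.74 default
overstates λ and makes calling conservative, which is worth knowing when
interpreting synthetic benchmarks run at defaults).

* **Eligibility.** A window with count n is eligible iff n ≥ c, where c is
  the smallest integer with P[Poisson(λ) ≥ c] < p (default p = 0.20).
* **Clustering.** Eligible windows separated by at most `gap_size` (default
  400 bp = 2 windows) of ineligible windows join into one island. The
  reported span is trimmed to the first/last eligible window; `read_count`
  sums every window in the span (sub-threshold gap windows included), while
  the score sums only eligible windows' contributions
  −ln P[Poisson(λ) ≥ nᵢ].
* **Significance.** The E-value E (default 100) is the expected number of
  background islands at or above the score threshold. The null island-score
  distribution is computed exactly for the gapped island definition: with
  per-window eligibility probability q and gap allowance g windows, islands
  start at rate q(1−q)^(g+1) per window, each additional eligible window
  joins with probability r = 1−(1−q)^(g+1), and the island score is the
  geometric mixture of k-fold convolutions of the single-window score
  distribution, evaluated on a grid of 0.1 score units. Grid rounding is
  **upward** (ceil), so discretization can only raise the threshold; the
  realized expected null count at the chosen threshold is therefore
  guaranteed ≤ E. Monte-Carlo checks on 10⁵-window background tracks at
  λ = 0.2 give a mean of ≈ 80 called islands at E = 100. The truncation
  tolerance for count and island-length tails is 10⁻¹²; a continuation
  probability too close to 1 for the grid raises an explicit
  non-convergence error naming the score step.
* **Comparison.** Two-condition shared/unique accounting uses ≥ 1 bp
  overlap. Shared counts may legitimately differ between conditions (one
  broad island overlapping several narrow ones), while
  shared + unique = total holds per condition by construction.

## Annotation

Two sources merge with RefSeq precedence: every RefSeq gene is kept; an
Ensembl gene is kept iff its span overlaps no RefSeq gene on the same
chromosome and strand (the strand requirement is configurable). Enriched
genes are those whose chosen region — TSS ± 2 kb promoter by default, with
TSS ± 1 kb and gene ± 5 kb available — overlaps ≥ 1 bp of an island. The
±2 kb promoter is the default because gene-level calls are what downstream
functional summaries consume; the ±1 kb definition is retained for
distribution tables.

Feature classification uses the island **midpoint** (a span could hit many
features; midpoint classification makes the seven categories a true
partition whose fractions sum to 1). Precedence when the midpoint hits
several features or genes: 5′UTR > 3′UTR > exon > first intron > last
intron > other intron; outside every gene body → intergenic; a single-intron
gene's intron counts as first intron. Distance to TSS is signed (negative =
upstream in the gene's own orientation), measured from the island midpoint
to the nearest TSS, ties broken toward the lexicographically smallest
gene id.

## Expression

Gene value = arithmetic mean of its probes' values on the provided (log)
scale; genes without probes are absent rather than zero. Categories are
rank-based and hence invariant under any strictly monotone transform:
deciles are ten near-equal rank groups (cat1 lowest), and the four-class
scheme marks genes at/below a silent floor as silent (floor defaults to the
25th percentile when not given; synthetic runs pass the generator's floor)
and splits the rest into equal-count tertiles.

## Profiles and clustering

Fragments are binned by midpoint, strand-oriented so column 0 is always the
most 5′ bin. TSS-fine mode: 5 bp bins over TSS ± 2 kb (800 columns).
Metagene mode: five 1 kb bins upstream, twenty 5 %-of-gene-length body bins,
five 1 kb bins downstream (30 columns); bodies shorter than 20 bp are
excluded (any longer body gives every 5 % bin ≥ 1 bp, so midpoint binning
suffices and no fractional per-bp assignment is needed). Category curves
divide the column-wise sum by (genes in category × reads in millions), so
sum(curve) × n_genes × reads/10⁶ recovers the raw read count — a tested
conservation identity.

The clustering matrix covers TSS ± 2 kb at 50 bp bins (80 columns; better
conditioned than 5 bp bins, which remain available), excludes genes shorter
than 2 kb, and is scaled per million but **not** row-standardized — absolute
enrichment magnitude is precisely the signal that separates unmarked silent
promoters from marked ones. k-means uses Euclidean distance, k-means++
initialization, 10 restarts, fixed seed (deterministic); k = 3 is the
headline configuration with k ∈ {2..5} sweepable. Cluster labels are
relabelled 1..k by decreasing centroid mean, so the flat/low-signal cluster
is always the last label.

## Synthetic data: what it emulates, and what it does not

The generator plants: non-overlapping gene models with exon structure and
terminal-10 %-of-terminal-exon UTRs, two annotation sources sharing a
configurable fraction of genes (identical coordinates, different
identifiers), probe-level expression (1–3 probes per gene, Gaussian probe
noise, a silent fraction fixed exactly at a floor value), uniform background
reads, and for each active gene Poisson(μ·w) reads at truncated-normal
offsets (sd = halfwidth/2, hard-truncated at ± halfwidth) around the TSS,
where w = (1−c) + c·2·rank/(n+1) ties intensity to expression rank with
coupling c. Fragment-center geometry is emulated: a planted read's 5′ start
sits half a fragment length upstream (on its strand) of the sampled
position, so 190 bp extension re-centres fragment midpoints on the planted
site, as in real ChIP-seq. Duplicates are exact positional copies of
uniformly chosen primary reads; multimap flags are Bernoulli per primary
read and inherited by copies. Ground truth records active gene sets per
condition, per-gene planted read counts, realized expression values, true
island intervals (each containing exactly one active TSS, enforced by a
minimum inter-gene gap ≥ 2× the enrichment halfwidth), and full read
accounting.

Defaults are sized for the desk-scale demo: five 1 Mb chromosomes, 300
genes, ~200k reads per condition, read length 25 bp, fragment length 190 bp,
70 % annotation-source overlap, 25 % silent genes, 80 % of active genes
shared between conditions. Benchmark scenarios in the test suite use a
background density of λ = 0.2 reads per 200 bp window — the genome-average
density that a few million reads on a mammalian-scale genome produce — with
planted sites at 20× that background.

Not emulated: sequence content (no bases or qualities), alignment and
mismatch errors, mappability structure (the synthetic genome is fully
mappable), chromatin-input bias, probe/dye effects, and inter-replicate
biological variability (each condition is a single pooled sample, as in the
experimental design this mirrors). Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
generative model, not robustness to the artifacts of real libraries.

## Pipeline

Six stages (reads → islands → annotation → expression → profiles →
clustering) run from one YAML config; all inputs are checked before any
stage runs. Each stage is cached on its output files; recomputing a stage
forces all downstream stages, so deleting one intermediate recomputes only
from that point. The manifest records per-stage status, parameters, wall
time, and SHA-256 checksums of inputs and outputs; TSV floats are written
with a fixed `%.6g` format so checksums are stable across runs.

## Known limitations

* The E-value null treats windows as independent Poisson; the fixed total
  read count induces a tiny negative correlation between windows that is
  negligible at genomic scales but measurable on toy tracks.
* Ceil rounding of the score grid can overshoot the threshold by up to one
  grid step per eligible window, so the realized E-value is typically below
  the requested E (≈ 80 at E = 100 in the calibration setting) — a
  deliberate one-sided bias.
* Feature classification assigns each island to exactly one category via
  its midpoint; broad domains spanning several features are not
  multi-counted.
* With E = 100, up to ~100 background islands genome-wide are expected by
  design; benchmarks with few planted sites should interpret precision-like
  metrics with that in mind.
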