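# Methods

This note documents the models and procedures implemented in `epimark`, the
choices made where the design was genuinely open, and what the synthetic
study does and does not establish.

## Replicate consolidation

### Copula-mixture IDR (narrow and mixed peak types)

Replicate peak calls are first matched one-to-one: all overlapping pairs are
ranked by descending overlap length (ties broken by the replicate-1 peak's
(chromosome, start), then the replicate-2 start) and taken greedily, each
peak used at most once. Unmatched singletons are discarded before model
fitting — a peak with no counterpart in the other replicate cannot be
scored for reproducibility and is treated as irreproducible by construction.

The matched score pairs (−log10 p by default, falling back to the
enrichment score when p-values are absent) are modelled with the
two-component Gaussian copula mixture: ranks → uniform pseudo-values
`u = (rank − 0.5)/n` (average ranks for ties; no random jitter, so the fit
is deterministic) → pseudo-data `z = G⁻¹(u)` under the current mixture
marginal `G(z) = π₁ Φ((z−μ)/σ) + (1−π₁) Φ(z)`. Each outer iteration
recomputes the pseudo-data, takes one E-step (posterior membership of the
reproducible component, a bivariate normal with mean (μ, μ), s.d. σ and
correlation ρ, against independent standard normal noise) and one CM-step
(posterior-weighted moments), and stops when the largest absolute parameter
change is below `tol`.

Numerical choices:

* `G⁻¹` is inverted on a 4,096-point grid spanning the support implied by
  both components, refined by two Newton steps; accuracy is far below the
  statistical noise of the ranks.
* Initialization (π₁ = 0.7, μ = 2.6, σ = 1.3, ρ = 0.8) and `tol = 1e−4`,
  `max_iter = 200`. The outer loop's parameter changes decay slowly
  (geometric, roughly 1e−4 per step near the end); runs that reach the cap
  return `converged=False` with a warning but carry essentially converged
  estimates — on 5,000 simulated pairs the recovered parameters sit within
  ±0.02 (π₁, ρ) and ±0.1 (μ, σ) of truth.
* Parameters are clamped 1e−4 inside their domains (π₁, ρ ∈ (0,1); μ, σ > 0).
* **Degeneracy guard.** On independent replicates the likelihood is
  maximized equally by π₁ → 0 and π₁ → 1 (both remove the dependence), and
  the EM can drift to π₁ → 1 with ρ at its floor — a fit that would declare
  everything reproducible. When the fitted ρ ≤ 0.05 the "reproducible"
  component carries no dependence and cannot certify any pair; the model
  then reports local and global IDR = 1 for all pairs. On genuinely
  reproducible data (ρ fitted ≳ 0.3) the guard is never active.
* Local IDR is the posterior irreproducibility; global IDR is the
  cumulative mean of the sorted local IDRs, held constant across tie blocks
  so that it is a monotone function of local IDR.

Consolidated narrow peaks are the union span of the matched pair with the
mean replicate score; the global IDR is carried in the q-value column as
−log10(IDR). Thresholds: 0.05 for true narrow peaks (H3K4me3), 0.10 for the
mixed peak type (H3K56ac), reflecting the broader-domain noise of the
latter.

### Broad domains

H3K27me3 and H2A.Z domains are consolidated by reciprocal overlap: a
replicate-1 domain is kept when some replicate-2 domain overlaps it by at
least 30% of *both* domain lengths (`-f 0.3 -r` semantics). The whole
replicate-1 domain is reported (`-wa`-like); the fragment-vs-whole choice is
a documented convention, and the selected pair set is symmetric in the
replicate order.

## Interval algebra

All coordinates are 0-based half-open; GFF3/GTF converted at the boundary;
chromosome names taken verbatim (mismatched chromosome sets across inputs
produce a warning listing the disjoint names). Merging unions overlapping
*and* book-ended intervals. Intersection supports overlap fractions of
either side and reciprocal application; `whole_a` mode reports each
qualifying A interval once, `fragment` mode reports overlap segments.
Exclusive subtraction removes an interval on any overlap.

Nearest-TSS distance anchors the peak at its **midpoint** (the convention of
distal-peak tooling); ties break to the lexicographically smallest gene id.
The distal filter keeps peaks with midpoint-to-nearest-TSS distance strictly
greater than the threshold (default 1,500 bp); peaks on gene-free
chromosomes are retained but flagged. Feature classification assigns each
peak by midpoint with fixed priority promoter > TTS flank > gene body >
intergenic, with strand-aware windows promoter = TSS −1,000..+100 and TTS
flank = TES..+100 — the windows are a declared convention, not an inferred
one.

Co-localization uses Fisher's exact test on merged peak sets: cells are
merged-A-with-B-overlap, A-only, B-only, and a "neither" cell estimated as
genome length over mean interval length minus the other cells (the
bedtools-fisher construction). The background cell is approximate by
nature; the test is validated by monotonicity of p in the planted overlap
fraction, not by any printed value.

## Expression statistics

Genes are transcribed in a tissue when their mean TPM across that tissue's
replicates is ≥ 1. Differential expression is a deliberately simple,
fully-documented stand-in for a count-based model: Welch's t on
log2(TPM+1) with log2FC the mean difference, BH adjustment across genes.
Genes with zero variance in both groups get p = 1. The stand-in's type-I
error sits at the nominal 5% on null data and its power at the planted
effect sizes (log2FC ≥ 2.5 at 10% replicate CV, 3 vs 3) exceeds 95%. The
tissue-specific gene set requires log2FC > 2 *and* BH p.adj < 0.05 in both
contrasts (strict inequalities).

Over-representation uses the upper hypergeometric tail P(X ≥ k) with BH
across terms. Preranked GSEA uses the weighted Kolmogorov–Smirnov running
sum (hits add |score|^w normalized by the hit total, misses subtract
1/(N−N_hits); ES is the maximum deviation), a gene-label permutation null,
NES = ES over the mean same-sign |null ES|, and a +1-smoothed same-sign
tail p. Gene labels (not phenotypes) are permuted because only ranked lists
are available. BH-adjusted p-values are monotone in the order statistics
and never below the raw p, but re-adjusting adjusted values inflates them
further — adjusted p-values are not a fixed point of the procedure, so no
idempotence is claimed or relied on.

## Enhancer → target pairing

The pipeline is strictly ordered: (1) distal filter against *all* TSSs;
(2) nearest gene over *all* genes; (3) membership test of that gene in the
two-contrast DE set; (4) attach per-contrast statistics and an intragenic
flag (locus overlaps a gene body; such loci are retained and flagged, not
excluded). The ordering matters — searching for the nearest gene only among
DE genes would pair loci with farther genes and produce different pairs —
and step (2)-then-(3) is the reading consistent with a two-step
distal-peaks-then-match workflow. Loci whose nearest gene fails the filter
are reported in a rejects table with the reason.

## Motif enrichment

PFMs become log2-odds PWMs with background-proportional pseudocounts
(default 0.25 over a uniform background). Scanning covers both strands;
ambiguous bases contribute the background-weighted mean cell of their
column. A window is a hit at ≥ 80% of the motif's maximum score — a fixed
fraction rather than an optimized threshold search: simpler, deterministic,
and a stated departure from multi-threshold enrichment tools. The
enrichment table counts sequences (zero-or-one per motif), tested one-sided
(enrichment in the primary set) with BH q-values across motifs; q < 0.05 is
reported as significant. Family summaries report −log10 q with q floored at
1e−300.

## Signal profiles

Track correlation is Spearman on identical bin grids (average-rank ties).
Metagene profiles sample strand-aware upstream flank (2 kb, 40 bins),
length-normalized gene body (60 bins) and downstream flank, averaging over
genes; genes shorter than the body bin count are skipped and counted. The
binning is a declared layout. Fingerprints sort bins ascending and plot
cumulative signal fraction against bin fraction; the curve is convex with
area ≤ 0.5, the diagonal for uniform coverage.

## The synthetic study

The generator emits the *downstream products* of a three-tissue,
four-mark, two-replicate ChIP-seq + three-replicate RNA-seq design — peak
calls, binned coverage, TPM tables, annotation, genome sequence, motifs and
a term map — not reads: read-level processing is upstream of this
pipeline's scope, so the synthetic boundary sits at the first consumed
input. One RNG stream per output kind, all derived from the master seed;
identical seeds give byte-identical bundles.

Default conditions: 3 × 1 Mb chromosomes at GC 0.42; 300 genes (log-normal
lengths, median 3 kb, minimum 500 bp, intergenic gaps ≥ 1 kb — every gap
additionally carries a 1.2 kb guard so neighbouring promoter windows and
TSS peaks cannot collide); 20% of genes untranscribed (< 1 TPM) in all
tissues; TPM baselines log-normal (median 8) with 10% replicate CV; 40
trichome-upregulated genes with planted log2FC ~ U(2.5, 8) against both
other tissues, their baselines floored at 4 TPM so the planted effect
survives the log2(TPM+1) compression of the stand-in DE test (the generator
models focal-tissue *upregulation* over a detectable baseline, not on/off
expression); transcribed genes carry H3K4me3/H3K56ac peaks (width
U(400, 1500)) centred on the TSS in every tissue; untranscribed genes carry
H3K27me3/H2A.Z domains over the body ±1 kb; 15 bivalent genes add a
trichome-only H3K27me3 domain; 25 enhancer loci are trichome-only H3K56ac
peaks placed 2–50 kb from a planted DE gene's TSS with that gene verified
nearest (≥ 500 bp margin over the runner-up, re-drawn on violation, error
after bounded retries); 15 dedicated intergenic tissue-specific peaks per
mark × tissue, kept clear of gene bodies and promoter windows, and for
trichome H3K56ac placed so their nearest gene is *not* a DE gene (they are
genuine tissue-specific chromatin, not unplanted enhancer pairs). Replicate
noise: boundary jitter sd 50 bp, spurious peaks at 20% of the true count
per replicate with lower scores, true-peak score pairs bivariate log-normal
with correlation 0.8. A 10-bp consensus motif is planted in 60% of enhancer
loci; a decoy motif is written but never planted. Coverage tracks (100-bp
bins) add each peak's score over its span — broad domains at half weight
over their outer 1 kb shoulders, reflecting domain-edge tapering — over a
low exponential noise floor.

What the synthetic data does *not* emulate: read-sampling noise and
mappability structure, peak-width/score dependence on local coverage,
chromatin state autocorrelation along chromosomes, realistic gene-length /
expression correlations, GC-dependent artefacts, and biological replicate
structure beyond log-normal score correlation and boundary jitter. Passing
tests therefore demonstrate correctness of the algebra and calibration of
the statistics under the planted model, not performance on real libraries.

## Evaluation conventions

Predictions are matched to the manifest by: reciprocal overlap ≥ 0.5 for
peaks and motif loci; id equality for gene sets; same gene *and* locus
overlap for enhancer pairs. Empty predictions report precision 0 with a
degenerate flag. With noise off (jitter 0, spurious rate 0) the pipeline
inverts the generator exactly for every planted entity kind.

## Problem sizes

The shipped study (3 Mb genome, 300 genes, ~2,000 true peak loci, 24
coverage tracks of 30k bins) runs the full stage chain in a few seconds;
the IDR simulation study uses 5,000 pairs per fit and 20 seeds for the
FDR measurement. These sizes give stable statistics for every planted
contrast while keeping the whole suite interactive.

## Known limitations

* The IDR EM uses one E/CM step per pseudo-data update (as specified by its
  contract) rather than inner-EM-to-convergence; it can reach `max_iter`
  with a `converged=False` flag while being numerically converged for all
  practical purposes.
* The co-localization "neither" cell is a coarse genome-background estimate;
  its p-values are comparable across analyses but not interpretable as
  exact genome-wide tests.
* The DE stand-in ignores count overdispersion structure; it is calibrated
  for TPM-scale log-normal noise only.
* Motif scanning uses an order-0 background and a fixed score threshold; no
  de-novo discovery.
* Single-gene nearest-TSS enhancer assignment; no chromatin-contact
  validation and no multi-gene assignment.
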