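# Methods

## The problem

In pooled CRISPR-Cas9 knockout screens, each gene's fitness effect is read
out from the change in abundance of the sgRNAs targeting it between a
plasmid (pre-selection) library and post-selection treatment replicates.
Cas9 cutting itself is toxic in proportion to the number of target loci: in
copy-number-amplified regions every guide is depleted regardless of the
target gene's function. Left uncorrected, this gene-independent signal
produces false-positive essential-gene calls concentrated in amplified —
and often entirely non-expressed — chromosomal segments.

screenclean detects and removes this bias *unsupervised*: no copy-number
profile, expression data or list of known essentials is required. The key
observation is that gene-independent depletion is regional — many
consecutive guides along the genome share it — whereas genuine fitness
effects are confined to the handful of guides of one gene.

## Pipeline

1. **Filter.** Guides with fewer than `min_reads = 30` raw plasmid reads are
   removed (strictly below threshold): their fold-changes are dominated by
   sampling noise.
2. **Normalise.** Median-of-ratios: each sample's size factor is the median,
   over guides with all-positive counts, of the count divided by the guide's
   geometric mean across all columns of the batch (plasmid plus every
   replicate); counts are divided by the factor. Scaling any column is
   absorbed by the factors up to a single global constant (the rescaled
   geometric-mean reference), so every log fold-change is exactly invariant;
   per-column normalised values are invariant only up to that constant.
3. **Log fold-changes.** Per replicate, `log2((t + eps)/(c + eps))` with a
   pseudocount `eps = 0.5` guarding treatment zeros (guides surviving the
   plasmid filter have `c >= 30`); replicates are then averaged to one logFC
   per guide.
4. **Order.** Guides are sorted by chromosome (natural order 1..22, X, Y;
   configurable; unknown names last, alphabetically) and start coordinate,
   ties broken by guide id. Coordinates are 1-based inclusive; ordering uses
   the guide start — only relative order matters. Guides missing from the
   library annotation are dropped and reported.
5. **Segment.** Circular binary segmentation per chromosome (below).
6. **Correct.** Every segment whose guides collectively target at least
   `min_genes = 3` distinct genes has its member logFCs centered by the
   segment mean (or median with `center=median`, the robust option for noisy
   screens). Segments targeting fewer genes are left untouched — a run of
   depleted guides from one or two genes is more plausibly a real fitness
   effect. No genes are pre-filtered by default; an `exclude_genes` option
   removes a set before segmentation (excluded guides are returned
   uncorrected) for sensitivity analyses, and `choose_min_genes` reruns the
   trial grid (gates 2/3/5/10, with and without exclusion) scoring each
   trial by AURC recall reductions of amplified vs essential control sets.
7. **Back-transform.** Corrected logFCs `N` become corrected treatment
   counts via `t_i = n * c * 2^N * t_i*/T*`: the corrected mean count is
   `c * 2^N` and the uncorrected replicate proportions are preserved
   (`T* = 0` splits the mean equally). The derivation of the mean treats the
   average of log-ratios as the log of the average ratio — exact only when
   replicates agree; `roundtrip_check` reports the resulting Jensen gap
   instead of hiding it. Outputs are real-valued; `--round` produces
   half-even-rounded integers for callers that require them. Corrected
   counts feed mean-variance downstream callers directly, with their own
   normalisation disabled (the counts are already normalised).

## Segmentation details

The ordered logFC vector of one chromosome is split recursively. For every
circular arc `(i, j]` the pooled-variance two-sample t-statistic compares
the arc mean against its complement. The maximising arc is found
exhaustively in O(m^2); because the statistic is a monotone function of the
between-group sum of squares `SSB = A^2/k + R^2/(m-k) - T^2/m` (with `A` the
arc sum, `R` the complement sum, `T`, `SST` fixed by the data), the
permutation loop ranks arrangements by max SSB at a few flops per arc
(numba-compiled). Complementary arcs describe the same split, so linear
arcs suffice; wrap-around arcs map to the two change-points of their
complement. Arc widths are constrained to `min_width = 2` markers per
changed region.

A split is accepted when the permutation p-value of the maximal statistic is
below `alpha = 0.01`, with at most `nperm = 10000` permutations (add-one
estimator `(b + 1)/(n + 1)`). The permutation loop stops early in either
direction once the decision is settled: it rejects a split as soon as the
exceedance count can no longer yield an estimate below `alpha`, and accepts
one when the 99.9% Clopper–Pearson upper bound on the exceedance probability
is below `alpha` — the decision equals the full-`nperm` decision except on
estimates within Monte-Carlo error of `alpha`. Ties at the maximum count as
exceedances (the comparison threshold sits one part in 10^9 below the
observed value, absorbing summation-order noise), making p-values
conservative on discrete-valued data. Accepted splits cut at the arc's
interior boundaries and recursion continues on the pieces; there is no
undo/pruning step, and no outlier-smoothing pre-pass is applied. Zero
within-group variance with unequal means (perfect separation) maps to a
large finite sentinel statistic. Each chromosome consumes an independent
permutation stream derived from the seed, so results are reproducible and
independent of which other chromosomes are present.

## Depletion calling and evaluation

Items (guides, or genes after averaging their guides' logFCs) are ranked
ascending. Walking down the ranked members of the positive (essential `E`)
and negative (non-essential) control sets only, precision is
`PPV(k) = |P(k) ∩ E| / |P(k)|`; the largest `k*` with `1 - PPV(k*) <= FDR`
fixes the threshold `F*` = logFC of the rank-`k*` control, and every scored
item strictly below `F*` is called depleted. The strict inequality means the
rank-`k*` control itself is never called; in a perfectly separable screen
recall of `E` is `(|E|-1)/|E|`, not 1. An empty call (`k* = 0`,
`F* = -inf`) results when no rank satisfies the bound.

Recall curves report recall of a positive set as a function of rank depth;
their area (AURC, trapezoid over the [0,1] rank fraction) is ~0.5 for a
random ranking. Correction quality is summarised as the percent AURC
reduction. Profile preservation treats the top-k most depleted uncorrected
guides as positives and the corrected logFCs as scores, reporting average
precision (AUPRC).

Copy-number bias diagnostics summarise segment mean logFC by DNA copy
number: the *starting point* is the smallest CN > 2 whose segments differ
from the CN = 2 segments by Welch's t-test at `alpha = 0.05` (groups with
fewer than 2 segments are skipped; `alpha` is a parameter); the *critical
point* maximises, over candidate knees `n` in `3..m-1`, the absolute slope
difference of least-squares lines fitted to the per-CN average segment means
on `2..n` and `n+1..m`. Candidates with fewer than two distinct CN levels on
a side are skipped; if that leaves no candidate (maximal CN of 4), the scan
falls back to degenerate minimum-norm fits (slope 0) for single-level
sides so a result is still defined. Globally linear data is flagged `weak`
(maximal slope difference below tolerance). Fitness-impact accounting
classifies genes losing significance after correction (attenuated) or
flipping direction (distorted), and partitions attenuated loss-of-fitness
genes sequentially into non-expressed (FPKM < 0.05), CN-amplified,
prior-known non-essential, and mild-phenotype (pre-correction logFC in the
4th quartile of loss-of-fitness genes) classes; classes lacking annotations
are reported as not computable.

## Synthetic screens

The generator emulates the structure the corrector exploits, with defaults
chosen as plausible study conditions: 2000 genes laid out contiguously
across 20 chromosomes (100 genes each), 5 guides per gene, 3 treatment
replicates; plasmid abundances log-normal (median 500, sigma 0.5); 10% of
genes essential with per-gene effects drawn N(-3, 1) logFC — real
essentials span a wide range of depletion strengths, and that spread is what
makes the control-based FDR threshold non-degenerate; three planted
30-gene bias regions (shifts -2.0, -1.5, -2.5) labelled CN = 8 and
non-expressed; per-guide noise sd 0.3; treatment counts negative-binomial
(dispersion 0.05) around `plasmid * 2^logFC`. All draws flow from a single
seed.

What it does *not* emulate — and hence what passing tests cannot show —
includes guide-efficiency heterogeneity, off-target cutting, partial or
sub-clonal amplifications, bias that correlates with expression, and
chromosome-scale trends; the generative model is a test harness, not a
claim about real screens. Benchmarks on it measure: planted-boundary
recovery (mean error in guides), recall at 5% FDR of planted bias-region
non-essential genes before/after correction (the correction should remove
most of it), recall of planted essentials (which it should preserve), and
top-50 profile-preservation AUPRC. The miniature `worked_fixture` (20 genes
x 3 guides, noise-free, plasmid 160 everywhere so shifted counts are exact
integers) makes every stage hand-checkable.

## Numerical and design choices

- Segment reports keep the arithmetic mean as `seg_mean` even under median
  centering (the offset uses the median); diagnostics stay comparable.
- Centering is idempotent: re-applying correction with the same segments
  changes nothing.
- Guide-count problem sizes in tests and the reproduction script (50
  three-block replicates, 200 null vectors, 20 screens of 10,000 guides)
  were chosen to estimate each rate to well under its decision margin.
- The `evaluate`/`segment`/`correct` CLI subcommands emit plain TSVs so
  external callers can be slotted between any two stages; `run` records a
  manifest (version, parameters, input digests) sufficient to reproduce a
  run bit-for-bit.

## Known limitations

- O(m^2) arc search per permutation: chromosomes beyond ~10^4 ordered
  guides become slow; real libraries (~2-3k guides per chromosome) are
  comfortable.
- The pure permutation p-value differs from the hybrid tail approximations
  some CBS implementations use, in borderline splits; the min-genes
  correction gate absorbs most such differences, but segment boundaries are
  not guaranteed to match other implementations marker-for-marker.
- Back-transformed counts inherit the mean-of-logs vs log-of-mean gap for
  unequal replicates (reported by `roundtrip_check`, typically < 0.5 logFC
  units at 3 replicates with moderate dispersion).
- Amplifications that span a whole chromosome are indistinguishable from a
  per-chromosome offset and are fully centered away, including any true
  fitness signal shared by the whole chromosome.
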