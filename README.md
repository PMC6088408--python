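# screenclean

Unsupervised correction of copy-number-driven, gene-independent sgRNA
depletion in pooled CRISPR-Cas9 knockout screens.

Cas9 cutting is toxic in proportion to the number of cut sites, so every
guide targeting a copy-number-amplified region is depleted whether or not
its gene matters for fitness. This inflates false-positive essential-gene
calls precisely where tumour genomes are amplified. screenclean removes the
bias using only the screen itself — no copy-number data, expression
profiles or essential-gene lists:

1. median-of-ratios normalisation of raw counts (after dropping guides with
   < 30 plasmid reads) and replicate-averaged log2 fold-changes
   `logFC = log2(t/c)`;
2. **circular binary segmentation** of the genome-ordered logFC profile,
   chromosome by chromosome: the arc `(i, j]` maximising the
   pooled-variance two-sample t-statistic against its complement is a
   candidate change-point pair, accepted when its permutation p-value
   (10,000 permutations) falls below α = 0.01, recursively;
3. **centering**: each segment whose guides collectively target ≥ 3
   distinct genes has its mean (or median) logFC subtracted from every
   member guide — regional bias is flattened, within-segment relative
   effects survive;
4. **count back-transformation**: corrected logFCs `N` become corrected
   replicate counts `t_i = n·c·2^N·t_i*/T*`, preserving the uncorrected
   replicate proportions, so mean-variance downstream callers can consume
   corrected data.

It also ships the calling and diagnostic machinery around the corrector:
rank-based depletion calls at fixed FDR from essential/non-essential
control precision (`PPV(k)`, `k*`, `F*`), recall/AURC and
profile-preservation AUPRC comparisons, copy-number bias starting/critical
points, fitness-call impact accounting, and a synthetic screen generator
with planted ground truth.

## Worked example

A synthetic screen of 300 genes on 3 chromosomes (5 guides/gene), with a
30-gene bias region (logFC shift −2) planted on chromosome 2 among
scattered essential genes:

```python
import numpy as np
import screenclean as sc

cfg = sc.SimulationConfig(
    n_genes=300, n_chromosomes=3,
    bias_regions=(sc.BiasRegion(chrom_index=1, start_gene=30, n_genes=30, shift=-2.0),),
    noise_sd=0.2, seed=5,
)
library, counts, truth = sc.simulate_screen(cfg)
result = sc.correct_screen(library, counts, cbs_params=sc.CbsParams(seed=5))

for s in result.correction.segments:
    if s.chrom == "2":
        print(f"  guides {s.start_index:4d}-{s.end_index:4d}  mean {s.seg_mean:+.3f}  "
              f"genes {s.n_genes:3d}  corrected={s.corrected}")
```

```
  guides  500- 539  mean +0.091  genes   8  corrected=True
  guides  540- 544  mean -2.560  genes   1  corrected=False
  ...
  guides  650- 709  mean -1.829  genes  12  corrected=True
  guides  710- 714  mean -5.092  genes   1  corrected=False
  guides  715- 799  mean -1.861  genes  17  corrected=True
  ...
  guides  955- 999  mean +0.167  genes   9  corrected=True
```

The planted region surfaces as contiguous segments with mean ≈ −1.8 and
many distinct genes (corrected), while five-guide segments of a single
strongly depleted gene — genuine essentials — fail the ≥ 3-gene gate and
are left untouched. Gene-level depletion calls at 5% FDR, thresholded on
the planted essential / clean non-essential control sets:

```python
bias = frozenset(truth.genes.loc[truth.genes["in_bias"] & ~truth.genes["essential"], "gene"])
neg  = sorted(truth.genes.loc[~truth.genes["essential"] & ~truth.genes["in_bias"], "gene"])
neg_ctrl = frozenset(np.random.default_rng(5).choice(neg, 100, replace=False))
for name, scores in [("before", sc.gene_scores(result.profile)),
                     ("after ", sc.gene_scores(result.correction.corrected_profile))]:
    call = sc.fdr_threshold(scores, truth.essential_genes, neg_ctrl, 0.05)
    print(name, "correction:",
          f"F* = {call.f_star:+.3f}",
          f"bias-gene recall = {len(bias & call.called)/len(bias):.2f}",
          f"essential recall = {len(truth.essential_genes & call.called)/len(truth.essential_genes):.2f}")
```

```
before correction: F* = -0.217  bias-gene recall = 1.00  essential recall = 1.00
after  correction: F* = -0.350  bias-gene recall = 0.03  essential recall = 1.00
```

Before correction every biased, non-essential gene is falsely called
depleted; after correction nearly all of those calls vanish while every
planted essential is retained.

The same pipeline is available from the shell — `screenclean simulate`,
`normalize`, `segment`, `correct`, `counts`, `evaluate` per stage, or
`screenclean run --config run.yaml` end to end with a reproducibility
manifest. All stage inputs/outputs are plain TSVs, so external callers can
be slotted in anywhere; corrected counts are emitted in the standard
`sgRNA  gene  <samples...>` layout with downstream normalisation meant to
be disabled (they are already normalised).

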