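"""Ground-truth benchmarks on synthetic screens.

These routines quantify, on screens with planted structure, the properties
the corrector is supposed to have: biased-region boundaries recovered to
guide resolution, recall of planted bias genes collapsing after correction
while planted-essential recall and the overall depletion ranking are
preserved, and a change-point false-positive rate on pure noise compatible
with the permutation test's nominal level.  They are used both by the test
suite and by the reproduction script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .correction import CorrectionParams
from .evaluation import fdr_threshold, gene_scores, profile_preservation
from .pipeline import correct_screen
from .segmentation import CbsParams, segment_chromosome
from .simulate import SimulationConfig, simulate_screen


def three_block_recovery(
    n_seeds: int = 50,
    block: int = 40,
    shift: float = 1.0,
    noise_sd: float = 0.1,
    alpha: float = 0.01,
    base_seed: int = 0,
) -> dict:
    """Exact boundary recovery of a planted three-block signal.

    Each replicate is ``[N(0, sd) x block, N(-shift, sd) x block,
    N(0, sd) x block]`` — a shift 10x the marker noise by default — and
    Reports two rates: ``boundary_recovery_rate`` — both planted change
    points appear exactly among the returned cuts — and the stricter
    ``exact_partition_rate`` — the returned segmentation is exactly the
    planted three blocks (extra nominal-level splits inside a block fail
    this but not the former; their frequency is bounded by the pure-noise
    false-split rate).
    """
    boundary_hits = 0
    exact_hits = 0
    planted = [(0, block), (block, 2 * block), (2 * block, 3 * block)]
    for s in range(n_seeds):
        rng = np.random.default_rng([base_seed, s])
        x = np.concatenate(
            [
                rng.normal(0, noise_sd, block),
                rng.normal(-shift, noise_sd, block),
                rng.normal(0, noise_sd, block),
            ]
        )
        segs = segment_chromosome(x, CbsParams(alpha=alpha, seed=s + base_seed))
        cuts = {e for _, e in segs[:-1]}
        boundary_hits += {block, 2 * block} <= cuts
        exact_hits += segs == planted
    return {
        "boundary_recovery_rate": boundary_hits / n_seeds,
        "exact_partition_rate": exact_hits / n_seeds,
        "n": n_seeds,
    }


def null_false_split_rate(
    n_vectors: int = 200,
    length: int = 100,
    alpha: float = 0.01,
    base_seed: int = 0,
) -> dict:
    """Fraction of i.i.d. Gaussian vectors split into more than one segment."""
    splits = 0
    for s in range(n_vectors):
        rng = np.random.default_rng([base_seed, 7, s])
        x = rng.normal(0, 1, length)
        segs = segment_chromosome(x, CbsParams(alpha=alpha, seed=s))
        splits += len(segs) > 1
    return {"false_split_rate": splits / n_vectors, "n": n_vectors}


@dataclasses.dataclass
class ScreenBenchmark:
    per_seed: pd.DataFrame

    @property
    def bias_recall_reduction_pct(self) -> float:
        pre = self.per_seed["bias_recall_pre"].mean()
        post = self.per_seed["bias_recall_post"].mean()
        return 100.0 * (pre - post) / pre

    @property
    def essential_recall_change_pp(self) -> float:
        return float(
            100.0
            * (
                self.per_seed["essential_recall_post"]
                - self.per_seed["essential_recall_pre"]
            )
            .abs()
            .mean()
        )

    @property
    def auprc_top50(self) -> float:
        return float(self.per_seed["auprc_top50"].mean())

    @property
    def boundary_mean_error_guides(self) -> float:
        return float(self.per_seed["boundary_error"].mean())


def _boundary_error(result, library, truth) -> float:
    """Mean distance (guides) from planted region edges to the nearest cut."""
    pos = pd.Series(
        np.arange(len(result.profile)), index=result.profile["sgRNA"].to_numpy()
    )
    cuts = np.array(
        sorted(
            {s.start_index for s in result.correction.segments}
            | {s.end_index + 1 for s in result.correction.segments}
        )
    )
    errors = []
    for _, region in truth.regions.iterrows():
        lo, hi = int(region["start_guide"]), int(region["end_guide"])
        members = library["sgRNA"].iloc[lo : hi + 1]
        inside = pos.reindex(members).dropna()
        if inside.empty:
            continue
        start, end = int(inside.min()), int(inside.max()) + 1
        errors.append(np.abs(cuts - start).min())
        errors.append(np.abs(cuts - end).min())
    return float(np.mean(errors))


def end_to_end_benchmark(
    n_screens: int = 20,
    base_seed: int = 0,
    config: SimulationConfig | None = None,
    fdr: float = 0.05,
    n_negative_controls: int = 500,
) -> ScreenBenchmark:
    """Full-pipeline correction benchmark over seeded synthetic screens.

    For each screen: recall at the given FDR of planted bias-region
    non-essential genes and of planted essentials, before and after
    correction (gene scores = mean guide logFC, threshold from the planted
    essential / clean non-essential control sets), the top-50
    profile-preservation AUPRC, and the planted-boundary error.
    """
    rows = []
    for s in range(n_screens):
        seed = base_seed + s
        cfg = dataclasses.replace(
            config or SimulationConfig(), seed=seed
        )
        library, counts, truth = simulate_screen(cfg)
        result = correct_screen(
            library,
            counts,
            cbs_params=CbsParams(seed=seed),
            correction_params=CorrectionParams(),
        )
        genes = truth.genes
        essential = truth.essential_genes
        bias_non_essential = frozenset(
            genes.loc[genes["in_bias"] & ~genes["essential"], "gene"]
        )
        clean = sorted(
            genes.loc[~genes["essential"] & ~genes["in_bias"], "gene"]
        )
        rng = np.random.default_rng([seed, 13])
        neg_controls = frozenset(
            rng.choice(clean, size=min(n_negative_controls, len(clean)), replace=False)
        )
        pre = gene_scores(result.profile)
        post = gene_scores(result.correction.corrected_profile)

        def recall(scores, positives):
            call = fdr_threshold(scores, essential, neg_controls, fdr)
            present = set(positives) & set(scores.index)
            return len(present & call.called) / len(present)

        auprc = profile_preservation(
            result.profile.set_index("sgRNA")["logFC"],
            result.correction.corrected_profile.set_index("sgRNA")["logFC"],
            [50],
        )[50]
        rows.append(
            {
                "seed": seed,
                "bias_recall_pre": recall(pre, bias_non_essential),
                "bias_recall_post": recall(post, bias_non_essential),
                "essential_recall_pre": recall(pre, essential),
                "essential_recall_post": recall(post, essential),
                "auprc_top50": auprc,
                "boundary_error": _boundary_error(result, library, truth),
            }
        )
    return ScreenBenchmark(per_seed=pd.DataFrame(rows))
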