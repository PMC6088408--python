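"""Segment-level correction of gene-independent depletion.

Knocking out a copy-number-amplified locus depletes every sgRNA cutting
inside it, regardless of the target gene's function.  The correction assumes
the observed logFC of a guide is the sum of its gene's true fitness effect
and a regional, gene-independent component shared by the whole segment:
centering a biased segment (subtracting its mean, or median, logFC from every
member guide) flattens the regional component while preserving relative
effects within the segment, letting true fitness signal emerge.

A segment is only corrected when its guides collectively target at least
``min_genes`` distinct genes (default 3): a segment dominated by one or two
genes is more plausibly a genuine fitness effect than a regional artefact.
No gene — essential or otherwise — is pre-filtered before segmentation under
the defaults.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Set

import numpy as np
import pandas as pd

from .segmentation import CbsParams, Segment, segment_genome

DEFAULT_MIN_GENES = 3


@dataclasses.dataclass
class CorrectionParams:
    min_genes: int = DEFAULT_MIN_GENES
    center: str = "mean"
    exclude_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if self.center not in ("mean", "median"):
            raise ValueError("center must be 'mean' or 'median'")
        self.exclude_genes = frozenset(self.exclude_genes)


@dataclasses.dataclass
class CorrectionResult:
    """Corrected profile, per-segment flags and per-guide offsets.

    ``offsets`` is what was subtracted from each guide (0 outside corrected
    segments); ``corrected_profile`` shares guide order with the input.
    """

    corrected_profile: pd.DataFrame
    segments: list[Segment]
    offsets: pd.Series


def correct_profile(
    profile: pd.DataFrame,
    segments: Iterable[Segment],
    params: CorrectionParams | None = None,
) -> CorrectionResult:
    """Center every segment that targets at least ``min_genes`` distinct genes.

    The center statistic is the segment's mean logFC, or its median when
    ``params.center == "median"`` (more robust with noisy data or toxic
    outlier guides).  The reported ``seg_mean`` stays the arithmetic mean in
    either case, for diagnostics.  Guides in uncorrected segments are left
    bit-identical.
    """
    params = params or CorrectionParams()
    segments = list(segments)
    n = len(profile)
    covered = sum(s.end_index - s.start_index + 1 for s in segments)
    if covered != n:
        raise ValueError("segments do not partition the profile")
    values = profile["logFC"].to_numpy(dtype=float).copy()
    offsets = np.zeros(n)
    out_segments: list[Segment] = []
    for seg in segments:
        sl = slice(seg.start_index, seg.end_index + 1)
        if seg.n_genes >= params.min_genes:
            if params.center == "median":
                shift = float(np.median(values[sl]))
            else:
                shift = float(np.mean(values[sl]))
            values[sl] -= shift
            offsets[sl] = shift
            out_segments.append(dataclasses.replace(seg, corrected=True))
        else:
            out_segments.append(dataclasses.replace(seg, corrected=False))
    corrected = profile.copy()
    corrected["logFC"] = values
    return CorrectionResult(
        corrected_profile=corrected,
        segments=out_segments,
        offsets=pd.Series(offsets, index=profile["sgRNA"].to_numpy(), name="offset"),
    )


def clean_profile(
    profile: pd.DataFrame,
    cbs_params: CbsParams | None = None,
    correction_params: CorrectionParams | None = None,
) -> CorrectionResult:
    """Segment a genome-ordered profile and correct the biased segments.

    When ``correction_params.exclude_genes`` is non-empty, those genes'
    guides are removed before segmentation and reinstated uncorrected (offset
    0) in the output, preserving the input guide order.
    """
    correction_params = correction_params or CorrectionParams()
    if not correction_params.exclude_genes:
        segments = segment_genome(profile, cbs_params)
        return correct_profile(profile, segments, correction_params)

    mask = ~profile["gene"].isin(correction_params.exclude_genes)
    sub = profile.loc[mask].reset_index(drop=True)
    segments = segment_genome(sub, cbs_params)
    sub_result = correct_profile(sub, segments, correction_params)

    corrected = profile.copy()
    values = corrected["logFC"].to_numpy(dtype=float)
    values[mask.to_numpy()] = sub_result.corrected_profile["logFC"].to_numpy()
    corrected["logFC"] = values
    offsets = np.zeros(len(profile))
    offsets[mask.to_numpy()] = sub_result.offsets.to_numpy()
    return CorrectionResult(
        corrected_profile=corrected,
        segments=sub_result.segments,
        offsets=pd.Series(
            offsets, index=profile["sgRNA"].to_numpy(), name="offset"
        ),
    )


def choose_min_genes(
    profile: pd.DataFrame,
    sets,
    filter_set: Set[str],
    candidate_ns: tuple[int, ...] = (2, 3, 5, 10),
    cbs_params: CbsParams | None = None,
    center: str = "mean",
) -> tuple[int, pd.DataFrame]:
    """Pick the ``min_genes`` gate by trial corrections.

    Runs segmentation + correction for every candidate gate, with and without
    excluding the ``filter_set`` of prior-known essential genes before the
    analysis, and scores each trial by the reduction in the area under the
    gene-level recall curve (AURC) for three positive-control collections:
    amplified genes, amplified non-expressed genes (both should *lose*
    recall) and a test set of essentials not in the filter set (which should
    *keep* recall).  Returns the gate maximising bias-recall reduction minus
    essential-recall reduction among the non-excluding trials, plus the full
    trial table.

    ``sets`` is an :class:`screenclean.evaluation.EvaluationSets`.
    """
    from .evaluation import gene_scores, recall_curve, recall_reduction

    test_set = set(sets.essential) - set(filter_set)
    pre_genes = gene_scores(profile)
    rows = []
    for n in candidate_ns:
        for exclude in (False, True):
            params = CorrectionParams(
                min_genes=n,
                center=center,
                exclude_genes=frozenset(filter_set) if exclude else frozenset(),
            )
            result = clean_profile(profile, cbs_params, params)
            post_genes = gene_scores(result.corrected_profile)
            row = {"min_genes": n, "filter_excluded": exclude}
            for name, positives in (
                ("amplified", sets.amplified),
                ("amplified_non_expressed", sets.amplified_non_expressed),
                ("test_set", test_set),
            ):
                if positives and set(positives) & set(pre_genes.index):
                    pre = recall_curve(pre_genes, positives).aurc
                    post = recall_curve(post_genes, positives).aurc
                    row[f"reduction_{name}"] = recall_reduction(pre, post)
                else:
                    row[f"reduction_{name}"] = np.nan
            rows.append(row)
    trials = pd.DataFrame(rows)
    plain = trials[~trials["filter_excluded"]].set_index("min_genes")
    bias = plain[["reduction_amplified", "reduction_amplified_non_expressed"]].mean(
        axis=1
    )
    score = bias.fillna(0.0) - plain["reduction_test_set"].fillna(0.0)
    chosen = int(score.idxmax())
    return chosen, trials
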