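"""Count normalisation and log fold-change computation.

Counts are normalised with the median-of-ratios method: each sample's size
factor is the median, over guides, of the ratio between the guide's count in
that sample and the guide's geometric mean across *all* sample columns of the
batch (plasmid plus every treatment replicate).  Guides with a zero anywhere
have geometric mean zero and are excluded from the median, but are still
rescaled.  Before normalisation, guides that were poorly represented in the
plasmid (fewer than 30 reads by default) are removed: their fold-changes are
dominated by sampling noise.

Depletion/enrichment of a guide is the log2 ratio of normalised treatment to
plasmid counts, averaged across replicates.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import CountTable, ValidationError

DEFAULT_MIN_PLASMID_READS = 30
DEFAULT_PSEUDOCOUNT = 0.5


class EmptyScreenError(ValidationError):
    """Every guide was removed by the plasmid-representation filter."""


@dataclasses.dataclass
class NormalisationResult:
    """Normalised counts plus the bookkeeping needed to interpret them."""

    table: CountTable
    size_factors: pd.Series
    filtered_guides: tuple[str, ...] = ()
    min_plasmid_reads: int = 0

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValidationError("size factors must be positive")


def filter_low_plasmid(
    counts: CountTable, min_reads: int = DEFAULT_MIN_PLASMID_READS
) -> tuple[CountTable, list[str]]:
    """Drop guides with plasmid count strictly below ``min_reads``."""
    if counts.normalised:
        raise ValidationError("plasmid filter must run on raw (unnormalised) counts")
    keep = counts.plasmid >= min_reads
    removed = counts.data.loc[~keep, "sgRNA"].tolist()
    if not keep.any():
        raise EmptyScreenError(
            f"no guide has >= {min_reads} plasmid reads; empty screen"
        )
    return counts.replace_data(counts.data.loc[keep]), removed


def median_ratio_normalise(counts: CountTable) -> NormalisationResult:
    """Median-of-ratios normalisation across all sample columns of the batch."""
    cols = list(counts.sample_columns)
    mat = counts.data[cols].to_numpy(dtype=float)
    # geometric mean per guide across every column; zero if any count is zero
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    finite = np.isfinite(logs).all(axis=1)
    if not finite.any():
        raise ValidationError(
            "size factors undefined: no guide has positive counts in every sample"
        )
    gmean = np.exp(logs[finite].mean(axis=1))
    factors = np.median(mat[finite] / gmean[:, None], axis=0)
    if (factors <= 0).any():
        raise ValidationError("size factors must be positive")
    data = counts.data.copy()
    data[cols] = mat / factors[None, :]
    return NormalisationResult(
        table=counts.replace_data(data, normalised=True),
        size_factors=pd.Series(factors, index=cols, name="size_factor"),
    )


def normalise_screen(
    counts: CountTable, min_reads: int = DEFAULT_MIN_PLASMID_READS
) -> NormalisationResult:
    """Plasmid filter followed by median-ratio normalisation."""
    filtered, removed = filter_low_plasmid(counts, min_reads)
    result = median_ratio_normalise(filtered)
    return dataclasses.replace(
        result, filtered_guides=tuple(removed), min_plasmid_reads=min_reads
    )


def compute_logfc(
    norm: NormalisationResult,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    keep_replicates: bool = False,
) -> pd.DataFrame:
    """Per-guide log2 fold-changes, averaged across replicates.

    Per replicate ``r``: ``logFC_r = log2((t_r + eps) / (c + eps))`` with the
    pseudocount ``eps`` guarding against zeros that survive the plasmid
    filter.  The profile's ``logFC`` column is the mean over replicates; it is
    *unordered* until passed through :func:`screenclean.io.sort_by_genome`.
    """
    table = norm.table
    c = table.plasmid.to_numpy(dtype=float)
    t = table.treatments.to_numpy(dtype=float)
    lfc = np.log2((t + pseudocount) / (c + pseudocount)[:, None])
    out = table.data[["sgRNA", "gene"]].copy()
    if keep_replicates:
        for j, col in enumerate(table.treatment_columns):
            out[f"logFC_{col}"] = lfc[:, j]
    out["logFC"] = lfc.mean(axis=1)
    return out.reset_index(drop=True)
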