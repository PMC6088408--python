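"""Back-transformation of corrected logFCs into corrected treatment counts.

Downstream callers built on mean-variance models of read counts cannot
consume corrected logFCs directly, so corrected counts are derived from
them.  Writing ``N`` for a guide's corrected (replicate-averaged) logFC and
``c`` for its plasmid count, the corrected mean treatment count is
``E(t) = c * 2**N``; the per-replicate corrected counts then split this mean
preserving the proportions seen in the uncorrected replicates:

    t_i = n * c * 2**N * t_i* / T*

with ``t_i*`` the uncorrected count in replicate ``i``, ``T* = sum_i t_i*``
and ``n`` the number of replicates.  When ``T* = 0`` the mean is split
equally (``t_i = c * 2**N``).

The derivation of ``E(t)`` treats the mean of log-ratios as the log of the
mean ratio, which is exact only when all replicates agree; for unequal
replicates the recomputed mean log-ratio deviates from ``N`` by Jensen's
inequality.  :func:`roundtrip_check` quantifies that discrepancy instead of
hiding it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import CountTable, ValidationError


@dataclasses.dataclass
class CorrectedCounts:
    """Real-valued corrected counts plus provenance references."""

    table: CountTable
    corrected_logfc: pd.Series  # N per guide, aligned with the table


def invert_to_counts(
    corrected_logfc: pd.Series,
    counts: CountTable,
) -> CorrectedCounts:
    """Derive corrected per-replicate treatment counts from corrected logFCs.

    Parameters
    ----------
    corrected_logfc
        Corrected logFC ``N`` per guide, indexed by guide id.
    counts
        The *normalised, uncorrected* count table supplying the plasmid
        column ``c`` and the replicate proportions ``t_i* / T*``.

    The plasmid column is passed through unchanged; outputs are real-valued
    (use :func:`round_counts` for callers requiring integers).
    """
    guides = counts.guides
    missing = set(corrected_logfc.index).symmetric_difference(guides)
    if missing:
        raise ValidationError(
            f"guide sets of logFCs and counts differ ({len(missing)} mismatches)"
        )
    N = corrected_logfc.reindex(guides).to_numpy(dtype=float)
    c = counts.plasmid.to_numpy(dtype=float)
    t_star = counts.treatments.to_numpy(dtype=float)
    n = counts.n_replicates
    T_star = t_star.sum(axis=1)
    mean_t = c * np.exp2(N)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = t_star / T_star[:, None]
    corrected = n * mean_t[:, None] * props
    degenerate = T_star == 0
    corrected[degenerate] = mean_t[degenerate, None]

    data = counts.data.copy()
    data[list(counts.treatment_columns)] = corrected
    return CorrectedCounts(
        table=counts.replace_data(data, normalised=True),
        corrected_logfc=pd.Series(N, index=guides.to_numpy(), name="logFC"),
    )


def round_counts(corrected: CorrectedCounts) -> CountTable:
    """Integer counts by half-even rounding, for callers requiring integers."""
    table = corrected.table
    data = table.data.copy()
    cols = list(table.treatment_columns)
    data[cols] = np.rint(data[cols].to_numpy(dtype=float))
    return table.replace_data(data)


def roundtrip_check(
    corrected: CorrectedCounts,
    pseudocount: float = 0.0,
) -> float:
    """Max |mean-of-log-ratios - N| across guides for corrected counts.

    Equals 0 (to floating tolerance) for a single replicate or when the
    uncorrected replicates were all equal; otherwise reports the Jensen-gap
    of the back-transformation (see module docstring).
    """
    table = corrected.table
    c = table.plasmid.to_numpy(dtype=float) + pseudocount
    t = table.treatments.to_numpy(dtype=float) + pseudocount
    if (t <= 0).any() or (c <= 0).any():
        raise ValidationError("roundtrip_check requires positive counts")
    recomputed = np.log2(t / c[:, None]).mean(axis=1)
    N = corrected.corrected_logfc.to_numpy(dtype=float)
    return float(np.max(np.abs(recomputed - N)))
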