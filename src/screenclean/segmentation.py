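"""Circular binary segmentation of genome-ordered log fold-changes.

The profile of replicate-averaged sgRNA logFCs, ordered by genomic position,
is segmented one chromosome at a time into runs of statistically equal mean.
Change-points are located by maximising a two-sample pooled-variance
t-statistic comparing every circular arc of the ordered signal against its
complement; the maximal statistic is assessed by permuting the values within
the region and the split is accepted when the permutation p-value falls below
``alpha``.  Accepted splits are applied recursively until no region can be
split further.

Defaults: ``alpha = 0.01``, ``nperm = 10000``, at least 2 markers per
changed region.  The permutation loop stops early, in either direction, once
the decision is settled: it rejects a split as soon as the final add-one
p-value estimate can no longer fall below ``alpha``, and accepts one when a
99.9% Clopper-Pearson upper bound on the exceedance probability is already
below ``alpha``.  With a fixed seed the output is deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

log = logging.getLogger(__name__)


@dataclasses.dataclass
class CbsParams:
    """Tuning knobs of the change-point search.

    alpha
        Significance threshold to accept a change-point (default 0.01).
    nperm
        Maximum permutations per p-value (default 10000).
    min_width
        Minimal number of markers in a changed region (default 2).
    seed
        Seed for the permutation stream; recorded in run metadata.
    """

    alpha: float = 0.01
    nperm: int = 10000
    min_width: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.nperm < 1:
            raise ValueError("nperm must be >= 1")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


@dataclasses.dataclass
class Segment:
    """A contiguous run of guides with statistically equal logFC.

    ``start_index``/``end_index`` are inclusive positions in the full
    genome-ordered profile the segmentation ran on (chromosome-local indices
    are ``start_index - offset`` for the chromosome's first profile index).
    """

    chrom: str
    start_index: int
    end_index: int
    seg_mean: float
    n_guides: int
    n_genes: int
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("segment start_index must be <= end_index")
        if self.n_genes > self.n_guides:
            raise ValueError("n_genes cannot exceed n_guides")


# ---------------------------------------------------------------------------
# statistic kernels


# The pooled-variance two-sample t over an arc is a monotone function of the
# between-group sum of squares: with arc sum A over k points, complement sum
# R = T - A over m - k points and total sum of squares SST,
#     t^2 = (m - 2) * SSB / (SST - SSB),   SSB = A^2/k + R^2/(m-k) - T^2/m.
# T and SST are invariant under permutation, so the permutation loop can rank
# arrangements by max SSB (a few flops per arc) instead of max |t|.


@njit(cache=True)
def _max_ssb_raw(x, min_width):
    """Max over arcs of A^2/k + R^2/(m-k) (SSB up to the constant T^2/m)."""
    m = x.shape[0]
    S = np.empty(m + 1)
    S[0] = 0.0
    for i in range(m):
        S[i + 1] = S[i] + x[i]
    T = S[m]
    best = -1.0
    for k in range(min_width, m - min_width + 1):
        invk = 1.0 / k
        invc = 1.0 / (m - k)
        for i in range(m - k + 1):
            A = S[i + k] - S[i]
            R = T - A
            B = A * A * invk + R * R * invc
            if B > best:
                best = B
    return best


@njit(cache=True)
def _best_arc_raw(x, min_width):
    """Argmax arc (i, j] of the statistic; returns (i, j, max raw SSB)."""
    m = x.shape[0]
    S = np.empty(m + 1)
    S[0] = 0.0
    for i in range(m):
        S[i + 1] = S[i] + x[i]
    T = S[m]
    best = -1.0
    bi = -1
    bj = -1
    for k in range(min_width, m - min_width + 1):
        invk = 1.0 / k
        invc = 1.0 / (m - k)
        for i in range(m - k + 1):
            A = S[i + k] - S[i]
            R = T - A
            B = A * A * invk + R * R * invc
            if B > best:
                best = B
                bi = i
                bj = i + k
    return bi, bj, best


@njit(cache=True)
def _count_exceed(perms, threshold, min_width):
    """Number of rows of ``perms`` whose max raw SSB is >= threshold."""
    n = 0
    for r in range(perms.shape[0]):
        if _max_ssb_raw(perms[r], min_width) >= threshold:
            n += 1
    return n


_DEGENERATE_STAT = 1e12


def _raw_to_stat(raw: float, x: np.ndarray) -> float:
    """Convert a raw max SSB into the max |t| it corresponds to."""
    m = x.shape[0]
    T = float(x.sum())
    sst = float(np.dot(x, x)) - T * T / m
    ssb = raw - T * T / m
    if ssb <= 0.0 or m <= 2:
        return 0.0
    denom = sst - ssb
    if denom <= sst * 1e-14:
        return _DEGENERATE_STAT  # perfect separation, zero within-arc variance
    return math.sqrt((m - 2) * ssb / denom)


def _stat_to_raw(stat: float, x: np.ndarray) -> float:
    m = x.shape[0]
    T = float(x.sum())
    sst = float(np.dot(x, x)) - T * T / m
    if stat >= _DEGENERATE_STAT:
        return sst + T * T / m
    z2 = stat * stat
    return sst * z2 / (m - 2 + z2) + T * T / m


def cbs_statistic(values: Sequence[float], i: int, j: int) -> float:
    """The two-sample pooled-variance t for arc ``(i, j]`` vs its complement.

    Indices follow the arc convention: the arc covers positions ``i+1..j``
    (1-based), i.e. ``values[i:j]``; the complement is everything else and
    must be non-empty.
    """
    x = np.asarray(values, dtype=float)
    m = x.shape[0]
    if not (0 <= i < j <= m):
        raise ValueError("require 0 <= i < j <= len(values)")
    k = j - i
    if k >= m:
        raise ValueError("arc complement is empty")
    arc = x[i:j]
    comp = np.concatenate((x[:i], x[j:]))
    d = arc.mean() - comp.mean()
    ssw = ((arc - arc.mean()) ** 2).sum() + ((comp - comp.mean()) ** 2).sum()
    if m > 2 and ssw > 0:
        denom = math.sqrt(ssw / (m - 2) * (1.0 / k + 1.0 / (m - k)))
        return float(d / denom)
    if abs(d) < 1e-12:
        return 0.0
    return math.copysign(_DEGENERATE_STAT, d)


# ---------------------------------------------------------------------------
# permutation p-value


@dataclasses.dataclass
class PermTestResult:
    p_value: float
    n_perm: int
    n_exceed: int


def permutation_pvalue(
    values: np.ndarray,
    params: CbsParams,
    rng: np.random.Generator,
    observed: float | None = None,
    early_stop: bool = True,
    batch: int = 200,
) -> PermTestResult:
    """Permutation p-value of the maximal arc statistic of ``values``.

    The estimate is the add-one rule ``(n_exceed + 1) / (n_perm + 1)``.  With
    ``early_stop`` the loop terminates once the accept/reject decision at
    ``params.alpha`` is settled (see module docstring); without it, exactly
    ``params.nperm`` permutations are scored — useful for calibration against
    exhaustive enumeration.
    """
    x = np.asarray(values, dtype=float)
    if observed is None:
        obs_raw = _max_ssb_raw(x, params.min_width)
    else:
        obs_raw = _stat_to_raw(observed, x)
    # ties at the maximum count as exceedances: exact equality is split by
    # last-ulp summation noise across permuted orderings, so compare against
    # a threshold one part in 1e9 below the observed value (conservative)
    threshold = obs_raw - 1e-9 * max(1.0, abs(obs_raw))
    # final estimate can never drop below alpha once count passes this
    reject_at = math.ceil(params.alpha * (params.nperm + 1)) - 1
    count = 0
    done = 0
    while done < params.nperm:
        b = min(batch, params.nperm - done)
        mat = np.tile(x, (b, 1))
        mat = rng.permuted(mat, axis=1)
        count += int(_count_exceed(mat, threshold, params.min_width))
        done += b
        if early_stop:
            if count > reject_at:
                break
            upper = stats.beta.ppf(0.999, count + 1, max(done - count, 1))
            if upper < params.alpha:
                break
    return PermTestResult(
        p_value=(count + 1) / (done + 1), n_perm=done, n_exceed=count
    )


# ---------------------------------------------------------------------------
# recursive segmentation


def segment_chromosome(
    values: Sequence[float],
    params: CbsParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Segment one chromosome's ordered logFC vector.

    Returns half-open ``(start, end)`` index ranges partitioning the vector.
    """
    params = params or CbsParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    x = np.asarray(values, dtype=float)
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        m = hi - lo
        if m < 2 * params.min_width:
            out.append((lo, hi))
            return
        seg = x[lo:hi]
        i, j, raw = _best_arc_raw(seg, params.min_width)
        stat = _raw_to_stat(raw, seg)
        if stat <= 0.0:
            out.append((lo, hi))
            return
        res = permutation_pvalue(seg, params, rng, observed=stat)
        if res.p_value >= params.alpha:
            out.append((lo, hi))
            return
        cuts = sorted({c for c in (i, j) if 0 < c < m})
        if not cuts:
            out.append((lo, hi))
            return
        edges = [lo] + [lo + c for c in cuts] + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            recurse(a, b)

    recurse(0, len(x))
    out.sort()
    # partition property: contiguous, non-overlapping, full coverage
    assert out[0][0] == 0 and out[-1][1] == len(x)
    assert all(a[1] == b[0] for a, b in zip(out[:-1], out[1:]))
    return out


def segment_genome(
    profile: pd.DataFrame,
    params: CbsParams | None = None,
) -> list[Segment]:
    """Segment a genome-ordered profile chromosome by chromosome.

    ``profile`` must be the output of :func:`screenclean.io.sort_by_genome`
    (columns ``sgRNA, gene, chrom, start, logFC``).  Segments never span
    chromosomes; each is annotated with its mean logFC, guide count and
    distinct-gene count.  Each chromosome draws from an independent
    permutation stream derived from ``params.seed``, so results do not depend
    on which other chromosomes are present.
    """
    params = params or CbsParams()
    segments: list[Segment] = []
    offset = 0
    chroms = profile["chrom"].to_numpy()
    values = profile["logFC"].to_numpy(dtype=float)
    genes = profile["gene"].to_numpy()
    # chromosomes in order of appearance (profile is genome-ordered)
    boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
    starts = [0, *boundaries.tolist(), len(chroms)]
    for ci, (lo, hi) in enumerate(zip(starts[:-1], starts[1:])):
        chrom = str(chroms[lo])
        if hi == lo:  # pragma: no cover - cannot arise from a DataFrame
            log.warning("chromosome %s has no guides; skipped", chrom)
            continue
        rng = np.random.default_rng([params.seed, ci])
        for s, e in segment_chromosome(values[lo:hi], params, rng):
            members = slice(lo + s, lo + e)
            segments.append(
                Segment(
                    chrom=chrom,
                    start_index=lo + s,
                    end_index=lo + e - 1,
                    seg_mean=float(values[members].mean()),
                    n_guides=e - s,
                    n_genes=int(pd.unique(genes[members]).size),
                )
            )
        offset = hi
    assert offset == len(chroms)
    return segments
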