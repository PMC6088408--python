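"""Depletion calling, recall machinery and copy-number bias diagnostics.

Depletion significance is calibrated against two gold-standard control
collections: a positive set ``E`` of known fitness-essential genes and a
negative set of non-essentials.  Ranking all items by logFC (most depleted
first) and walking down the ranked *controls only*, precision at rank ``k``
is ``PPV(k) = |P(k) ∩ E| / |P(k)|``; the largest ``k*`` with
``1 - PPV(k*) <= FDR`` fixes a logFC threshold ``F*`` (the logFC of the
control at rank ``k*``), and every library item scoring strictly below
``F*`` is called depleted at that FDR.

Bias diagnostics summarise how segment-level mean logFC varies with DNA copy
number: the *bias starting point* is the smallest copy number whose segments
differ significantly (Welch's t-test) from the CN = 2 segments, and the
*bias critical point* is the copy number at which a two-piece linear fit of
mean logFC against CN shows the largest slope change.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Mapping, Set

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

log = logging.getLogger(__name__)

DEFAULT_FDR = 0.05


@dataclasses.dataclass
class EvaluationSets:
    """Named control gene collections plus optional per-gene annotations."""

    essential: frozenset[str]
    non_essential: frozenset[str]
    amplified: frozenset[str] = frozenset()
    amplified_non_expressed: frozenset[str] = frozenset()
    custom: dict[str, frozenset[str]] = dataclasses.field(default_factory=dict)
    per_gene_cn: pd.Series | None = None
    per_gene_fpkm: pd.Series | None = None

    def __post_init__(self) -> None:
        self.essential = frozenset(self.essential)
        self.non_essential = frozenset(self.non_essential)
        self.amplified = frozenset(self.amplified)
        self.amplified_non_expressed = frozenset(self.amplified_non_expressed)
        if self.essential & self.non_essential:
            raise ValueError("essential and non-essential control sets overlap")


@dataclasses.dataclass
class DepletionCall:
    """Result of the rank-based FDR procedure."""

    k_star: int
    f_star: float
    called: frozenset[str]
    fdr_level: float


def fdr_threshold(
    scores: pd.Series,
    essential: Set[str],
    non_essential: Set[str],
    fdr: float = DEFAULT_FDR,
) -> DepletionCall:
    """Depletion calls at a fixed FDR from ranked control precision.

    ``scores`` are logFCs indexed by item (guide or gene); lower = more
    depleted.  Only control items enter the precision scan; every scored item
    with logFC strictly below the resulting threshold ``F*`` is called.
    When no rank satisfies the bound the call is empty with ``k_star = 0``
    and ``f_star = -inf``.
    """
    controls = scores[scores.index.isin(essential) | scores.index.isin(non_essential)]
    if controls.index.isin(essential).sum() == 0 or controls.index.isin(
        non_essential
    ).sum() == 0:
        raise ValueError("both control sets must be represented among scored items")
    order = controls.reset_index()
    order.columns = ["item", "score"]
    order = order.sort_values(["score", "item"], kind="mergesort")
    is_e = order["item"].isin(essential).to_numpy()
    k = np.arange(1, len(order) + 1)
    n_neg = np.cumsum(~is_e)
    # 1 - PPV(k) <= fdr  <=>  (#negatives in prefix) <= fdr * k
    ok = n_neg <= fdr * k + 1e-12
    if not ok.any():
        return DepletionCall(0, float("-inf"), frozenset(), fdr)
    k_star = int(k[ok][-1])
    f_star = float(order["score"].to_numpy()[k_star - 1])
    called = frozenset(scores.index[scores.to_numpy() < f_star])
    return DepletionCall(k_star, f_star, called, fdr)


def gene_scores(profile: pd.DataFrame) -> pd.Series:
    """Per-gene score: mean logFC of the gene's guides."""
    return profile.groupby("gene")["logFC"].mean()


def call_genes(
    profile: pd.DataFrame,
    sets: EvaluationSets,
    fdr: float = DEFAULT_FDR,
) -> DepletionCall:
    """Gene-level depletion calls: average guide logFCs, then the FDR scan."""
    return fdr_threshold(gene_scores(profile), sets.essential, sets.non_essential, fdr)


def recall_at_fdr(
    scores: pd.Series,
    sets: EvaluationSets,
    positives: Set[str],
    fdr: float = DEFAULT_FDR,
) -> float:
    """Fraction of ``positives`` called depleted at the given FDR."""
    call = fdr_threshold(scores, sets.essential, sets.non_essential, fdr)
    present = set(positives) & set(scores.index)
    if not present:
        raise ValueError("no positive-set item among scored items")
    return len(present & call.called) / len(present)


# ---------------------------------------------------------------------------
# recall curves


@dataclasses.dataclass
class RecallCurve:
    rank_fraction: np.ndarray
    recall: np.ndarray
    aurc: float


def recall_curve(scores: pd.Series, positives: Set[str]) -> RecallCurve:
    """Recall of ``positives`` as a function of rank depth, plus its area.

    Items are ranked ascending by score (most depleted first); the area under
    the curve (AURC, trapezoid over the [0, 1] rank fraction) is ~0.5 for a
    random ranking and approaches 1 when positives concentrate at the top.
    """
    present = set(positives) & set(scores.index)
    if not present:
        raise ValueError("positive set is empty among scored items")
    order = scores.reset_index()
    order.columns = ["item", "score"]
    order = order.sort_values(["score", "item"], kind="mergesort")
    hits = order["item"].isin(present).to_numpy()
    rec = np.concatenate(([0.0], np.cumsum(hits) / len(present)))
    x = np.linspace(0.0, 1.0, len(rec))
    return RecallCurve(x, rec, float(np.trapezoid(rec, x)))


def recall_reduction(aurc_pre: float, aurc_post: float) -> float:
    """Percent reduction in AURC after correction."""
    if aurc_pre <= 0:
        raise ValueError("pre-correction AURC must be positive")
    return 100.0 * (aurc_pre - aurc_post) / aurc_pre


def profile_preservation(
    pre: pd.Series,
    post: pd.Series,
    top_k: Iterable[int],
) -> dict[int, float]:
    """How well the corrected ranking preserves top pre-correction depletions.

    For each ``k``, the ``k`` most-depleted guides of the uncorrected profile
    become the positive class and the corrected logFCs the ranking scores;
    returns area under the precision/recall curve per ``k``.
    """
    if set(pre.index) != set(post.index):
        raise ValueError("pre and post profiles must share the same guides")
    order = pre.reset_index()
    order.columns = ["item", "score"]
    order = order.sort_values(["score", "item"], kind="mergesort")
    post = post.reindex(pre.index)
    out: dict[int, float] = {}
    for k in top_k:
        if not 0 < k <= len(pre):
            raise ValueError(f"top_k value {k} outside 1..{len(pre)}")
        positives = set(order["item"].iloc[:k])
        y_true = pre.index.isin(positives)
        out[k] = float(average_precision_score(y_true, -post.to_numpy()))
    return out


# ---------------------------------------------------------------------------
# copy-number bias diagnostics


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t-test: (statistic, p-value)."""
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bias_starting_point(
    segment_means_by_cn: Mapping[int, Iterable[float]],
    alpha: float = 0.05,
    min_segments: int = 2,
) -> int | None:
    """Smallest CN > 2 whose segment mean-logFCs differ from the CN = 2 group.

    Groups with fewer than ``min_segments`` segments are skipped with a
    warning and the scan continues.  Returns ``None`` when no copy number
    qualifies.
    """
    groups = {int(cn): np.asarray(list(v), dtype=float) for cn, v in segment_means_by_cn.items()}
    if 2 not in groups or len(groups[2]) < min_segments:
        raise ValueError("the CN = 2 reference group needs >= 2 segments")
    for cn in sorted(c for c in groups if c > 2):
        if len(groups[cn]) < min_segments:
            log.warning("CN %d group has < %d segments; skipped", cn, min_segments)
            continue
        _, p = welch_t(groups[cn], groups[2])
        if p < alpha:
            return cn
    return None


@dataclasses.dataclass
class CriticalPoint:
    cn: int
    slope_difference: float
    weak: bool
    candidates: pd.DataFrame


def bias_critical_point(
    segment_cn: Iterable[int],
    segment_means: Iterable[float],
    weak_tolerance: float = 1e-6,
) -> CriticalPoint:
    """CN at which the logFC-vs-CN trend changes slope the most.

    The response per distinct copy number is the average of its segments'
    mean logFCs.  For each candidate ``n`` in ``3..m-1`` (``m`` = maximal
    CN), two least-squares lines are fitted — ``P(n)`` on copy numbers
    ``2..n`` and ``L(n)`` on ``n+1..m`` — and the candidate maximising the
    absolute slope difference is returned.  Candidates with fewer than two
    distinct copy numbers on either side are skipped; a result whose maximal
    slope difference is below ``weak_tolerance`` is flagged ``weak``
    (globally linear data).
    """
    cn = np.asarray(list(segment_cn), dtype=int)
    means = np.asarray(list(segment_means), dtype=float)
    if cn.shape != means.shape:
        raise ValueError("segment_cn and segment_means must have equal length")
    keep = cn >= 2
    cn, means = cn[keep], means[keep]
    per_cn = pd.Series(means).groupby(cn).mean()
    levels = per_cn.index.to_numpy()
    m = int(levels.max())
    if m < 4:
        raise ValueError("need maximal CN >= 4 for a candidate scan")
    def scan(min_levels: int) -> list[dict]:
        rows = []
        for n in range(3, m):
            left = levels[(levels >= 2) & (levels <= n)]
            right = levels[(levels >= n + 1) & (levels <= m)]
            if len(left) < min_levels or len(right) < min_levels:
                continue
            # a single-level side (fallback only) has no identifiable slope;
            # use the minimum-norm fit, slope 0
            slope_p = (
                np.polyfit(left, per_cn[left].to_numpy(), 1)[0] if len(left) > 1 else 0.0
            )
            slope_l = (
                np.polyfit(right, per_cn[right].to_numpy(), 1)[0]
                if len(right) > 1
                else 0.0
            )
            rows.append(
                {
                    "cn": n,
                    "slope_low": slope_p,
                    "slope_high": slope_l,
                    "slope_difference": abs(slope_p - slope_l),
                }
            )
        return rows

    rows = scan(min_levels=2)
    if not rows:
        rows = scan(min_levels=1)
    if not rows:
        raise ValueError("no candidate CN with a copy number on each side")
    table = pd.DataFrame(rows)
    best = table.loc[table["slope_difference"].idxmax()]
    return CriticalPoint(
        cn=int(best["cn"]),
        slope_difference=float(best["slope_difference"]),
        weak=bool(best["slope_difference"] < weak_tolerance),
        candidates=table,
    )


# ---------------------------------------------------------------------------
# fitness-gene impact accounting


#: sequential, disjoint explanation classes for attenuated loss-of-fitness genes
ATTENUATION_CLASSES = (
    "non_expressed",
    "cn_amplified",
    "known_non_essential",
    "mild_phenotype",
    "unexplained",
)

NON_EXPRESSED_FPKM = 0.05


@dataclasses.dataclass
class FitnessImpactReport:
    n_screened: int
    n_pre_significant: int
    attenuated_pct_of_screened: float
    attenuated_pct_of_significant: float
    distorted_pct_of_screened: float
    distorted_pct_of_significant: float
    attenuated_loss: frozenset[str]
    attenuated_gain: frozenset[str]
    distorted: frozenset[str]
    loss_classes: dict[str, int | None]


def fitness_gene_impact(
    pre_calls: pd.DataFrame,
    post_calls: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
) -> FitnessImpactReport:
    """Account for genes whose fitness call changes after correction.

    ``pre_calls``/``post_calls`` are indexed by gene with boolean column
    ``significant``, integer ``direction`` (-1 loss-of-fitness, +1 gain) and
    real ``logfc`` (pre-correction gene score).  *Attenuated* genes are
    significant before but not after correction; *distorted* genes stay
    significant with the opposite direction.

    Attenuated loss-of-fitness genes are partitioned sequentially into
    disjoint classes: non-expressed (FPKM < 0.05), copy-number amplified,
    prior-known non-essential, mild phenotype (pre-correction logFC in the
    4th quartile of pre-correction loss-of-fitness genes), then unexplained.
    ``annotations`` may carry columns ``fpkm``, ``amplified`` and
    ``non_essential``; a missing column makes its class not-computable
    (``None``), and such genes fall through to later classes.
    """
    genes = pre_calls.index
    if not genes.equals(post_calls.index):
        post_calls = post_calls.reindex(genes)
    pre_sig = pre_calls["significant"].astype(bool)
    post_sig = post_calls["significant"].astype(bool)
    attenuated = pre_sig & ~post_sig
    distorted = (
        pre_sig & post_sig & (pre_calls["direction"] != post_calls["direction"])
    )
    n = len(genes)
    n_sig = int(pre_sig.sum())

    def pct(count: int, denom: int) -> float:
        return 100.0 * count / denom if denom else 0.0

    loss = pre_calls["direction"] == -1
    attenuated_loss = set(genes[attenuated & loss])
    attenuated_gain = set(genes[attenuated & ~loss])

    # sequential partition of the attenuated loss-of-fitness genes
    classes: dict[str, int | None] = {}
    remaining = set(attenuated_loss)
    loss_sig = pre_calls[pre_sig & loss]
    mild_cut = float(loss_sig["logfc"].quantile(0.75)) if len(loss_sig) else np.nan

    def take(name: str, members: set[str] | None) -> None:
        nonlocal remaining
        if members is None:
            classes[name] = None
            return
        hit = remaining & members
        classes[name] = len(hit)
        remaining -= hit

    ann = annotations if annotations is not None else pd.DataFrame(index=genes)
    take(
        "non_expressed",
        set(ann.index[ann["fpkm"] < NON_EXPRESSED_FPKM]) if "fpkm" in ann else None,
    )
    take(
        "cn_amplified",
        set(ann.index[ann["amplified"].astype(bool)]) if "amplified" in ann else None,
    )
    take(
        "known_non_essential",
        set(ann.index[ann["non_essential"].astype(bool)])
        if "non_essential" in ann
        else None,
    )
    take(
        "mild_phenotype",
        set(pre_calls.index[pre_calls["logfc"] > mild_cut])
        if np.isfinite(mild_cut)
        else None,
    )
    classes["unexplained"] = len(remaining)

    return FitnessImpactReport(
        n_screened=n,
        n_pre_significant=n_sig,
        attenuated_pct_of_screened=pct(int(attenuated.sum()), n),
        attenuated_pct_of_significant=pct(int(attenuated.sum()), n_sig),
        distorted_pct_of_screened=pct(int(distorted.sum()), n),
        distorted_pct_of_significant=pct(int(distorted.sum()), n_sig),
        attenuated_loss=frozenset(attenuated_loss),
        attenuated_gain=frozenset(attenuated_gain),
        distorted=frozenset(genes[distorted]),
        loss_classes=classes,
    )
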