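import itertools

import numpy as np
import pandas as pd
import pytest

import screenclean as sc
from screenclean.evaluation import welch_t

from conftest import brute_force_fdr_scan


def scores_from_labels(labels):
    """Controls in a forced rank order: scores ascending, labels E/N."""
    vals = np.linspace(-5, -1, len(labels))
    idx = [f"{'E' if l else 'N'}{i}" for i, l in enumerate(labels)]
    scores = pd.Series(vals, index=idx)
    essential = {i for i, l in zip(idx, labels) if l}
    negatives = {i for i, l in zip(idx, labels) if not l}
    return scores, essential, negatives


class TestFdrThreshold:
    def test_toy_ordering(self):
        labels = [1, 1, 1, 0, 1, 0, 0, 0]
        scores, E, N = scores_from_labels(labels)
        call = sc.fdr_threshold(scores, E, N, fdr=0.05)
        assert call.k_star == 3
        assert call.f_star == scores.iloc[2]

    def test_all_essential_controls(self):
        labels = [1] * 6
        scores, E, _ = scores_from_labels(labels)
        scores["lib1"] = -10.0  # non-control library item, deeply depleted
        scores["lib2"] = 0.0
        call = sc.fdr_threshold(scores, E, {"N_absent"} | {"lib2"}, fdr=0.05)
        assert call.k_star >= 6
        assert "lib1" in call.called

    def test_fdr_zero_stops_at_pure_prefix(self):
        labels = [1, 1, 0, 1]
        scores, E, N = scores_from_labels(labels)
        call = sc.fdr_threshold(scores, E, N, fdr=0.0)
        assert call.k_star == 2

    def test_no_qualifying_rank_gives_empty_call(self):
        labels = [0, 1]
        scores, E, N = scores_from_labels(labels)
        call = sc.fdr_threshold(scores, E, N, fdr=0.05)
        assert call.k_star == 0
        assert call.f_star == float("-inf")
        assert call.called == frozenset()

    def test_threshold_is_strict(self):
        scores = pd.Series(
            {"E0": -3.0, "E1": -2.0, "tie": -2.0, "lib": -2.5, "N0": -1.0}
        )
        call = sc.fdr_threshold(scores, {"E0", "E1"}, {"N0"}, fdr=0.05)
        # F* = -2.0 (rank-2 control); ties at F* are excluded, -2.5 is called
        assert call.f_star == -2.0
        assert call.called == frozenset({"E0", "lib"})

    def test_matches_bruteforce_on_all_orderings_up_to_length_12(self):
        """Exhaustive oracle over every control labelling of length <= 12."""
        for length in range(2, 13):
            for bits in range(1, 2**length - 1):
                labels = [(bits >> i) & 1 for i in range(length)]
                scores, E, N = scores_from_labels(labels)
                call = sc.fdr_threshold(scores, E, N, fdr=0.05)
                k, f = brute_force_fdr_scan(labels, scores.to_numpy(), 0.05)
                assert call.k_star == k
                assert call.f_star == f

    def test_recall_monotone_in_fdr(self):
        rng = np.random.default_rng(11)
        labels = rng.random(60) < 0.5
        scores, E, N = scores_from_labels(labels.tolist())
        sets = sc.EvaluationSets(frozenset(E), frozenset(N))
        recalls = [
            sc.recall_at_fdr(scores, sets, E, fdr) for fdr in (0.01, 0.05, 0.1, 0.2)
        ]
        assert all(b >= a for a, b in zip(recalls, recalls[1:]))


class TestCallGenes:
    def _profile(self, gene_logfc, guides_per_gene=2):
        rows = []
        for g, (gene, vals) in enumerate(gene_logfc.items()):
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "sgRNA": f"{gene}_{i}",
                        "gene": gene,
                        "chrom": "1",
                        "start": 1 + len(rows) * 100,
                        "logFC": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_gene_score_is_mean_of_guides(self):
        prof = self._profile({"A": [-2.0, -4.0]})
        assert sc.gene_scores(prof)["A"] == -3.0

    def test_separable_screen_near_full_recall(self):
        """All essentials below all negatives: every essential except the
        rank-k* boundary control is called (the threshold is strict)."""
        prof = self._profile(
            {
                **{f"E{i}": [-4.0 - i * 0.1] for i in range(5)},
                **{f"N{i}": [0.0 + i * 0.1] for i in range(5)},
            }
        )
        sets = sc.EvaluationSets(
            frozenset(f"E{i}" for i in range(5)), frozenset(f"N{i}" for i in range(5))
        )
        call = sc.call_genes(prof, sets, fdr=0.05)
        assert call.k_star == 5
        assert call.f_star == -4.0
        recall = len(sets.essential & call.called) / 5
        assert recall == 4 / 5

    def test_single_guide_gene_score_equals_guide(self):
        prof = self._profile({"A": [-1.7], "B": [0.3]})
        scores = sc.gene_scores(prof)
        assert scores["A"] == -1.7 and scores["B"] == 0.3


class TestRecallCurves:
    def test_random_ranking_aurc_near_half(self):
        rng = np.random.default_rng(0)
        aurcs = []
        for seed in range(20):
            scores = pd.Series(
                np.random.default_rng(seed).normal(size=400),
                index=[f"g{i}" for i in range(400)],
            )
            pos = {f"g{i}" for i in range(0, 400, 2)}
            aurcs.append(sc.recall_curve(scores, pos).aurc)
        assert abs(np.mean(aurcs) - 0.5) < 0.05

    def test_top_ranked_positives_aurc_near_one(self):
        scores = pd.Series(
            np.arange(500, dtype=float), index=[f"g{i}" for i in range(500)]
        )
        pos = {f"g{i}" for i in range(10)}  # the 10 best scores
        assert sc.recall_curve(scores, pos).aurc > 0.98

    def test_identical_profiles_zero_reduction(self):
        assert sc.recall_reduction(0.7, 0.7) == 0.0


class TestProfilePreservation:
    def _profiles(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        pre = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        return pre

    def test_identity_gives_auprc_one(self):
        pre = self._profiles()
        out = sc.profile_preservation(pre, pre.copy(), [10, 50, 100])
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_reversed_ranking_near_baseline(self):
        pre = self._profiles()
        out = sc.profile_preservation(pre, -pre, [20])
        assert out[20] < 0.3  # near the |P|/total = 0.1 baseline

    def test_noise_grid_monotone(self):
        pre = self._profiles()
        rng = np.random.default_rng(1)
        noise = rng.normal(size=len(pre))
        scores = [
            sc.profile_preservation(pre, pre + sigma * noise, [30])[30]
            for sigma in (2.0, 0.5, 0.1, 0.0)
        ]
        assert all(b >= a for a, b in zip(scores, scores[1:]))
        assert scores[-1] == pytest.approx(1.0)

    def test_oversized_k_rejected(self):
        pre = self._profiles(n=20)
        with pytest.raises(ValueError):
            sc.profile_preservation(pre, pre, [21])


class TestWelch:
    def test_matches_closed_form(self):
        a = np.array([-1.2, -0.8, -1.5, -0.9])
        b = np.array([0.1, -0.2, 0.4, 0.0, 0.3])
        t, p = welch_t(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se = np.sqrt(va / len(a) + vb / len(b))
        t_manual = (a.mean() - b.mean()) / se
        df = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        from scipy import stats as ss

        p_manual = 2 * ss.t.sf(abs(t_manual), df)
        assert t == pytest.approx(t_manual, rel=1e-12)
        assert p == pytest.approx(p_manual, rel=1e-12)


class TestBiasStartingPoint:
    def test_identical_groups_return_none(self):
        rng = np.random.default_rng(21)
        groups = {cn: rng.normal(0, 0.5, 30) for cn in (2, 3, 4, 5)}
        assert sc.bias_starting_point(groups) is None

    def test_planted_shift_from_cn6(self):
        rng = np.random.default_rng(2)
        groups = {cn: rng.normal(0, 0.1, 20) for cn in (2, 3, 4, 5)}
        groups.update({cn: rng.normal(-2, 0.1, 20) for cn in (6, 7, 8)})
        assert sc.bias_starting_point(groups) == 6

    def test_single_segment_group_skipped(self):
        rng = np.random.default_rng(3)
        groups = {
            2: rng.normal(0, 0.1, 20),
            3: np.array([-5.0]),  # too small: skipped
            4: rng.normal(-2, 0.1, 20),
        }
        assert sc.bias_starting_point(groups) == 4

    def test_reference_group_required(self):
        with pytest.raises(ValueError):
            sc.bias_starting_point({3: [0.1, 0.2]})


class TestBiasCriticalPoint:
    def test_piecewise_knee_recovered_exactly(self):
        # flat at CN 2..7, then a steep decline whose fitted line does not
        # pass through the knee value, so the argmax at 7 is unique
        cn = list(range(2, 11))
        means = [0.0] * 6 + [-1.5, -3.5, -5.5]
        res = sc.bias_critical_point(cn, means)
        assert res.cn == 7
        assert not res.weak
        # oracle: exhaustive candidate scan
        best = max(
            res.candidates.itertuples(), key=lambda r: r.slope_difference
        )
        assert best.cn == 7

    def test_globally_linear_flagged_weak(self):
        cn = list(range(2, 10))
        means = [-0.5 * c for c in cn]
        res = sc.bias_critical_point(cn, means)
        assert res.weak

    def test_minimal_cn_range_single_candidate(self):
        res = sc.bias_critical_point([2, 3, 4, 4], [0.0, -0.5, -2.0, -2.2])
        assert res.cn == 3
        assert len(res.candidates) == 1


class TestFitnessGeneImpact:
    def _calls(self, sig, direction, logfc):
        return pd.DataFrame(
            {"significant": sig, "direction": direction, "logfc": logfc},
            index=[f"G{i}" for i in range(len(sig))],
        )

    def test_identical_calls_no_impact(self):
        pre = self._calls([True, True, False], [-1, 1, -1], [-2.0, 1.0, -0.1])
        rep = sc.fitness_gene_impact(pre, pre.copy())
        assert rep.attenuated_pct_of_screened == 0.0
        assert rep.distorted_pct_of_significant == 0.0

    def test_direction_flip_is_distorted_not_attenuated(self):
        pre = self._calls([True], [-1], [-2.0])
        post = self._calls([True], [1], [1.5])
        rep = sc.fitness_gene_impact(pre, post)
        assert rep.distorted == frozenset({"G0"})
        assert rep.attenuated_loss | rep.attenuated_gain == frozenset()

    def test_sequential_partition_of_attenuated_loss(self):
        sig = [True] * 8
        direction = [-1] * 8
        logfc = [-4.0, -3.5, -3.0, -2.5, -2.0, -1.5, -1.0, -0.4]
        pre = self._calls(sig, direction, logfc)
        post = self._calls([True] * 4 + [False] * 4, direction, logfc)
        ann = pd.DataFrame(
            {
                "fpkm": [1.0] * 4 + [0.01, 1.0, 1.0, 1.0],
                "amplified": [False] * 5 + [True, False, False],
                "non_essential": [False] * 6 + [True, False],
            },
            index=pre.index,
        )
        rep = sc.fitness_gene_impact(pre, post, ann)
        # G4 non-expressed, G5 amplified, G6 known non-essential,
        # G7 mild (logfc -0.4 above the Q3 of pre loss genes)
        assert rep.loss_classes["non_expressed"] == 1
        assert rep.loss_classes["cn_amplified"] == 1
        assert rep.loss_classes["known_non_essential"] == 1
        assert rep.loss_classes["mild_phenotype"] == 1
        assert rep.loss_classes["unexplained"] == 0
        assert rep.attenuated_pct_of_significant == pytest.approx(50.0)

    def test_missing_annotations_not_computable(self):
        pre = self._calls([True], [-1], [-2.0])
        post = self._calls([False], [-1], [-2.0])
        rep = sc.fitness_gene_impact(pre, post, annotations=None)
        assert rep.loss_classes["non_expressed"] is None
        assert rep.loss_classes["cn_amplified"] is None
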