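import numpy as np
import pandas as pd
import pytest

import screenclean as sc
from screenclean.segmentation import Segment


def make_profile(logfc, genes, chrom="1"):
    n = len(logfc)
    return pd.DataFrame(
        {
            "sgRNA": [f"g{i:03d}" for i in range(n)],
            "gene": genes,
            "chrom": chrom,
            "start": 1 + np.arange(n) * 100,
            "logFC": np.asarray(logfc, dtype=float),
        }
    )


def seg(start, end, profile, **kw):
    members = profile.iloc[start : end + 1]
    return Segment(
        chrom=str(members["chrom"].iloc[0]),
        start_index=start,
        end_index=end,
        seg_mean=float(members["logFC"].mean()),
        n_guides=end - start + 1,
        n_genes=members["gene"].nunique(),
        **kw,
    )


class TestCorrectProfile:
    def test_mean_centering_zeroes_segment(self):
        prof = make_profile([-2.1] * 10 + [0.0] * 10, ["A", "B", "C", "D"] * 5)
        segments = [seg(0, 9, prof), seg(10, 19, prof)]
        res = sc.correct_profile(prof, segments)
        first = res.corrected_profile["logFC"].iloc[:10]
        assert np.allclose(first, 0.0, atol=1e-12)
        assert np.allclose(res.offsets.iloc[:10], -2.1)

    def test_min_genes_gate_blocks_two_gene_segment(self):
        prof = make_profile([-3.0] * 6 + [0.0] * 6, ["A", "B"] * 3 + ["C", "D", "E"] * 2)
        segments = [seg(0, 5, prof), seg(6, 11, prof)]
        res = sc.correct_profile(prof, segments, sc.CorrectionParams(min_genes=3))
        assert not res.segments[0].corrected
        assert (res.corrected_profile["logFC"].iloc[:6] == -3.0).all()
        assert (res.offsets.iloc[:6] == 0.0).all()

    def test_median_centering(self):
        prof = make_profile([-5.0, 0.0, 0.0, 0.0, 0.0], ["A", "B", "C", "D", "E"])
        segments = [seg(0, 4, prof)]
        res = sc.correct_profile(
            prof, segments, sc.CorrectionParams(center="median")
        )
        # median 0 -> values unchanged, but segment counts as corrected
        assert np.allclose(res.corrected_profile["logFC"], prof["logFC"])
        assert res.segments[0].corrected
        assert np.median(res.corrected_profile["logFC"]) == 0.0
        # reported mean stays the arithmetic mean for diagnostics
        assert res.segments[0].seg_mean == pytest.approx(-1.0)

    def test_uncorrected_guides_bit_identical(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=12)
        prof = make_profile(vals, ["A", "B"] * 3 + ["C", "D", "E", "F"] * 1 + ["G", "H"])
        segments = [seg(0, 5, prof), seg(6, 11, prof)]
        res = sc.correct_profile(prof, segments, sc.CorrectionParams(min_genes=3))
        assert not res.segments[0].corrected and res.segments[1].corrected
        assert (
            res.corrected_profile["logFC"].iloc[:6].to_numpy()
            == prof["logFC"].iloc[:6].to_numpy()
        ).all()

    @pytest.mark.parametrize("center", ["mean", "median"])
    def test_corrected_center_statistic_zero(self, center):
        rng = np.random.default_rng(2)
        prof = make_profile(rng.normal(-1, 2, 20), [f"G{i // 2}" for i in range(20)])
        segments = [seg(0, 9, prof), seg(10, 19, prof)]
        res = sc.correct_profile(prof, segments, sc.CorrectionParams(center=center))
        stat = np.mean if center == "mean" else np.median
        for s in res.segments:
            if s.corrected:
                vals = res.corrected_profile["logFC"].iloc[
                    s.start_index : s.end_index + 1
                ]
                assert abs(stat(vals)) < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        prof = make_profile(rng.normal(size=10), [f"G{i // 2}" for i in range(10)])
        segments = [seg(0, 9, prof)]
        once = sc.correct_profile(prof, segments)
        twice = sc.correct_profile(once.corrected_profile, once.segments)
        pd.testing.assert_frame_equal(once.corrected_profile, twice.corrected_profile)

    def test_segments_must_partition(self):
        prof = make_profile([0.0] * 6, ["A"] * 6)
        with pytest.raises(ValueError, match="partition"):
            sc.correct_profile(prof, [seg(0, 3, prof)])


class TestCleanProfile:
    def test_excluded_genes_reinserted_uncorrected(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(-2, 0.05, 30), rng.normal(0, 0.05, 30)])
        genes = [f"G{i // 3}" for i in range(60)]
        prof = make_profile(vals, genes)
        excl = frozenset(["G3", "G12"])
        res = sc.clean_profile(
            prof,
            sc.CbsParams(seed=1),
            sc.CorrectionParams(exclude_genes=excl),
        )
        mask = prof["gene"].isin(excl).to_numpy()
        assert (res.offsets.to_numpy()[mask] == 0.0).all()
        assert (
            res.corrected_profile["logFC"].to_numpy()[mask]
            == prof["logFC"].to_numpy()[mask]
        ).all()
        assert list(res.corrected_profile["sgRNA"]) == list(prof["sgRNA"])


class TestChooseMinGenes:
    def test_trial_table_shape_and_choice(self, small_screen):
        (library, counts, truth), _ = small_screen
        res = sc.correct_screen(library, counts, cbs_params=sc.CbsParams(seed=5))
        rng = np.random.default_rng(5)
        clean = truth.genes.loc[
            ~truth.genes["essential"] & ~truth.genes["in_bias"], "gene"
        ]
        sets = sc.EvaluationSets(
            essential=truth.essential_genes,
            non_essential=frozenset(rng.choice(clean, 60, replace=False)),
            amplified=truth.bias_genes,
            amplified_non_expressed=frozenset(
                truth.genes.loc[
                    truth.genes["in_bias"] & ~truth.genes["expressed"], "gene"
                ]
            ),
        )
        filter_set = frozenset(list(truth.essential_genes)[:10])
        chosen, trials = sc.choose_min_genes(
            res.profile,
            sets,
            filter_set,
            candidate_ns=(2, 3),
            cbs_params=sc.CbsParams(seed=5),
        )
        assert len(trials) == 2 * 2  # candidates x with/without filter set
        assert chosen in (2, 3)
        assert {"reduction_amplified", "reduction_test_set"} <= set(trials.columns)
        # bias regions span >= 5 genes, so gates 2 and 3 behave identically
        red = trials[~trials["filter_excluded"]].set_index("min_genes")
        assert red.loc[2, "reduction_amplified"] == pytest.approx(
            red.loc[3, "reduction_amplified"], abs=5.0
        )

    def test_degenerate_screen_reports_no_op(self):
        rng = np.random.default_rng(6)
        prof = make_profile(rng.normal(0, 0.3, 40), [f"G{i // 2}" for i in range(40)])
        genes = sorted(set(prof["gene"]))
        sets = sc.EvaluationSets(
            essential=frozenset(genes[:5]),
            non_essential=frozenset(genes[5:15]),
            amplified=frozenset(genes[15:18]),
        )
        chosen, trials = sc.choose_min_genes(
            prof, sets, frozenset(genes[:2]), candidate_ns=(2, 3),
            cbs_params=sc.CbsParams(seed=6),
        )
        # single flat segment: correction centers everything once, and every
        # trial yields the same (near-zero) reductions
        assert np.allclose(trials["reduction_amplified"].to_numpy(), 0.0, atol=1e-6)
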