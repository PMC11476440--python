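import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from triomix import (
    CountMatrix,
    DEG_THRESHOLDS,
    DMR_THRESHOLDS,
    DifferentialRecord,
    MethylRegionTable,
    ThresholdSet,
    ValidationError,
    bh_adjust,
    classify,
    filter_low_coverage_regions,
    normalize_libraries,
    simulate_counts,
)
from triomix.differential import test_counts as run_count_test
from triomix.differential import test_methylation as run_methylation_test


def _counts(arr, groups):
    idx = pd.Index([f"f{i}" for i in range(len(arr))], name="feature_id")
    cols = list(groups)
    return CountMatrix(pd.DataFrame(arr, index=idx, columns=cols), groups)


class TestNormalizeLibraries:
    def test_identical_samples_unit_factors(self):
        m = _counts([[10, 10], [50, 50]], {"a": "control", "b": "treated"})
        assert normalize_libraries(m).to_numpy() == pytest.approx([1.0, 1.0])

    def test_doubled_library_factor_ratio_two(self):
        m = _counts([[10, 20], [50, 100], [7, 14]], {"a": "control", "b": "treated"})
        sf = normalize_libraries(m)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_all_zero_matrix_errors(self):
        m = _counts([[0, 0], [0, 0]], {"a": "control", "b": "treated"})
        with pytest.raises(ValidationError):
            normalize_libraries(m)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value_identity(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3] * 3)

    def test_matches_manual_formula(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        # independent step-up oracle: sort, adjust, enforce monotonicity
        order = np.argsort(p)
        m = len(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1.0)
        assert bh_adjust(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_in_rank_and_bounded(self, ps):
        ps = sorted(ps)
        adj = bh_adjust(ps)
        assert np.all(np.diff(adj) >= -1e-12)
        assert np.all((adj >= 0) & (adj <= 1))


class TestClassify:
    CASES = [
        # worked-example rows at their native thresholds
        (1.224, 0.002, 0.002, DMR_THRESHOLDS, "up"),
        # |lfc| below the 0.5 cutoff stays ns regardless of significance;
        # published integration tables carry such sub-threshold fold changes,
        # which is why integration accepts pre-thresholded records instead of
        # re-classifying them
        (-0.452, 1.69e-8, 1.69e-8, DEG_THRESHOLDS, "ns"),
        (0.49, 0.001, 0.001, DEG_THRESHOLDS, "ns"),
        # inclusive boundary at the cutoff itself
        (0.5, 0.05, 0.05, DEG_THRESHOLDS, "up"),
        (-1.0, 0.05, 0.9, DMR_THRESHOLDS, "down"),  # DMR uses raw p, not fdr
    ]

    @pytest.mark.parametrize("lfc,p,fdr,thr,expected", CASES)
    def test_direction(self, lfc, p, fdr, thr, expected):
        (rec,) = classify([DifferentialRecord("x", "gene", lfc, p, fdr)], thr)
        assert rec.direction == expected

    @given(
        st.floats(-3, 3),
        st.floats(0, 1),
        st.floats(0, 1),
    )
    def test_exhaustive_and_exclusive(self, lfc, p, fdr):
        (rec,) = classify([DifferentialRecord("x", "gene", lfc, p, fdr)], DEG_THRESHOLDS)
        assert rec.direction in ("up", "down", "ns")
        if rec.direction == "up":
            assert lfc >= 0.5 and fdr <= 0.05
        if rec.direction == "down":
            assert lfc <= -0.5 and fdr <= 0.05


class TestTestCounts:
    def test_identical_groups_null(self):
        arr = [[50, 60, 50, 60], [200, 180, 200, 180]]
        m = _counts(arr, {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"})
        for rec in run_count_test(m):
            assert rec.log2fc == pytest.approx(0.0)
            assert rec.p_value == pytest.approx(1.0, abs=0.05)

    def test_all_zero_feature_filtered(self):
        arr = [[0, 0, 0, 0], [50, 60, 50, 60]]
        m = _counts(arr, {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"})
        recs = run_count_test(m)
        assert [r.feature_id for r in recs] == ["f1"]

    def test_planted_effect_recovered(self):
        # strong planted fold change at low dispersion is called essentially always
        called = 0
        for seed in range(20):
            cm, _ = simulate_counts(
                [f"g{i}" for i in range(200)], 5,
                {"g0": 3.0}, baseline_mean=200, dispersion=0.02, seed=seed,
            )
            recs = {r.feature_id: r for r in classify(run_count_test(cm), DEG_THRESHOLDS)}
            if recs["g0"].direction == "up" and recs["g0"].fdr < 0.05:
                called += 1
        assert called >= 19

    def test_sign_symmetry_under_group_swap(self):
        cm, _ = simulate_counts([f"g{i}" for i in range(50)], 3,
                                {"g1": 1.0}, seed=11)
        swapped = CountMatrix(
            cm.values.copy(),
            {s: ("treated" if g == "control" else "control") for s, g in cm.group_labels.items()},
        )
        a = {r.feature_id: r for r in run_count_test(cm)}
        b = {r.feature_id: r for r in run_count_test(swapped)}
        for fid in a:
            assert a[fid].log2fc == pytest.approx(-b[fid].log2fc, abs=1e-9)
            assert a[fid].p_value == pytest.approx(b[fid].p_value, abs=1e-9)

    def test_single_sample_group_rejected(self):
        m = _counts([[5, 6, 7]], {"c1": "control", "t1": "treated", "t2": "treated"})
        with pytest.raises(ValidationError):
            run_count_test(m)


def _meth(meth_rows, unmeth_rows, groups):
    idx = pd.Index([f"r{i}" for i in range(len(meth_rows))], name="region_id")
    regions = pd.DataFrame(
        [("chr1", 100 * i, 100 * (i + 1), "CpG") for i in range(len(meth_rows))],
        index=idx, columns=["chrom", "start", "end", "context"],
    )
    cols = list(groups)
    return MethylRegionTable(
        regions,
        pd.DataFrame(meth_rows, index=idx, columns=cols),
        pd.DataFrame(unmeth_rows, index=idx, columns=cols),
        groups,
    )


GROUPS12 = {f"c{i}": "control" for i in range(6)} | {f"t{i}": "treated" for i in range(6)}


class TestLowCoverageFilter:
    def test_half_of_samples_below_four_removed(self):
        # 6 of 12 samples with 3 reads -> exactly 50% -> removed
        meth = [[1] * 12]
        unmeth = [[2] * 6 + [10] * 6]
        t = _meth(meth, unmeth, GROUPS12)
        assert len(filter_low_coverage_regions(t).regions) == 0

    def test_under_half_low_kept(self):
        meth = [[0] * 5 + [3] * 7]
        unmeth = [[0] * 5 + [2] * 7]
        t = _meth(meth, unmeth, GROUPS12)
        assert len(filter_low_coverage_regions(t).regions) == 1

    def test_all_covered_kept(self):
        t = _meth([[5] * 12], [[5] * 12], GROUPS12)
        assert len(filter_low_coverage_regions(t).regions) == 1


class TestTestMethylation:
    def test_identical_fractions_zero_lfc(self):
        t = _meth([[10, 10, 10, 10]], [[30, 30, 30, 30]],
                  {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"})
        (rec,) = run_methylation_test(t)
        assert rec.log2fc == pytest.approx(0.0)
        assert rec.p_value > 0.99

    def test_pooled_odds_ratio_with_pseudocounts(self):
        t = _meth([[5, 5, 25, 25]], [[45, 45, 25, 25]],
                  {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"})
        (rec,) = run_methylation_test(t)
        expected = np.log2((50.5 / 50.5) / (10.5 / 90.5))
        assert rec.log2fc == pytest.approx(expected)
        assert rec.p_value < 1e-6

    def test_zero_reads_in_group_rejected(self):
        t = _meth([[0, 0, 5, 5]], [[0, 0, 5, 5]],
                  {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"})
        with pytest.raises(ValidationError):
            run_methylation_test(t)

    def test_planted_shift_recovered(self):
        from triomix import generate_annotation, simulate_methylation

        ann = generate_annotation(5, seed=0)
        gene = ann.genes[0].gene_id
        called = 0
        for seed in range(20):
            tab, _, _ = simulate_methylation(
                ann, coverage_mean=30, planted_dmrs={gene: 2.0}, n_per_group=6,
                n_background=20, seed=seed,
            )
            recs = {r.feature_id: r for r in run_methylation_test(tab)}
            r = recs[f"dmr_{gene}"]
            if r.p_value <= 0.05 and abs(r.log2fc) >= 1:
                called += 1
        assert called >= 18
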