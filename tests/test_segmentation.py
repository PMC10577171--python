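"""DP segmentation: optimality, breakpoints, baselines, validation transfer."""

import itertools

import numpy as np
import pytest

import radioseg as rs
from radioseg.segmentation import (
    SegmentCostTable,
    classify_labels,
    compute_breakpoints,
    mean_split_baseline,
    optimal_segmentation,
    segment_cost,
    stability_scan,
    evaluate_validation,
)
from radioseg.simulate import Regime, SyntheticSpec, default_study_spec, generate

from conftest import make_cohort


def brute_force_min_cost(table, K, min_size):
    """Exhaustive enumeration of all K-partitions; left-to-right cost sums."""
    N = table.n_samples
    best = np.inf
    positions = range(min_size, N - min_size + 1)
    for cuts in itertools.combinations(positions, K - 1):
        edges = (0,) + cuts + (N,)
        if any(edges[i + 1] - edges[i] < min_size for i in range(K)):
            continue
        total = 0.0
        for i in range(K):
            total = total + table.cost(edges[i], edges[i + 1])
        if total < best:
            best = total
    return best


def small_cohort(seed, n):
    """Two-regime synthetic cohort with a handful of markers."""
    spec = SyntheticSpec(
        n_samples=n,
        n_markers=8,
        sf2_range=(0.14, 0.49),
        regimes=(
            Regime(upper=0.30, support=(0,), coefficients=(0.2,), intercept=0.2),
            Regime(upper=0.49, support=(1,), coefficients=(-0.15,), intercept=0.42),
        ),
        noise_sd=0.01,
        seed=seed,
    )
    cohort, truth = generate(spec)
    return cohort, truth


def check_mre_identity(seg):
    """The overall MRE equals both the weighted batch mean and the plain mean."""
    N = len(seg.sample_ids)
    weighted = sum(
        m * size / N for m, size in zip(seg.segment_mre, seg.segment_sizes)
    )
    assert seg.overall_mre == pytest.approx(weighted, abs=1e-12)
    assert seg.overall_mre == pytest.approx(seg.per_sample_re.mean(), abs=1e-12)


class TestSegmentCost:
    def test_noiseless_window_has_near_zero_cost(self):
        spec = SyntheticSpec(
            n_samples=20, n_markers=5,
            regimes=(Regime(upper=0.49, support=(0,), coefficients=(0.2,),
                            intercept=0.3),),
            sf2_range=(0.14, 0.49), noise_sd=0.0, seed=1,
        )
        cohort, _ = generate(spec)
        sc = cohort.sorted_by_sf2()
        _, cost = segment_cost(sc, 0, 19, list(sc.marker_ids))
        assert cost == pytest.approx(0.0, abs=1e-8)

    def test_intercept_only_cost_is_null_model_re_sum(self, rng):
        """When no candidate clears the BF bar, cost is the mean-model RE sum."""
        n = 15
        fc = rng.normal(size=(n, 3))
        sf2 = rng.uniform(0.2, 0.4, n)
        sc = make_cohort(fc, sf2).sorted_by_sf2()
        model, cost = segment_cost(sc, 0, n - 1, list(sc.marker_ids),
                                   bf_threshold=np.inf)
        assert model.terms == ()
        oracle = np.sum(np.abs(sf2.mean() - np.sort(sf2)) / np.sort(sf2))
        assert cost == pytest.approx(oracle, abs=1e-10)

    def test_memoization_returns_identical_results(self):
        cohort, _ = small_cohort(seed=2, n=25)
        sc = cohort.sorted_by_sf2()
        table = SegmentCostTable(sc, list(sc.marker_ids)[:4], min_size=5)
        c1 = table.cost(0, 12)
        c2 = table.cost(0, 12)
        assert c1 == c2
        assert (0, 12) in table._cache

    def test_window_below_min_size_rejected(self):
        cohort, _ = small_cohort(seed=2, n=25)
        sc = cohort.sorted_by_sf2()
        table = SegmentCostTable(sc, list(sc.marker_ids)[:4], min_size=10)
        with pytest.raises(ValueError, match="min_size"):
            table.cost(0, 5)


class TestOptimalSegmentation:
    def test_k1_equals_global_model(self):
        cohort, _ = small_cohort(seed=3, n=30)
        cands = rs.select_candidates(rs.pearson_screen(cohort), alpha=1e-3)
        seg = optimal_segmentation(cohort, 1, cands, min_size=10)
        model, _ = rs.forward_select(cohort, cands)
        metrics = rs.evaluate(model, cohort)
        assert seg.K == 1
        assert seg.boundaries == ()
        assert seg.overall_mre == pytest.approx(metrics.mre, abs=1e-12)

    @pytest.mark.parametrize("seed,K", [(0, 2), (1, 2), (2, 3), (3, 3)])
    def test_dp_equals_brute_force(self, seed, K):
        cohort, _ = small_cohort(seed=seed, n=27)
        cands = list(cohort.marker_ids)[:4]
        sc = cohort.sorted_by_sf2()
        table = SegmentCostTable(sc, cands, min_size=5)
        seg = optimal_segmentation(cohort, K, cands, min_size=5, table=table)
        edges = (0,) + seg.boundaries + (27,)
        total = 0.0
        for i in range(K):  # left-to-right, matching the DP's accumulation
            total = total + table.cost(edges[i], edges[i + 1])
        oracle = brute_force_min_cost(table, K, min_size=5)
        assert total == oracle  # exact: same cost terms, same summation order

    def test_planted_boundary_recovered_noiselessly(self):
        spec = SyntheticSpec(
            n_samples=40, n_markers=6,
            sf2_range=(0.14, 0.49),
            regimes=(
                Regime(upper=0.30, support=(0,), coefficients=(0.2,), intercept=0.2),
                Regime(upper=0.49, support=(1,), coefficients=(-0.15,),
                       intercept=0.42),
            ),
            noise_sd=0.0, seed=5,
        )
        cohort, truth = generate(spec)
        seg = optimal_segmentation(cohort, 2, list(cohort.marker_ids)[:2],
                                   min_size=5)
        assert seg.boundaries == truth.sorted_cut_positions(cohort.sf2)
        assert seg.overall_mre < 1e-6

    def test_mre_identity_and_breakpoint_monotonicity(self):
        cohort, _ = generate(default_study_spec(seed=6, n_null_markers=100))
        cands = rs.select_candidates(rs.pearson_screen(cohort))
        for K in (2, 3, 4):
            seg = optimal_segmentation(cohort, K, cands)
            check_mre_identity(seg)
            assert all(b1 < b2 for b1, b2 in zip(seg.breakpoints,
                                                 seg.breakpoints[1:]))
            assert all(s >= 10 for s in seg.segment_sizes)

    def test_dp_dominates_random_segmentations(self, rng):
        cohort, _ = small_cohort(seed=7, n=30)
        cands = list(cohort.marker_ids)[:4]
        sc = cohort.sorted_by_sf2()
        table = SegmentCostTable(sc, cands, min_size=5)
        seg = optimal_segmentation(cohort, 3, cands, min_size=5, table=table)
        dp_total = seg.per_sample_re.sum()
        N = 30
        tried = 0
        while tried < 100:
            cuts = sorted(rng.choice(range(5, N - 4), size=2, replace=False))
            edges = [0] + list(cuts) + [N]
            if any(edges[i + 1] - edges[i] < 5 for i in range(3)):
                continue
            tried += 1
            total = sum(table.cost(edges[i], edges[i + 1]) for i in range(3))
            assert dp_total <= total + 1e-12

    def test_infeasible_k_rejected(self):
        cohort, _ = small_cohort(seed=8, n=25)
        with pytest.raises(ValueError, match="infeasible"):
            optimal_segmentation(cohort, 3, list(cohort.marker_ids), min_size=10)


class TestBreakpointsAndLabels:
    def test_breakpoint_is_max_of_lower_segment(self):
        sorted_sf2 = np.array([0.1, 0.2, 0.3, 0.4])
        assert compute_breakpoints([2], sorted_sf2) == (0.2,)
        assert compute_breakpoints([], sorted_sf2) == ()
        assert compute_breakpoints([1, 3], sorted_sf2) == (0.1, 0.3)

    def test_labels_k2_and_k5(self):
        assert classify_labels(2, [3, 2]) == ("RS",) * 3 + ("RR",) * 2
        labels5 = classify_labels(5, [2, 2, 2, 2, 2])
        assert labels5[:2] == ("RS", "RS")
        assert labels5[-2:] == ("RR", "RR")
        assert set(labels5[2:8]) == {"NS"}
        assert len(labels5) == 10

    def test_k1_not_classifiable(self):
        with pytest.raises(ValueError):
            classify_labels(1, [10])


class TestStabilityScan:
    def test_single_point_scan_flags_unstabilized(self):
        cohort, _ = small_cohort(seed=9, n=40)
        cands = list(cohort.marker_ids)[:3]
        res = stability_scan(cohort, cands, K_min=3, K_max=3, min_size=10)
        assert res.recommended_K == 3
        assert not res.stabilized

    def test_five_regime_signal_stabilizes_utmost_borders(self):
        """Strong planted structure: utmost borders repeat across K, usually at K=5."""
        stab_at_5 = 0
        for seed in range(5):
            cohort, _ = generate(default_study_spec(seed=seed))
            cands = rs.select_candidates(rs.pearson_screen(cohort))
            res = stability_scan(cohort, cands)
            if res.stabilized:
                K = res.recommended_K
                low, hi = (res.segmentations[K].breakpoints[0],
                           res.segmentations[K].breakpoints[-1])
                assert low == res.segmentations[K + 1].breakpoints[0]
                assert hi == res.segmentations[K + 1].breakpoints[-1]
                if K == 5:
                    stab_at_5 += 1
        assert stab_at_5 >= 3

    def test_mre_decreases_with_k(self):
        cohort, _ = generate(default_study_spec(seed=0))
        cands = rs.select_candidates(rs.pearson_screen(cohort))
        res = stability_scan(cohort, cands, K_min=2, K_max=5)
        mres = [res.segmentations[K].overall_mre for K in range(2, 6)]
        assert all(a >= b for a, b in zip(mres, mres[1:]))


class TestMeanSplitBaseline:
    def test_symmetric_toy_splits_in_half(self, rng):
        sf2 = np.concatenate([rng.uniform(0.2, 0.25, 10), rng.uniform(0.35, 0.4, 10)])
        fc = rng.normal(size=(20, 3))
        seg = mean_split_baseline(make_cohort(fc, sf2), ["M0"])
        assert seg.segment_sizes == (10, 10)

    def test_strictly_below_mean_goes_low_side(self):
        sf2 = np.array([0.2, 0.25, 0.3, 0.3, 0.35, 0.4])  # mean = 0.3
        fc = np.zeros((6, 1))
        seg = mean_split_baseline(make_cohort(fc, sf2), [])
        # samples with SF2 < 0.3 (two of them) form the lower side
        assert seg.segment_sizes == (2, 4)
        assert seg.breakpoints == (0.25,)

    def test_weighted_mre_identity(self):
        cohort, _ = small_cohort(seed=10, n=30)
        seg = mean_split_baseline(cohort, list(cohort.marker_ids)[:3])
        check_mre_identity(seg)

    def test_dp_two_segment_never_worse(self):
        """DP optimality dominance over the particular mean split."""
        for seed in range(3):
            cohort, _ = generate(default_study_spec(seed=seed,
                                                        n_null_markers=200))
            cands = rs.select_candidates(rs.pearson_screen(cohort))
            dp = optimal_segmentation(cohort, 2, cands)
            base = mean_split_baseline(cohort, cands)
            assert dp.overall_mre <= base.overall_mre + 1e-12


@pytest.fixture(scope="module")
def fitted():
    cohort, _ = generate(default_study_spec(seed=11, n_null_markers=100))
    split = rs.split_train_validation(cohort, 13, seed=11)
    cands = rs.select_candidates(rs.pearson_screen(split.train))
    seg = optimal_segmentation(split.train, 4, cands)
    return seg, split


class TestEvaluateValidation:
    def test_training_as_validation_reproduces_training_mre(self, fitted):
        seg, split = fitted
        metrics = evaluate_validation(seg, split.train)
        assert metrics.weighted_mre == pytest.approx(seg.overall_mre, abs=1e-12)
        assert metrics.flagged == ()

    def test_out_of_range_sample_flagged_to_utmost_segment(self, fitted):
        seg, split = fitted
        low = float(seg.sf2[0])
        tiny = make_cohort(np.zeros((2, split.train.n_markers)),
                           [low / 2, low / 2 + 0.001])
        tiny = rs.CohortMatrix(tiny.sample_ids, split.train.marker_ids,
                               tiny.fc, tiny.sf2)
        metrics = evaluate_validation(seg, tiny)
        assert metrics.assignments == (0, 0)
        assert set(metrics.flagged) == set(tiny.sample_ids)

    def test_weighted_mre_is_hand_computed_mean(self, fitted):
        seg, split = fitted
        metrics = evaluate_validation(seg, split.validation)
        res = []
        for i, sid in enumerate(split.validation.sample_ids):
            k = metrics.assignments[i]
            sub = split.validation.take_samples([i])
            pred = seg.segment_models[k].predict(sub)[0]
            res.append(abs(pred - sub.sf2[0]) / abs(sub.sf2[0]))
        assert metrics.weighted_mre == pytest.approx(np.mean(res), abs=1e-12)

    def test_breakpoint_assignment_is_upper_inclusive(self, fitted):
        seg, _ = fitted
        bp = seg.breakpoints[0]
        tiny = make_cohort(np.zeros((1, 1)), [bp])
        tiny = rs.CohortMatrix(tiny.sample_ids, seg.segment_models[0].markers or
                               ("M00001",), np.zeros((1, 1)), tiny.sf2)
        # a sample exactly at the first breakpoint belongs to the first segment
        assign = np.searchsorted(np.asarray(seg.breakpoints), tiny.sf2,
                                 side="left")
        assert assign[0] == 0
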