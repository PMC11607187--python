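import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conformalseg import (
    CalibrationTable,
    MondrianConformalSegmenter,
    calibrate,
    certain_masks,
    empirical_coverage,
    ensemble_average,
    nonconformity,
    p_value,
    predict_regions,
    threshold_map,
)
from conformalseg.conformal import (
    REGION_BG,
    REGION_BOTH,
    REGION_EMPTY,
    REGION_FG,
    CalibrationError,
    PredictionRegionMap,
)
from conformalseg.grids import GridMismatchError, LabelMask, ProbabilityMap


def _pmap(arr, spacing=(1.0, 1.0, 1.0)):
    return ProbabilityMap(np.asarray(arr, dtype=float), spacing)


def _mask(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelMask(np.asarray(arr), spacing)


def _pvalue_oracle(score, scores):
    return (sum(1 for s in scores if s >= score) + 1) / (len(scores) + 1)


class TestEnsembleAverage:
    def test_single_map_returned_unchanged(self):
        m = _pmap(np.random.default_rng(0).random((4, 4, 2)))
        assert np.allclose(ensemble_average([m]).probs, m.probs)

    def test_five_identical_maps_average_to_themselves(self):
        m = _pmap(np.full((3, 3, 3), 0.3))
        assert np.allclose(ensemble_average([m] * 5).probs, m.probs)

    def test_known_voxel_mean(self):
        maps = [_pmap(np.full((1, 1, 1), v)) for v in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert ensemble_average(maps).probs[0, 0, 0] == pytest.approx(0.6)

    def test_grid_mismatch_rejected(self):
        a = _pmap(np.zeros((2, 2, 2)))
        b = _pmap(np.zeros((2, 2, 2)), spacing=(0.5, 0.5, 3.0))
        with pytest.raises(GridMismatchError):
            ensemble_average([a, b])


class TestThresholdMap:
    def test_all_ones_give_full_foreground(self):
        assert threshold_map(_pmap(np.ones((2, 2, 2)))).voxels.all()

    def test_tie_goes_to_foreground(self):
        m = threshold_map(_pmap(np.full((1, 1, 1), 0.5)), t=0.5)
        assert m.voxels[0, 0, 0] == 1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_map(_pmap(np.zeros((1, 1, 1))), t=1.0)


class TestNonconformity:
    @pytest.mark.parametrize(
        "p_fg,label,expected",
        [(1.0, 1, 0.0), (1.0, 0, 1.0), (0.7, 0, 0.7), (0.7, 1, pytest.approx(0.3))],
    )
    def test_score_is_one_minus_label_probability(self, p_fg, label, expected):
        assert nonconformity(p_fg, label) == expected

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            nonconformity(0.5, 2)


class TestPValue:
    def test_score_below_all_calibration_scores(self):
        assert p_value(0.05, np.array([0.1, 0.2, 0.3])) == 1.0

    def test_score_above_all_calibration_scores(self):
        assert p_value(0.9, np.array([0.1, 0.2, 0.3])) == 0.25

    def test_midrange_score_counts_ties_as_ge(self):
        assert p_value(0.15, np.array([0.1, 0.2, 0.3])) == 0.75

    def test_empty_scores_rejected(self):
        with pytest.raises(CalibrationError):
            p_value(0.5, np.array([]))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        score=st.floats(0, 1),
        scores=st.lists(st.floats(0, 1), min_size=1, max_size=50),
    )
    def test_matches_rank_enumeration_oracle(self, score, scores):
        assert p_value(score, np.array(scores)) == pytest.approx(
            _pvalue_oracle(score, scores)
        )

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(4)
        cal = np.sort(rng.random(20))
        scores = rng.random(50)
        vec = p_value(scores, cal)
        assert np.allclose(vec, [p_value(s, cal) for s in scores])


class TestCalibrate:
    def test_no_subsampling_keeps_every_voxel_once(self):
        p = _pmap([[[0.9, 0.8]], [[0.7, 0.2]]])
        m = _mask([[[1, 1]], [[1, 0]]])
        table = calibrate([(p, m)], per_class_cap=100, seed=0)
        assert np.allclose(table.scores_fg, [0.1, 0.2, 0.3])
        assert np.allclose(table.scores_bg, [0.2])

    def test_perfect_segmenter_scores_all_zero(self):
        labels = np.random.default_rng(5).integers(0, 2, (4, 4, 2))
        table = calibrate([(_pmap(labels.astype(float)), _mask(labels))], seed=0)
        assert np.all(table.scores_fg == 0)
        assert np.all(table.scores_bg == 0)

    def test_missing_class_raises_naming_it(self):
        p = _pmap(np.full((2, 2, 2), 0.9))
        m = _mask(np.ones((2, 2, 2)))
        with pytest.raises(CalibrationError, match="background"):
            calibrate([(p, m)])

    def test_cap_and_seed_are_deterministic(self, small_cohort):
        exams = [(e.prob, e.mask) for e in small_cohort[:3]]
        t1 = calibrate(exams, per_class_cap=500, seed=9)
        t2 = calibrate(exams, per_class_cap=500, seed=9)
        assert np.array_equal(t1.scores_fg, t2.scores_fg)
        assert t1.scores_fg.size == 1500

    def test_table_round_trips_through_file(self, tmp_path, small_cohort):
        exams = [(e.prob, e.mask) for e in small_cohort[:2]]
        table = calibrate(exams, per_class_cap=100, seed=1)
        table.save(tmp_path / "table.npz")
        loaded = CalibrationTable.load(tmp_path / "table.npz")
        assert np.array_equal(loaded.scores_bg, table.scores_bg)
        assert loaded.per_class_cap == table.per_class_cap
        assert loaded.seed == table.seed


class TestPredictRegions:
    def test_tiny_alpha_yields_all_both(self):
        table = CalibrationTable(np.array([0.1, 0.5]), np.array([0.2, 0.6]), 10, 0)
        regions = predict_regions(_pmap(np.random.default_rng(6).random((3, 3, 2))), table, 0.01)
        assert np.all(regions.codes == REGION_BOTH)

    def test_perfectly_confident_voxel_is_certain_foreground(self):
        n = 19  # alpha 0.15 >= 1/(n+1) so the background label can be excluded
        table = CalibrationTable(np.zeros(n), np.zeros(n), 100, 0)
        regions = predict_regions(_pmap(np.ones((1, 1, 1))), table, 0.15)
        assert regions.codes[0, 0, 0] == REGION_FG

    def test_ambiguous_voxel_with_symmetric_tables_is_both(self):
        sym = np.array([0.2, 0.4, 0.6])
        table = CalibrationTable(sym, sym.copy(), 10, 0)
        regions = predict_regions(_pmap(np.full((1, 1, 1), 0.5)), table, 0.15)
        assert regions.codes[0, 0, 0] == REGION_BOTH

    def test_nested_regions_across_alpha_sweep(self, fitted_segmenter, eval_exams):
        # smaller alpha never removes labels: region(a2) subset of region(a1) for a1 < a2
        alphas = (0.01, 0.05, 0.10, 0.15, 0.20)
        for exam in eval_exams[:4]:
            regs = [fitted_segmenter.predict(exam.prob, alpha=a) for a in alphas]
            for lo, hi in zip(regs, regs[1:]):
                for label in (0, 1):
                    assert not np.any(hi.covers(label) & ~lo.covers(label))

    def test_ambiguity_shrinks_as_alpha_grows(self, fitted_segmenter, eval_exams):
        alphas = (0.01, 0.05, 0.10, 0.15, 0.20)
        for exam in eval_exams[:4]:
            n_both = [
                int((fitted_segmenter.predict(exam.prob, alpha=a).codes == REGION_BOTH).sum())
                for a in alphas
            ]
            assert all(b >= a for a, b in zip(n_both[1:], n_both))


class TestCertainMasks:
    def test_all_fg_map(self):
        reg = PredictionRegionMap(np.full((2, 2, 2), REGION_FG), 0.15, (1, 1, 1))
        certain, uncertain = certain_masks(reg)
        assert certain.voxels.all() and not uncertain.voxels.any()

    def test_all_both_map(self):
        reg = PredictionRegionMap(np.full((2, 2, 2), REGION_BOTH), 0.15, (1, 1, 1))
        certain, uncertain = certain_masks(reg)
        assert not certain.voxels.any() and uncertain.voxels.all()

    def test_mixed_map_counts(self):
        codes = np.concatenate(
            [
                np.full(10, REGION_FG),
                np.full(80, REGION_BG),
                np.full(7, REGION_BOTH),
                np.full(3, REGION_EMPTY),
            ]
        ).reshape(10, 10, 1)
        certain, uncertain = certain_masks(PredictionRegionMap(codes, 0.15, (1, 1, 1)))
        assert certain.voxels.sum() == 10
        assert uncertain.voxels.sum() == 10


class TestCoverage:
    def test_both_covers_everything(self):
        reg = PredictionRegionMap(np.full((2, 2, 2), REGION_BOTH), 0.15, (1, 1, 1))
        truth = _mask(np.random.default_rng(7).integers(0, 2, (2, 2, 2)))
        assert empirical_coverage([reg], [truth], 0) == 1.0
        assert empirical_coverage([reg], [truth], 1) == 1.0

    def test_empty_covers_nothing(self):
        reg = PredictionRegionMap(np.full((2, 2, 2), REGION_EMPTY), 0.15, (1, 1, 1))
        truth = _mask(np.ones((2, 2, 2)))
        assert empirical_coverage([reg], [truth], 1) == 0.0

    def test_absent_class_is_an_error(self):
        reg = PredictionRegionMap(np.full((2, 2, 2), REGION_FG), 0.15, (1, 1, 1))
        with pytest.raises(CalibrationError):
            empirical_coverage([reg], [_mask(np.ones((2, 2, 2)))], 0)

    def test_mean_coverage_over_cohorts_near_nominal(self):
        # marginal validity in expectation: average per-class coverage across
        # independently generated cohorts stays near 1 - alpha (loose band;
        # single-cohort coverage fluctuates at the exam level)
        from conftest import SMALL_SPEC
        from conformalseg import generate_cohort

        covs = {0: [], 1: []}
        for seed in (101, 102, 103):
            cohort = generate_cohort(SMALL_SPEC, 30, seed)
            cal, ev = cohort[:10], cohort[10:]
            clf = MondrianConformalSegmenter(alpha=0.15, random_state=1).fit(
                [e.prob for e in cal], [e.mask for e in cal]
            )
            regs = clf.predict([e.prob for e in ev])
            for label in (0, 1):
                covs[label].append(empirical_coverage(regs, [e.mask for e in ev], label))
        for label in (0, 1):
            assert np.mean(covs[label]) > 0.78
            assert np.mean(covs[label]) < 0.97


class TestEstimatorProtocol:
    def test_get_set_params_round_trip(self):
        clf = MondrianConformalSegmenter(alpha=0.1, per_class_cap=50, random_state=2)
        params = clf.get_params()
        assert params == {"alpha": 0.1, "per_class_cap": 50, "random_state": 2}
        clf.set_params(alpha=0.2)
        assert clf.alpha == 0.2

    def test_unfitted_predict_raises(self, small_cohort):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            MondrianConformalSegmenter().predict(small_cohort[0].prob)

    def test_fit_exposes_sorted_score_attributes(self, fitted_segmenter):
        for s in (fitted_segmenter.scores_bg_, fitted_segmenter.scores_fg_):
            assert np.all(np.diff(s) >= 0)
            assert s.min() >= 0 and s.max() <= 1

    def test_score_is_worst_class_coverage(self, fitted_segmenter, eval_exams):
        X = [e.prob for e in eval_exams[:4]]
        y = [e.mask for e in eval_exams[:4]]
        regs = fitted_segmenter.predict(X)
        expected = min(empirical_coverage(regs, y, c) for c in (0, 1))
        assert fitted_segmenter.score(X, y) == pytest.approx(expected)
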