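"""Preprocessing chain: filters, shift, log2, quantile normalisation,
per-run standardisation — each checked against hand computations or
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from basalmir.errors import ValidationError
from basalmir.preprocess import (
    ArrayPreprocessor,
    RunStandardizer,
    filter_by_detection,
    filter_low_intensity,
    log2_transform,
    quantile_normalize,
    shift_min_to_one,
    standardize_features,
)
from basalmir.simulate import ExpressionSimConfig, gen_expression
from basalmir.types import ExpressionMatrix, SampleAnnotation, Stage


def _raw(values, features=None, samples=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix(
        values,
        Stage.RAW,
        feature_ids=features or [f"f{i}" for i in range(values.shape[0])],
        sample_ids=samples or [f"s{j}" for j in range(values.shape[1])],
    )


class TestIntensityFilter:
    def test_boundary_at_threshold_is_retained(self):
        # "less than 150 ... excluded": maxima 149.9 drops, 150 and 600 stay
        m = _raw([[149.9, 10.0], [150.0, 10.0], [600.0, 10.0]])
        kept = filter_low_intensity(m, 150.0)
        assert kept.feature_ids == ["f1", "f2"]
        assert kept.stage is Stage.FILTERED

    def test_zero_threshold_is_identity_on_positive_matrices(self):
        m = _raw([[1.0, 2.0], [3.0, 4.0]])
        assert filter_low_intensity(m, 0.0).feature_ids == m.feature_ids

    def test_agrees_with_brute_force_max(self, rng):
        values = rng.uniform(0, 400, size=(200, 8))
        m = _raw(values)
        kept = set(filter_low_intensity(m, 150.0).feature_ids)
        expected = {f"f{i}" for i in range(200) if max(values[i]) >= 150.0}
        assert kept == expected

    def test_planted_subthreshold_features_removed(self, rng):
        values = rng.uniform(200, 400, size=(300, 6))
        low = rng.choice(300, size=100, replace=False)
        values[low] = rng.uniform(0, 149, size=(100, 6))
        kept = set(filter_low_intensity(_raw(values), 150.0).feature_ids)
        assert kept == {f"f{i}" for i in range(300) if i not in set(low)}

    def test_all_removed_is_hard_error(self):
        with pytest.raises(ValidationError):
            filter_low_intensity(_raw([[1.0, 2.0]]), 150.0)

    def test_features_with_missing_values_are_dropped(self):
        m = _raw([[200.0, np.nan], [200.0, 300.0]])
        assert filter_low_intensity(m, 150.0).feature_ids == ["f1"]


class TestDetectionFilter:
    def test_all_scores_at_threshold_removed_strict(self):
        m = _raw([[5.0, 6.0]])
        scores = pd.DataFrame([[0.95, 0.95]], index=["f0"], columns=["s0", "s1"])
        with pytest.raises(ValidationError):
            filter_by_detection(m, scores, 0.95)

    def test_single_exceeding_score_retains(self):
        m = _raw([[5.0, 6.0], [7.0, 8.0]])
        scores = pd.DataFrame(
            [[0.96, 0.10], [0.95, 0.95]], index=["f0", "f1"], columns=["s0", "s1"]
        )
        assert filter_by_detection(m, scores, 0.95).feature_ids == ["f0"]

    def test_agrees_with_any_scan(self, rng):
        values = rng.uniform(1, 10, size=(50, 5))
        scores = rng.uniform(0.5, 1.0, size=(50, 5))
        m = _raw(values)
        grid = pd.DataFrame(scores, index=m.feature_ids, columns=m.sample_ids)
        kept = set(filter_by_detection(m, grid, 0.95).feature_ids)
        expected = {m.feature_ids[i] for i in range(50) if (scores[i] > 0.95).any()}
        assert kept == expected


class TestShiftAndLog:
    def test_shift_arithmetic(self):
        m = _raw([[-50.0], [0.0], [100.0]]).advance(
            np.array([[-50.0], [0.0], [100.0]]), Stage.FILTERED
        )
        shifted = shift_min_to_one(m)
        assert shifted.values[:, 0].tolist() == [1.0, 51.0, 151.0]

    def test_shift_is_identity_when_min_is_one(self):
        m = _raw([[1.0], [5.0]]).advance(np.array([[1.0], [5.0]]), Stage.FILTERED)
        assert (shift_min_to_one(m).values == m.values).all()

    def test_shift_idempotent_on_own_output(self, rng):
        values = rng.normal(0, 50, size=(20, 4))
        m = _raw(values).advance(values, Stage.FILTERED)
        once = shift_min_to_one(m)
        twice = shift_min_to_one(once)
        assert np.allclose(once.values, twice.values)
        assert np.allclose(once.values.min(axis=0), 1.0)

    def test_log2_values(self):
        m = _raw([[1.0], [8.0]])
        shifted = m.advance(m.values, Stage.FILTERED).advance(m.values, Stage.SHIFTED)
        logged = log2_transform(shifted)
        assert logged.values[:, 0].tolist() == [0.0, 3.0]

    def test_log2_round_trip(self, rng):
        x = rng.uniform(0, 10, size=(30, 3))
        m = _raw(2.0**x).advance(2.0**x, Stage.FILTERED).advance(2.0**x, Stage.SHIFTED)
        assert np.allclose(log2_transform(m).values, x)


def _log2_matrix(values):
    values = np.asarray(values, dtype=float)
    m = _raw(values)
    return (
        m.advance(values, Stage.FILTERED)
        .advance(values, Stage.SHIFTED)
        .advance(values, Stage.LOG2)
    )


class TestQuantileNormalize:
    def test_hand_computed_two_sample_reference(self):
        # samples (1,2) and (3,4): rank-wise reference means (2,3)
        qn = quantile_normalize(_log2_matrix([[1.0, 3.0], [2.0, 4.0]]))
        assert qn.values.tolist() == [[2.0, 2.0], [3.0, 3.0]]

    def test_identical_samples_are_fixed_point(self):
        values = [[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]]
        qn = quantile_normalize(_log2_matrix(values))
        assert np.allclose(qn.values, values)

    def test_all_columns_share_sorted_vector(self, rng):
        qn = quantile_normalize(_log2_matrix(rng.normal(5, 2, size=(40, 6))))
        ref = np.sort(qn.values[:, 0])
        for j in range(qn.shape[1]):
            assert np.allclose(np.sort(qn.values[:, j]), ref)

    def test_ties_get_mean_of_reference_span(self):
        # column 0 has a 2-way tie at the bottom ranks
        qn = quantile_normalize(_log2_matrix([[1.0, 1.0], [1.0, 2.0], [5.0, 3.0]]))
        ref = np.sort(np.array([[1, 1], [1, 2], [5, 3]]), axis=0).mean(axis=1)
        assert np.allclose(qn.values[:2, 0], ref[:2].mean())
        assert qn.values[2, 0] == ref[2]

    def test_idempotent(self, rng):
        once = quantile_normalize(_log2_matrix(rng.normal(5, 2, size=(25, 4))))
        assert np.allclose(quantile_normalize(once).values, once.values)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        arrays(
            float,
            (12, 4),
            elements=st.floats(0, 16, allow_nan=False, allow_infinity=False),
        )
    )
    def test_preserves_within_sample_rank_order(self, values):
        qn = quantile_normalize(_log2_matrix(values))
        for j in range(values.shape[1]):
            before = values[:, j]
            after = qn.values[:, j]
            for a in range(12):
                for b in range(12):
                    if before[a] < before[b]:
                        assert after[a] <= after[b]


class TestStandardize:
    def test_hand_example_single_run(self):
        values = np.array([[2.0, 4.0, 6.0]])
        m = _log2_matrix(values).advance(values, Stage.QUANTILE_NORMALIZED)
        anns = [SampleAnnotation(f"s{j}", "normal", "run1", "chip1") for j in range(3)]
        out, flagged = standardize_features(m, anns)
        assert np.allclose(out.values, [[-1.0, 0.0, 1.0]])  # mean 4, sample sd 2
        assert flagged == []

    def test_constant_feature_zeroed_and_flagged(self):
        values = np.array([[7.0, 7.0, 7.0], [1.0, 2.0, 3.0]])
        m = _log2_matrix(values).advance(values, Stage.QUANTILE_NORMALIZED)
        anns = [SampleAnnotation(f"s{j}", "normal", "run1", "chip1") for j in range(3)]
        out, flagged = standardize_features(m, anns)
        assert (out.values[0] == 0).all()
        assert flagged == ["f0"]

    def test_per_run_moments(self, rng):
        values = rng.normal(8, 2, size=(30, 10))
        m = _log2_matrix(values).advance(values, Stage.QUANTILE_NORMALIZED)
        anns = [
            SampleAnnotation(f"s{j}", "normal", "run1" if j < 4 else "run2", f"chip{1 if j < 4 else 2}")
            for j in range(10)
        ]
        out, _ = standardize_features(m, anns)
        for cols in ([0, 1, 2, 3], [4, 5, 6, 7, 8, 9]):
            block = out.values[:, cols]
            assert np.allclose(block.mean(axis=1), 0.0, atol=1e-12)
            assert np.allclose(block.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestCompositePipeline:
    def test_zero_noise_no_batch_null_standardizes_to_zero(self):
        # with no noise, no chip effects and no planted effects every sample
        # is identical within a run, so every feature is flagged constant
        # and standardises to exactly zero
        cfg = ExpressionSimConfig(
            seed=3,
            n_features=60,
            n_low_features=0,
            de_features=0,
            noise_sd=0.0,
            chip_effect_sd=0.0,
            n_per_group={"basal_brca1": 4, "basal_sporadic": 4},
            run1_size=4,
        )
        raw, anns, _ = gen_expression(cfg)
        normalized = ArrayPreprocessor(intensity_threshold=0.0).fit_transform(raw)
        standardizer = RunStandardizer(anns)
        std = standardizer.fit(normalized).transform(normalized)
        assert (std.values == 0.0).all()
        assert standardizer.zero_variance_features_ == std.feature_ids

    def test_fitted_preprocessor_reproduces_function_chain(self, study_like_simulation):
        raw, anns, _ = study_like_simulation
        pre = ArrayPreprocessor()
        via_estimator = pre.fit_transform(raw)
        chain = quantile_normalize(
            log2_transform(shift_min_to_one(filter_low_intensity(raw)))
        )
        assert np.allclose(via_estimator.values, chain.values)
        assert pre.retained_features_ == chain.feature_ids

    def test_estimator_params_round_trip(self):
        pre = ArrayPreprocessor(intensity_threshold=99.0)
        assert pre.get_params() == {"intensity_threshold": 99.0}
        pre.set_params(intensity_threshold=10.0)
        assert pre.intensity_threshold == 10.0
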