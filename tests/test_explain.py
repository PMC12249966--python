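import numpy as np
import pandas as pd
import pytest

import inflammclock as ic
from inflammclock.bundle import LinearPredictor, MLPPredictor
from inflammclock.explain import ExplainError, _permutation_shapley
from helpers import shapley_enum_oracle


def _linear_clock(markers, coef, intercept=50.0):
    return ic.ClockModel(markers=list(markers),
                         x_mean=np.zeros(len(markers)),
                         x_sd=np.ones(len(markers)),
                         model=LinearPredictor(np.asarray(coef, float),
                                               intercept),
                         backend="elasticnet", params={}, metrics={})


def _frame(arr, markers):
    return pd.DataFrame(np.asarray(arr, float),
                        index=[f"S{i}" for i in range(len(arr))],
                        columns=markers)


class TestLinearClosedForm:
    def test_contributions_equal_w_times_centred_x(self):
        markers = ["A", "B", "C"]
        clock = _linear_clock(markers, [2.0, -1.0, 0.5])
        rng = np.random.default_rng(0)
        est = _frame(rng.normal(size=(20, 3)), markers)
        bg = _frame(rng.normal(size=(50, 3)), markers)
        attrs = ic.attribute(clock, est, bg)
        expected = (est.to_numpy() - bg.to_numpy().mean(axis=0)) \
            * np.array([2.0, -1.0, 0.5])
        np.testing.assert_allclose(attrs.contributions.to_numpy(), expected,
                                   atol=1e-9)
        assert (attrs.local_accuracy_error() <= 1e-6).all()

    def test_background_mean_sample_gets_zero(self):
        markers = ["A", "B"]
        clock = _linear_clock(markers, [3.0, 4.0])
        bg = _frame([[1.0, 2.0], [3.0, 4.0]], markers)
        est = _frame([[2.0, 3.0]], markers)  # exactly the background mean
        attrs = ic.attribute(clock, est, bg)
        np.testing.assert_allclose(attrs.contributions.to_numpy(), 0,
                                   atol=1e-12)
        assert attrs.predictions.iloc[0] == pytest.approx(attrs.base)

    def test_intercept_only_clock_all_zero(self):
        markers = ["A", "B"]
        clock = _linear_clock(markers, [0.0, 0.0], intercept=42.0)
        rng = np.random.default_rng(1)
        est = _frame(rng.normal(size=(5, 2)), markers)
        attrs = ic.attribute(clock, est, est)
        np.testing.assert_allclose(attrs.contributions.to_numpy(), 0,
                                   atol=1e-12)

    def test_empty_background_errors(self):
        markers = ["A", "B"]
        clock = _linear_clock(markers, [1.0, 1.0])
        est = _frame([[0.0, 0.0]], markers)
        with pytest.raises(ExplainError, match="background"):
            ic.attribute(clock, est, est.iloc[:0])


class TestPermutationEstimator:
    @staticmethod
    def _mlp_predict():
        rng = np.random.default_rng(2)
        W1, b1 = rng.normal(size=(3, 8)), rng.normal(size=8)
        W2, b2 = rng.normal(size=(8, 1)), rng.normal(size=1)
        return MLPPredictor(weights=[W1, W2], biases=[b1, b2])

    def test_matches_exact_enumeration(self):
        model = self._mlp_predict()
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4, 3))
        B = rng.normal(size=(4, 3))
        got = _permutation_shapley(model, X, B, n_permutations=4000,
                                   rng=np.random.default_rng(0))
        for i in range(len(X)):
            exact = shapley_enum_oracle(model.predict, X[i], B)
            np.testing.assert_allclose(got[i], exact, atol=0.15)

    def test_telescoping_local_accuracy(self):
        model = self._mlp_predict()
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        B = rng.normal(size=(5, 3))
        contrib = _permutation_shapley(model, X, B, n_permutations=100,
                                       rng=np.random.default_rng(1))
        # sums telescope to f(x) - mean_b f(b) regardless of permutation count
        expected = model.predict(X) - model.predict(B).mean()
        np.testing.assert_allclose(contrib.sum(axis=1), expected, atol=1e-9)

    def test_symmetry_of_identical_markers(self):
        # a model symmetric in its two inputs must credit them equally
        model = LinearPredictor(np.array([1.5, 1.5]), 0.0)
        clock = _linear_clock(["A", "B"], [1.5, 1.5])
        rng = np.random.default_rng(5)
        col = rng.normal(size=30)
        est = _frame(np.column_stack([col, col]), ["A", "B"])
        attrs = ic.attribute(clock, est, est)
        np.testing.assert_allclose(attrs.contributions["A"],
                                   attrs.contributions["B"], atol=1e-9)

    def test_ignored_marker_gets_zero(self):
        clock = _linear_clock(["A", "B"], [2.0, 0.0])
        rng = np.random.default_rng(6)
        est = _frame(rng.normal(size=(10, 2)), ["A", "B"])
        attrs = ic.attribute(clock, est, est)
        np.testing.assert_allclose(attrs.contributions["B"], 0, atol=1e-12)


class TestGlobalImportance:
    def test_dominant_coefficient_ranks_first(self):
        clock = _linear_clock(["A", "B", "C"], [0.1, 5.0, 0.2])
        rng = np.random.default_rng(7)
        est = _frame(rng.normal(size=(40, 3)), ["A", "B", "C"])
        attrs = ic.attribute(clock, est, est)
        ranked = ic.global_importance(attrs)
        assert ranked["marker"].iloc[0] == "B"

    def test_all_zero_ties_resolve_lexicographically(self):
        clock = _linear_clock(["B", "A"], [0.0, 0.0])
        est = _frame(np.zeros((3, 2)), ["B", "A"])
        attrs = ic.attribute(clock, est, est)
        assert ic.global_importance(attrs)["marker"].tolist() == ["A", "B"]


class TestSimilarAgePercentile:
    @staticmethod
    def _cohort(levels, ages):
        ids = [f"S{i}" for i in range(len(levels))]
        est = pd.DataFrame({"M": levels}, index=ids)
        meta = pd.DataFrame({"Age": ages}, index=ids)
        return est, meta

    def test_window_minimum_is_zero_percent(self):
        est, meta = self._cohort([1.0, 2.0, 3.0, 4.0], [50, 51, 52, 53])
        assert ic.similar_age_percentile("S0", "M", est, meta) == 0.0

    def test_three_of_four_lower(self):
        est, meta = self._cohort([3.5, 1, 2, 3, 4], [50, 50, 51, 52, 53])
        assert ic.similar_age_percentile("S0", "M", est, meta) == 75.0

    def test_median_with_tie_counts_half(self):
        est, meta = self._cohort([2.0, 1.0, 2.0, 3.0], [50, 50, 50, 50])
        assert ic.similar_age_percentile("S0", "M", est, meta) == 50.0

    def test_window_widened_once(self):
        est, meta = self._cohort([5.0, 1.0], [50, 58])  # 8 > 5, <= 10
        assert ic.similar_age_percentile("S0", "M", est, meta,
                                         window=5.0) == 100.0

    def test_empty_even_after_widening_errors(self):
        est, meta = self._cohort([5.0, 1.0], [50, 90])
        with pytest.raises(ExplainError, match="within"):
            ic.similar_age_percentile("S0", "M", est, meta, window=5.0)


class TestContributionDelta:
    @staticmethod
    def _attrs_meta(case_shift):
        markers = ["A", "B"]
        n = 40
        rng = np.random.default_rng(8)
        contrib = rng.normal(size=(n, 2))
        status = np.array(["control"] * (n // 2) + ["case"] * (n // 2))
        contrib[status == "case", 0] += case_shift
        ids = [f"S{i}" for i in range(n)]
        attrs = ic.AttributionTable(
            contributions=pd.DataFrame(contrib, index=ids, columns=markers),
            base=50.0, predictions=pd.Series(np.zeros(n), index=ids),
            settings=ic.ShapSettings())
        meta = pd.DataFrame({
            "Age": 50.0, "DatasetID": "D1", "Status": status,
            "ICDChapter": np.where(status == "case", 1, np.nan),
        }, index=ids)
        return attrs, meta

    def test_constructed_shift_recovered(self):
        attrs, meta = self._attrs_meta(2.0)
        base_attrs, _ = self._attrs_meta(0.0)
        delta = ic.contribution_delta(attrs, meta)
        base = ic.contribution_delta(base_attrs, meta)
        assert (delta.loc[1, "A"] - base.loc[1, "A"]) == pytest.approx(2.0)
        assert delta.loc[1, "B"] == pytest.approx(base.loc[1, "B"])

    def test_label_swap_negates(self):
        attrs, meta = self._attrs_meta(1.5)
        swapped = meta.copy()
        swapped["Status"] = np.where(meta["Status"] == "case", "control",
                                     "case")
        swapped["ICDChapter"] = np.where(swapped["Status"] == "case", 1,
                                         np.nan)
        d1 = ic.contribution_delta(attrs, meta)
        d2 = ic.contribution_delta(attrs, swapped)
        np.testing.assert_allclose(d1.to_numpy(), -d2.to_numpy(), atol=1e-12)
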