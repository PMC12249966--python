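import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.linear_model import ElasticNet

import inflammclock as ic
from inflammclock.search import SearchBudget, fit_quiet
from inflammclock.surrogate import SurrogateError, _metrics


class TestLogTransform:
    def test_zero_maps_to_zero(self):
        assert ic.log_transform(np.array([0.0]))[0] == 0.0

    def test_e_minus_one_maps_to_one(self):
        assert ic.log_transform(np.array([np.e - 1]))[0] == pytest.approx(1.0)

    @given(hnp.arrays(np.float64, st.integers(1, 20),
                      elements=st.floats(0, 1e6)))
    @settings(max_examples=30, deadline=None)
    def test_round_trip_identity(self, levels):
        back = ic.inverse_transform(ic.log_transform(levels))
        np.testing.assert_allclose(back, levels, rtol=1e-12, atol=1e-12)

    def test_below_offset_errors(self):
        with pytest.raises(SurrogateError):
            ic.log_transform(np.array([-1.0]))


class TestSplits:
    def test_ten_samples_split_eight_two(self):
        tv, te = ic.split_cohort([f"S{i}" for i in range(10)], seed=1)
        assert (len(tv), len(te)) == (8, 2)

    def test_same_seed_identical(self):
        ids = [f"S{i}" for i in range(57)]
        assert ic.split_cohort(ids, seed=9) == ic.split_cohort(ids, seed=9)

    def test_partition(self):
        ids = [f"S{i}" for i in range(100)]
        tv, te = ic.split_cohort(ids, seed=2)
        assert sorted(tv + te) == sorted(ids)
        assert not set(tv) & set(te)

    def test_cv_folds_partition_and_ratio(self):
        folds = ic.cv_folds([f"S{i}" for i in range(8)], seed=0)
        counts = np.bincount(folds, minlength=4)
        assert counts.tolist() == [2, 2, 2, 2]
        # each fold trains on 6 = 3x its 2 validation samples
        for f in range(4):
            assert (folds != f).sum() == 3 * (folds == f).sum()


def _linear_cohort(n=300, p=8, noise=0.01, seed=0):
    rng = np.random.default_rng(seed)
    beta = pd.DataFrame(rng.uniform(size=(n, p)),
                        index=[f"S{i}" for i in range(n)],
                        columns=[f"cg{j}" for j in range(p)])
    y_log = 1.0 + 2.0 * beta["cg0"] + 1.0 * beta["cg1"] - 1.5 * beta["cg2"] \
        + noise * rng.normal(size=n)
    levels = np.expm1(np.clip(y_log, 0, None))
    return beta, pd.Series(levels, index=beta.index)


class TestTuneAndTrain:
    def test_linear_target_recovered(self):
        beta, levels = _linear_cohort()
        s = ic.tune_and_train(beta, levels, list(beta.columns), "M",
                              budget=SearchBudget(trials=12,
                                                  startup_trials=4),
                              seed=0)
        assert s.test_r >= 0.99

    def test_noise_target_near_null_correlation(self):
        rng = np.random.default_rng(11)
        beta = pd.DataFrame(rng.uniform(size=(200, 6)),
                            index=[f"S{i}" for i in range(200)],
                            columns=[f"cg{j}" for j in range(6)])
        levels = pd.Series(np.exp(rng.normal(size=200)), index=beta.index)
        s = ic.tune_and_train(beta, levels, list(beta.columns), "M",
                              budget=SearchBudget(trials=8, startup_trials=4),
                              seed=1)
        assert abs(s.test_r) < 2 / np.sqrt(40)

    def test_minimal_budget_is_valid(self):
        beta, levels = _linear_cohort(n=60)
        s = ic.tune_and_train(beta, levels, list(beta.columns), "M",
                              budget=SearchBudget(trials=1, startup_trials=1),
                              seed=0)
        assert set(s.metrics) == {"train", "val", "test"}
        assert np.isfinite(s.metrics["val"]["mae"])

    def test_training_metrics_reproduce_on_reapply(self):
        beta, levels = _linear_cohort(n=80)
        s = ic.tune_and_train(beta, levels, list(beta.columns), "M",
                              budget=SearchBudget(trials=4, startup_trials=2),
                              seed=3)
        tv, _ = ic.split_cohort(list(beta.index), seed=3)
        pred = s.predict(beta.loc[tv])
        redone = _metrics(ic.log_transform(levels.loc[tv].to_numpy()), pred)
        assert redone["mae"] == pytest.approx(s.metrics["train"]["mae"],
                                              abs=1e-9)
        assert redone["pearson_r"] == pytest.approx(
            s.metrics["train"]["pearson_r"], abs=1e-9)

    def test_elasticnet_refit_matches_direct_coordinate_descent(self):
        """The stored backend at its chosen hyperparameters must equal an
        independently constructed ElasticNet fit on the same standardised
        design, coefficient for coefficient."""
        beta, levels = _linear_cohort(n=100)
        s = ic.tune_and_train(beta, levels, list(beta.columns), "M",
                              budget=SearchBudget(trials=4, startup_trials=2),
                              seed=5)
        tv, _ = ic.split_cohort(list(beta.index), seed=5)
        Z = (beta.loc[tv].to_numpy() - s.x_mean) / s.x_sd
        y = ic.log_transform(levels.loc[tv].to_numpy())
        direct = ElasticNet(alpha=s.params["alpha"],
                            l1_ratio=s.params["l1_ratio"],
                            max_iter=3000, tol=1e-5, random_state=5)
        fit_quiet(direct, Z, y)
        np.testing.assert_allclose(direct.coef_, s.model.coef_, atol=1e-6)

    def test_ridge_limit_matches_closed_form(self):
        """With l1_ratio=0 the penalised fit has the analytic ridge solution
        w = (Z'Z/n + alpha I)^(-1) Z'y / n on centred data."""
        rng = np.random.default_rng(6)
        n, p = 120, 5
        Z = rng.normal(size=(n, p))
        y = Z @ rng.normal(size=p) + 0.1 * rng.normal(size=n)
        alpha = 0.3
        est = ElasticNet(alpha=alpha, l1_ratio=0.0, max_iter=50000, tol=1e-12)
        fit_quiet(est, Z, y)
        Zc = Z - Z.mean(axis=0)
        yc = y - y.mean()
        w = np.linalg.solve(Zc.T @ Zc / n + alpha * np.eye(p), Zc.T @ yc / n)
        np.testing.assert_allclose(est.coef_, w, atol=1e-5)


class TestGate:
    @staticmethod
    def _fake(marker, r):
        s = ic.TrainedSurrogate(marker=marker, cpgs=["cg0"],
                                x_mean=np.zeros(1), x_sd=np.ones(1),
                                model=None, backend="elasticnet", params={},
                                metrics={"test": {"mae": 0.1, "pearson_r": r}})
        return s

    def test_reported_panel_thresholding(self):
        surr = {"CCL9": self._fake("CCL9", 0.78),
                "CCL3": self._fake("CCL3", 0.37)}
        rep = ic.gate_markers(surr, threshold=0.5)
        assert rep.retained == ["CCL9"]
        assert rep.table.set_index("marker").loc["CCL3", "retained"] == False  # noqa: E712

    def test_boundary_value_is_retained(self):
        rep = ic.gate_markers({"M": self._fake("M", 0.5)}, threshold=0.5)
        assert rep.retained == ["M"]

    def test_zero_threshold_vacuous(self):
        surr = {m: self._fake(m, r) for m, r in
                [("A", 0.0), ("B", 0.9), ("C", 0.2)]}
        assert ic.gate_markers(surr, threshold=0.0).retained == ["A", "B", "C"]

    def test_no_marker_retained_errors(self):
        with pytest.raises(SurrogateError, match="threshold"):
            ic.gate_markers({"M": self._fake("M", 0.1)}, threshold=0.5)


class TestPredictMarkers:
    def test_rowwise_and_missing_cpg_error(self):
        beta, levels = _linear_cohort(n=60)
        s = ic.tune_and_train(beta, levels, list(beta.columns), "M",
                              budget=SearchBudget(trials=2, startup_trials=2),
                              seed=0)
        est = ic.predict_markers(beta, {"M": s})
        assert est.shape == (60, 1)
        # duplicated sample row -> duplicated estimate row
        dup = pd.concat([beta.iloc[[0]], beta])
        est_dup = ic.predict_markers(dup, {"M": s})
        assert est_dup.iloc[0, 0] == est_dup.iloc[1, 0]
        with pytest.raises(SurrogateError, match="cg0"):
            ic.predict_markers(beta.drop(columns=["cg0"]), {"M": s})
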