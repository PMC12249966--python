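"""Level 2: the age clock trained on retained surrogate marker estimates.

Chronological age (years, untransformed) is regressed on the log-scale
synthetic marker levels produced by the gated level-1 surrogates. Splitting
respects dataset structure: within each dataset, samples are divided into
five empirical age quintiles; if every quintile holds at least five samples
the dataset is split 80/20 (train+validation / test) stratified by
quintile, otherwise the entire dataset is assigned to the test pool and
contributes no training samples. Hyperparameters use the same budgeted
search and 4-fold cross-validation as level 1.

Age acceleration is defined sample-wise as predicted minus chronological
age; a group's *bias* is its mean signed acceleration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import AGE, SAMPLE_ID
from .search import (BackendSpec, SearchBudget, fit_quiet, make_estimator,
                     run_search)
from .surrogate import _metrics

N_QUINTILES = 5
MIN_PER_QUINTILE = 5


class ClockError(ValueError):
    pass


# ---------------------------------------------------------------------------
# age-stratified split plan
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Per-sample subset assignment plus per-dataset disposition.

    ``assignments``: DataFrame indexed by sample ID with columns ``subset``
    ("trainval" | "test") and ``cv_fold`` (0..3 within trainval, -1 in test).
    ``dispositions``: dataset -> "stratified" | "all-test".
    ``edges``: dataset -> quintile boundaries (for stratified datasets).
    """

    assignments: pd.DataFrame
    dispositions: dict[str, str]
    edges: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def trainval_ids(self) -> list[str]:
        a = self.assignments
        return a.index[a["subset"] == "trainval"].tolist()

    @property
    def test_ids(self) -> list[str]:
        a = self.assignments
        return a.index[a["subset"] == "test"].tolist()


def _quintile_groups(ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical quintile edges (interior) and per-sample group index.

    Samples exactly on an edge fall in the lower group."""
    edges = np.quantile(ages, [0.2, 0.4, 0.6, 0.8])
    groups = np.searchsorted(edges, ages, side="left")
    return edges, groups


def age_stratified_split(meta: pd.DataFrame, seed: int = 0,
                         test_fraction: float = 0.2,
                         n_folds: int = 4) -> SplitPlan:
    """Build the per-dataset quintile-stratified split plan."""
    if len(meta) == 0:
        raise ClockError("empty cohort")
    if "DatasetID" not in meta.columns:
        meta = meta.assign(DatasetID="dataset0")
    rng = np.random.default_rng(seed)

    rows: list[tuple[str, str, int]] = []
    dispositions: dict[str, str] = {}
    edge_map: dict[str, np.ndarray] = {}
    for ds in sorted(meta["DatasetID"].astype(str).unique()):
        sub = meta[meta["DatasetID"].astype(str) == ds]
        ids = np.array(sub.index)
        ages = sub[AGE].to_numpy(dtype=float)
        edges, groups = _quintile_groups(ages)
        counts = np.bincount(groups, minlength=N_QUINTILES)
        if (counts < MIN_PER_QUINTILE).any():
            dispositions[ds] = "all-test"
            rows += [(s, "test", -1) for s in ids]
            continue
        dispositions[ds] = "stratified"
        edge_map[ds] = edges
        for g in range(N_QUINTILES):
            gids = ids[groups == g]
            perm = rng.permutation(len(gids))
            n_test = int(round(len(gids) * test_fraction))
            test_set = set(perm[:n_test].tolist())
            tv = [gids[i] for i in range(len(gids)) if i not in test_set]
            rows += [(gids[i], "test", -1) for i in sorted(test_set)]
            # round-robin CV folds inside the shuffled trainval part
            tv_perm = rng.permutation(len(tv))
            for j, i in enumerate(tv_perm):
                rows.append((tv[i], "trainval", j % n_folds))
    assignments = pd.DataFrame(rows, columns=[SAMPLE_ID, "subset", "cv_fold"]
                               ).set_index(SAMPLE_ID).loc[meta.index]
    return SplitPlan(assignments=assignments, dispositions=dispositions,
                     edges=edge_map)


# ---------------------------------------------------------------------------
# clock model
# ---------------------------------------------------------------------------


@dataclass
class ClockModel:
    """Fitted level-2 age model over the retained marker estimates."""

    markers: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    model: object
    backend: str
    params: dict
    metrics: dict[str, dict[str, float]]
    seed: int = 0

    def _design(self, estimates: pd.DataFrame) -> np.ndarray:
        missing = [m for m in self.markers if m not in estimates.columns]
        if missing:
            raise ClockError(f"estimate matrix lacks marker column(s): {missing}")
        X = estimates[self.markers].to_numpy(dtype=float)
        return (X - self.x_mean) / self.x_sd

    def predict(self, estimates: pd.DataFrame) -> np.ndarray:
        """Predicted age in years, one value per estimate row."""
        return np.asarray(self.model.predict(self._design(estimates)),
                          dtype=float)


def train_clock(estimates: pd.DataFrame, meta: pd.DataFrame, plan: SplitPlan,
                spec: BackendSpec | None = None,
                budget: SearchBudget | None = None,
                seed: int = 0) -> ClockModel:
    """Tune and fit the age clock on the plan's train+validation samples."""
    spec = spec or BackendSpec.elasticnet()
    budget = budget or SearchBudget()
    markers = sorted(estimates.columns.astype(str))
    if len(markers) < 2:
        raise ClockError("need at least 2 retained markers to train a clock")
    missing = [s for s in plan.assignments.index if s not in estimates.index]
    if missing:
        raise ClockError(f"estimates missing for {len(missing)} planned samples")
    tv_ids = plan.trainval_ids
    if not tv_ids:
        raise ClockError("split plan has no training samples (all-test cohort)")

    X_tv = estimates.loc[tv_ids, markers].to_numpy(dtype=float)
    y_tv = meta.loc[tv_ids, AGE].to_numpy(dtype=float)
    folds = plan.assignments.loc[tv_ids, "cv_fold"].to_numpy()
    x_mean = X_tv.mean(axis=0)
    x_sd = X_tv.std(axis=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Z_tv = (X_tv - x_mean) / x_sd
    n_folds = int(folds.max()) + 1

    def objective(params: dict) -> float:
        maes = []
        for f in range(n_folds):
            val = folds == f
            est = make_estimator(spec, params, seed)
            fit_quiet(est, Z_tv[~val], y_tv[~val])
            maes.append(np.mean(np.abs(y_tv[val] - est.predict(Z_tv[val]))))
        return float(np.mean(maes))

    best, _ = run_search(objective, spec.space, budget, seed)

    oof = np.empty_like(y_tv)
    for f in range(n_folds):
        val = folds == f
        est = make_estimator(spec, best, seed)
        fit_quiet(est, Z_tv[~val], y_tv[~val])
        oof[val] = est.predict(Z_tv[val])

    model = make_estimator(spec, best, seed)
    fit_quiet(model, Z_tv, y_tv)
    clock = ClockModel(markers=markers, x_mean=x_mean, x_sd=x_sd,
                       model=model, backend=spec.kind, params=best,
                       metrics={}, seed=seed)
    test_ids = plan.test_ids
    metrics = {
        "train": _metrics(y_tv, clock.predict(estimates.loc[tv_ids])),
        "val": _metrics(y_tv, oof),
    }
    if test_ids:
        y_test = meta.loc[test_ids, AGE].to_numpy(dtype=float)
        metrics["test"] = _metrics(y_test, clock.predict(estimates.loc[test_ids]))
    clock.metrics = metrics
    return clock


# ---------------------------------------------------------------------------
# predictions and cohort metrics
# ---------------------------------------------------------------------------


def predict_age(estimates: pd.DataFrame, clock: ClockModel,
                meta: pd.DataFrame) -> pd.DataFrame:
    """Prediction table: SampleID, Age, PredictedAge, AgeAcceleration.

    Age acceleration is exactly predicted minus chronological age."""
    ids = estimates.index
    pred = clock.predict(estimates)
    ages = meta.loc[ids, AGE].to_numpy(dtype=float)
    out = pd.DataFrame({
        AGE: ages,
        "PredictedAge": pred,
        "AgeAcceleration": pred - ages,
    }, index=ids)
    out.index.name = SAMPLE_ID
    return out


def cohort_metrics(pred: pd.DataFrame, by: str | pd.Series | None = None
                   ) -> pd.DataFrame:
    """MAE (years), Pearson r, and bias (mean signed acceleration) per group.

    With ``by=None`` a single row ``all`` is returned. Groups with constant
    chronological age get ``r = NaN`` with a warning."""
    if by is None:
        groups = pd.Series("all", index=pred.index)
    elif isinstance(by, str):
        groups = pred[by].astype(str)
    else:
        groups = pd.Series(by, index=pred.index).astype(str)
    rows = []
    for g in sorted(groups.unique()):
        sub = pred[groups == g]
        acc = sub["AgeAcceleration"].to_numpy(dtype=float)
        age = sub[AGE].to_numpy(dtype=float)
        predicted = sub["PredictedAge"].to_numpy(dtype=float)
        mae = float(np.mean(np.abs(acc)))
        bias = float(np.mean(acc))
        if len(sub) >= 2 and np.std(age) > 0 and np.std(predicted) > 0:
            r = float(stats.pearsonr(age, predicted)[0])
        else:
            warnings.warn(
                f"group {g!r}: Pearson r undefined (constant ages or "
                "predictions); reported as NaN")
            r = float("nan")
        rows.append((g, len(sub), mae, r, bias))
    return pd.DataFrame(rows, columns=["group", "n", "mae_years",
                                       "pearson_r", "bias_years"]
                        ).set_index("group")
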