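"""Level 1: per-marker surrogate regressors from methylation to log cytokine
levels, with train/validation/test evaluation and correlation gating.

Each inflammatory marker gets its own regressor trained on its mRMR-selected
CpG set. Targets are log-transformed (``ln(level + 1)`` with levels in
pg/mL) to tame the heavy right tail of cytokine panels; predictions can be
mapped back with the exact inverse. The cohort is split 80/20 into
train+validation and a held-out test subset; hyperparameters are chosen by
4-fold cross-validation (3:1 train:validation) minimising mean validation
MAE on the log scale, then refit on the full train+validation split.

A marker enters the level-2 age clock only if its surrogate reaches a
held-out (test) Pearson correlation of at least the gating threshold,
0.5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .search import (BackendSpec, SearchBudget, fit_quiet, make_estimator,
                     run_search)


class SurrogateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# target transform
# ---------------------------------------------------------------------------

LOG_OFFSET = 1.0  # pg/mL


def log_transform(levels: np.ndarray) -> np.ndarray:
    """``y = ln(level + 1)``; defined for levels > -1 pg/mL."""
    levels = np.asarray(levels, dtype=float)
    if np.any(levels[~np.isnan(levels)] <= -LOG_OFFSET):
        raise SurrogateError("marker level <= -1 pg/mL cannot be log-transformed")
    return np.log1p(levels)


def inverse_transform(y: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`log_transform`: ``level = exp(y) - 1``."""
    return np.expm1(np.asarray(y, dtype=float))


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def split_cohort(sample_ids, test_fraction: float = 0.2, seed: int = 0
                 ) -> tuple[list, list]:
    """Deterministic 80/20 partition into (trainval, test) given a seed."""
    ids = list(sample_ids)
    if len(ids) < 5:
        raise SurrogateError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = int(round(len(ids) * test_fraction))
    test_idx = set(perm[:n_test].tolist())
    trainval = [ids[i] for i in range(len(ids)) if i not in test_idx]
    test = [ids[i] for i in sorted(test_idx)]
    return trainval, test


def cv_folds(sample_ids, n_folds: int = 4, seed: int = 0) -> np.ndarray:
    """Assign each sample a validation-fold index 0..n_folds-1 (3:1 split)."""
    ids = list(sample_ids)
    if len(ids) < n_folds:
        raise SurrogateError(f"need at least {n_folds} samples for {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.empty(len(ids), dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        folds[chunk] = f
    return folds


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    mae = float(np.mean(np.abs(y_true - y_pred)))
    if len(y_true) >= 2 and np.std(y_true) > 0 and np.std(y_pred) > 0:
        r = float(stats.pearsonr(y_true, y_pred)[0])
    else:
        r = float("nan")
    return {"mae": mae, "pearson_r": r}


# ---------------------------------------------------------------------------
# trained surrogate
# ---------------------------------------------------------------------------


@dataclass
class TrainedSurrogate:
    """One marker's fitted surrogate: CpG list, frozen standardisation,
    regressor, and per-subset metrics (MAE and Pearson r on the log scale)."""

    marker: str
    cpgs: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    model: object
    backend: str
    params: dict
    metrics: dict[str, dict[str, float]]
    transform: str = "log1p"
    seed: int = 0

    def _design(self, beta: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.cpgs if c not in beta.columns]
        if missing:
            raise SurrogateError(
                f"{self.marker}: input lacks {len(missing)} required CpG(s): "
                f"{missing[:10]}"
            )
        X = beta[self.cpgs].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise SurrogateError(
                f"{self.marker}: missing beta values in input; impute first")
        return (X - self.x_mean) / self.x_sd

    def predict(self, beta: pd.DataFrame) -> np.ndarray:
        """Log-scale marker estimates for each row of ``beta``."""
        return np.asarray(self.model.predict(self._design(beta)), dtype=float)

    @property
    def test_r(self) -> float:
        return self.metrics["test"]["pearson_r"]


def tune_and_train(beta: pd.DataFrame, levels: pd.Series | np.ndarray,
                   cpgs: list[str], marker: str,
                   spec: BackendSpec | None = None,
                   budget: SearchBudget | None = None,
                   seed: int = 0,
                   split: tuple[list, list] | None = None) -> TrainedSurrogate:
    """Budgeted hyperparameter search + refit for one marker.

    ``levels`` are raw pg/mL (NaN rows dropped); the model is fitted on
    ``ln(level+1)``. Per-trial score is the mean validation MAE over the
    4 cross-validation folds; the best configuration is refit on the full
    train+validation split and evaluated on the held-out test subset.
    ``split`` fixes a pre-computed (trainval, test) partition so the same
    held-out samples can be shared across markers (and kept out of feature
    selection); by default a fresh 80/20 split is drawn from ``seed``.
    """
    spec = spec or BackendSpec.elasticnet()
    budget = budget or SearchBudget()
    levels = pd.Series(np.asarray(levels, dtype=float), index=beta.index)
    ok = levels.notna()
    beta = beta.loc[ok]
    y_all = log_transform(levels[ok].to_numpy())
    ids = list(beta.index)

    if split is None:
        trainval, test = split_cohort(ids, seed=seed)
    else:
        present = set(ids)
        trainval = [s for s in split[0] if s in present]
        test = [s for s in split[1] if s in present]
        if len(trainval) < 5 or not test:
            raise SurrogateError(f"{marker}: provided split leaves too few "
                                 "samples after dropping missing levels")
    folds = cv_folds(trainval, seed=seed)

    X_tv = beta.loc[trainval, cpgs].to_numpy(dtype=float)
    if np.isnan(X_tv).any():
        raise SurrogateError(f"{marker}: missing beta values; impute first")
    x_mean = X_tv.mean(axis=0)
    x_sd = X_tv.std(axis=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Z_tv = (X_tv - x_mean) / x_sd
    pos = {s: i for i, s in enumerate(ids)}
    y_tv = y_all[[pos[s] for s in trainval]]

    def objective(params: dict) -> float:
        maes = []
        for f in range(4):
            val = folds == f
            est = make_estimator(spec, params, seed)
            fit_quiet(est, Z_tv[~val], y_tv[~val])
            maes.append(np.mean(np.abs(y_tv[val] - est.predict(Z_tv[val]))))
        return float(np.mean(maes))

    best, history = run_search(objective, spec.space, budget, seed)

    # out-of-fold validation metrics at the chosen configuration
    oof = np.empty_like(y_tv)
    for f in range(4):
        val = folds == f
        est = make_estimator(spec, best, seed)
        fit_quiet(est, Z_tv[~val], y_tv[~val])
        oof[val] = est.predict(Z_tv[val])
    val_metrics = _metrics(y_tv, oof)

    model = make_estimator(spec, best, seed)
    fit_quiet(model, Z_tv, y_tv)

    surr = TrainedSurrogate(
        marker=marker, cpgs=list(cpgs), x_mean=x_mean, x_sd=x_sd,
        model=model, backend=spec.kind, params=best,
        metrics={}, seed=seed,
    )
    y_test = y_all[[pos[s] for s in test]]
    surr.metrics = {
        "train": _metrics(y_tv, surr.predict(beta.loc[trainval])),
        "val": val_metrics,
        "test": _metrics(y_test, surr.predict(beta.loc[test])),
    }
    for sub, m in surr.metrics.items():
        if not np.isfinite(m["mae"]):
            raise SurrogateError(f"{marker}: non-finite {sub} MAE")
    return surr


# ---------------------------------------------------------------------------
# gating and panel prediction
# ---------------------------------------------------------------------------


@dataclass
class GateReport:
    """Per-marker held-out correlation and the retain/exclude decision."""

    table: pd.DataFrame  # columns: marker, test_r, retained
    threshold: float

    @property
    def retained(self) -> list[str]:
        return self.table.loc[self.table["retained"], "marker"].tolist()


def gate_markers(surrogates: dict[str, TrainedSurrogate],
                 threshold: float = 0.5) -> GateReport:
    """Retain markers whose surrogate test Pearson r >= ``threshold``."""
    rows = [(m, s.test_r, bool(s.test_r >= threshold))
            for m, s in sorted(surrogates.items())]
    table = pd.DataFrame(rows, columns=["marker", "test_r", "retained"])
    if not table["retained"].any():
        raise SurrogateError(
            f"no marker reached test r >= {threshold}; review the gating "
            "threshold or the level-1 training data"
        )
    return GateReport(table=table, threshold=threshold)


def predict_markers(beta: pd.DataFrame,
                    surrogates: dict[str, TrainedSurrogate],
                    markers: list[str] | None = None) -> pd.DataFrame:
    """Log-scale estimate matrix (samples x markers) from retained surrogates."""
    markers = sorted(surrogates) if markers is None else list(markers)
    missing_cpgs: list[str] = []
    for m in markers:
        missing_cpgs += [c for c in surrogates[m].cpgs
                         if c not in beta.columns]
    if missing_cpgs:
        uniq = sorted(set(missing_cpgs))
        raise SurrogateError(
            f"input beta matrix lacks {len(uniq)} required CpG probe(s): "
            f"{uniq[:10]}"
        )
    est = {m: surrogates[m].predict(beta) for m in markers}
    return pd.DataFrame(est, index=beta.index)[markers]
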