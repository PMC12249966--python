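"""Shapley-value attribution of clock predictions to individual markers.

Each prediction is decomposed as ``base + sum_j contribution_j`` where
``base`` is the mean prediction over a background cohort and the
contributions (in years) are Shapley values of the markers. For linear
backends the Shapley value has the closed form
``w_j (x_j - mean background x_j)`` and is computed exactly. For arbitrary
backends a permutation-sampling estimator is used: marker values enter in a
random order, absent coalition members take their values from a background
row, and a marker's contribution is the mean prediction change when it
enters. Background rows are cycled deterministically so that the per-sample
telescoping identity — contributions summing to prediction minus mean
background prediction — holds up to floating-point error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clock import ClockModel
from .cohort_io import AGE


class ExplainError(ValueError):
    pass


@dataclass
class ShapSettings:
    n_permutations: int = 2048
    background_size: int = 256
    seed: int = 0


@dataclass
class AttributionTable:
    """Per-sample marker contributions (years) plus the shared base value."""

    contributions: pd.DataFrame  # samples x markers, years
    base: float
    predictions: pd.Series
    settings: ShapSettings

    def local_accuracy_error(self) -> pd.Series:
        """|base + sum(contributions) - prediction| per sample."""
        total = self.base + self.contributions.sum(axis=1)
        return (total - self.predictions).abs()


def _linear_weights(clock: ClockModel) -> np.ndarray | None:
    model = clock.model
    coef = getattr(model, "coef_", None)
    if coef is None:
        return None
    return np.asarray(coef, dtype=float).ravel()


def attribute(clock: ClockModel, estimates: pd.DataFrame,
              background: pd.DataFrame,
              settings: ShapSettings | None = None) -> AttributionTable:
    """Shapley contributions of each marker for each row of ``estimates``.

    Closed form for linear backends; permutation sampling otherwise."""
    settings = settings or ShapSettings()
    if len(background) == 0:
        raise ExplainError("background cohort is empty")
    X = clock._design(estimates)
    B = clock._design(background)
    rng = np.random.default_rng(settings.seed)
    if len(B) > settings.background_size:
        idx = rng.choice(len(B), size=settings.background_size, replace=False)
        B = B[np.sort(idx)]
    base = float(np.mean(clock.model.predict(B)))
    pred = np.asarray(clock.model.predict(X), dtype=float)
    d = len(clock.markers)

    w = _linear_weights(clock)
    if w is not None:
        contrib = (X - B.mean(axis=0)) * w
    else:
        contrib = _permutation_shapley(clock.model, X, B,
                                       settings.n_permutations, rng)
    table = pd.DataFrame(contrib, index=estimates.index,
                         columns=clock.markers)
    return AttributionTable(contributions=table, base=base,
                            predictions=pd.Series(pred, index=estimates.index),
                            settings=settings)


def _permutation_shapley(model, X: np.ndarray, B: np.ndarray,
                         n_permutations: int, rng: np.random.Generator
                         ) -> np.ndarray:
    """Monte-Carlo Shapley values by sampled feature orderings.

    Background rows are cycled so every row is used equally often, which
    makes the contribution sum telescope exactly to
    ``f(x) - mean_b f(b)`` per sample."""
    n, d = X.shape
    n_bg = len(B)
    # use a multiple of the background size so the cycle closes
    P = max(n_bg, (n_permutations // n_bg) * n_bg)
    bg_idx = np.tile(np.arange(n_bg), P // n_bg)
    contrib = np.zeros((n, d))
    for p in range(P):
        order = rng.permutation(d)
        b = B[bg_idx[p]]
        # rows[0] = pure background, rows[k] = first k features from x
        coalition = np.tile(b, (n * (d + 1), 1)).reshape(n, d + 1, d)
        for k, j in enumerate(order):
            coalition[:, k + 1:, j] = X[:, [j]]
        preds = model.predict(coalition.reshape(-1, d)).reshape(n, d + 1)
        deltas = np.diff(preds, axis=1)
        contrib[:, order] += deltas
    return contrib / P


def global_importance(attrs: AttributionTable) -> pd.DataFrame:
    """Markers ranked by mean |contribution| (years), descending; ties by name."""
    mean_abs = attrs.contributions.abs().mean(axis=0)
    df = pd.DataFrame({"marker": mean_abs.index.astype(str),
                       "mean_abs_contribution": mean_abs.to_numpy()})
    df = df.sort_values(["mean_abs_contribution", "marker"],
                        ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def similar_age_percentile(sample_id: str, marker: str,
                           estimates: pd.DataFrame, meta: pd.DataFrame,
                           window: float = 5.0) -> float:
    """Percentage of similar-aged cohort samples with a lower marker level.

    "Similar" means chronological age within ``window`` years of the query
    sample (the query itself excluded). Ties count half. If the window is
    empty it is widened once to twice the span before failing."""
    if sample_id not in estimates.index:
        raise ExplainError(f"unknown sample {sample_id!r}")
    age0 = float(meta.loc[sample_id, AGE])
    level0 = float(estimates.loc[sample_id, marker])
    others = estimates.index[estimates.index != sample_id]
    ages = meta.loc[others, AGE].astype(float)
    for w in (window, 2 * window):
        in_win = others[(ages - age0).abs() <= w]
        if len(in_win):
            levels = estimates.loc[in_win, marker].to_numpy(dtype=float)
            lower = float(np.sum(levels < level0))
            ties = float(np.sum(levels == level0))
            return 100.0 * (lower + 0.5 * ties) / len(levels)
    raise ExplainError(
        f"no cohort samples within ±{2 * window} years of age {age0}")


def contribution_delta(attrs: AttributionTable, meta: pd.DataFrame
                       ) -> pd.DataFrame:
    """Mean case-minus-control Shapley contribution per (ICD chapter, marker).

    Within each dataset, cases of a chapter are compared to that dataset's
    controls; chapters spanning several datasets are aggregated by an
    unweighted mean over datasets. Positive values mean the marker pushes
    predicted age up more in cases than in controls."""
    contrib = attrs.contributions
    meta = meta.loc[contrib.index]
    status = meta["Status"].astype(str)
    deltas: dict[tuple, list[np.ndarray]] = {}
    for ds in sorted(meta["DatasetID"].astype(str).unique()):
        in_ds = meta["DatasetID"].astype(str) == ds
        controls = contrib[in_ds & (status == "control")]
        if len(controls) == 0:
            import warnings
            warnings.warn(f"dataset {ds!r} has no controls; its case groups "
                          "are skipped")
            continue
        cases = meta[in_ds & (status == "case")]
        for chapter in sorted(cases["ICDChapter"].dropna().unique()):
            grp = contrib.loc[cases.index[cases["ICDChapter"] == chapter]]
            if len(grp) == 0:
                continue
            delta = grp.mean(axis=0) - controls.mean(axis=0)
            deltas.setdefault(chapter, []).append(delta.to_numpy())
    if not deltas:
        raise ExplainError("no (chapter, dataset) pair with cases and controls")
    rows = {int(ch): np.mean(np.vstack(v), axis=0) for ch, v in deltas.items()}
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=contrib.columns)
    out.index.name = "ICDChapter"
    return out.sort_index()
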