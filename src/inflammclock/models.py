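"""Model/Results classes tying the pipeline stages together.

The two estimation levels are exposed in the familiar build-then-fit idiom:

>>> panel = SurrogatePanelModel(cohort.beta, cohort.markers, n_cpgs=100)
>>> panel_res = panel.fit(seed=0)
>>> estimates = panel_res.predict(cohort.beta)
>>> clock = InflammAgeModel(estimates, cohort.meta)
>>> clock_res = clock.fit(seed=0)
>>> print(clock_res.summary())

``SurrogatePanelModel`` owns level 1 (per-marker CpG selection, surrogate
regression, correlation gating); ``InflammAgeModel`` owns level 2 (the age
clock over the retained synthetic markers) and hangs prediction tables,
Shapley attributions and the disease battery off its results object. The
clock is fitted on control samples only — evaluating on disease groups then
measures genuine sensitivity, not leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import battery as battery_mod
from . import clock as clock_mod
from . import explain as explain_mod
from .cohort_io import BetaMatrix, validate_meta
from .feature_selection import (SelectionMap, marker_cpg_correlation_map,
                                select_marker_cpgs)
from .search import BackendSpec, SearchBudget
from .surrogate import (GateReport, TrainedSurrogate, gate_markers,
                        log_transform, predict_markers, split_cohort,
                        tune_and_train)


def _as_frame(beta) -> pd.DataFrame:
    return beta.values if isinstance(beta, BetaMatrix) else beta


# ---------------------------------------------------------------------------
# level 1
# ---------------------------------------------------------------------------


class SurrogatePanelModel:
    """Level-1 model: one surrogate regressor per inflammatory marker.

    Parameters
    ----------
    beta : BetaMatrix or DataFrame
        Complete (imputed) methylation matrix, samples x CpGs.
    markers : DataFrame
        Measured marker levels in pg/mL, aligned on sample ID.
    backend : BackendSpec
        Regressor family and search space shared by all markers.
    n_cpgs : int
        mRMR selection size per marker (100 by default).
    threshold : float
        Gating threshold on held-out Pearson r (inclusive).
    """

    def __init__(self, beta, markers: pd.DataFrame,
                 backend: BackendSpec | None = None,
                 n_cpgs: int = 100, threshold: float = 0.5):
        self.beta = _as_frame(beta)
        self.markers = markers.loc[self.beta.index]
        self.backend = backend or BackendSpec.elasticnet()
        self.n_cpgs = int(n_cpgs)
        self.threshold = float(threshold)

    def fit(self, budget: SearchBudget | None = None, seed: int = 0
            ) -> "SurrogatePanelResults":
        budget = budget or SearchBudget()
        k = min(self.n_cpgs, self.beta.shape[1])
        # one shared 80/20 split for all markers; CpG selection sees only the
        # train+validation side so the gate's test r stays leakage-free
        trainval, test = split_cohort(self.beta.index, seed=seed)
        selection = select_marker_cpgs(self.beta.loc[trainval],
                                       self.markers.loc[trainval], k=k,
                                       transform=log_transform)
        surrogates: dict[str, TrainedSurrogate] = {}
        for marker in self.markers.columns:
            surrogates[str(marker)] = tune_and_train(
                self.beta, self.markers[marker], selection.cpgs(str(marker)),
                marker=str(marker), spec=self.backend, budget=budget,
                seed=seed, split=(trainval, test),
            )
        gate = gate_markers(surrogates, threshold=self.threshold)
        return SurrogatePanelResults(model=self, selection=selection,
                                     surrogates=surrogates, gate=gate,
                                     seed=seed)


@dataclass
class SurrogatePanelResults:
    """Fitted surrogates, their per-subset metrics and the gate decisions."""

    model: SurrogatePanelModel
    selection: SelectionMap
    surrogates: dict[str, TrainedSurrogate]
    gate: GateReport
    seed: int = 0

    @property
    def retained(self) -> list[str]:
        return self.gate.retained

    def required_cpgs(self) -> list[str]:
        """Union of retained markers' CpG sets — the input contract of the
        released model."""
        seen: set[str] = set()
        for m in self.retained:
            seen.update(self.surrogates[m].cpgs)
        return sorted(seen)

    def predict(self, beta) -> pd.DataFrame:
        """Log-scale estimate matrix for the retained markers."""
        return predict_markers(_as_frame(beta),
                               {m: self.surrogates[m] for m in self.retained},
                               self.retained)

    def correlation_map(self) -> pd.DataFrame:
        return marker_cpg_correlation_map(self.model.beta, self.model.markers,
                                          self.selection)

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for m in sorted(self.surrogates):
            s = self.surrogates[m]
            rows.append({
                "marker": m,
                "n_cpgs": len(s.cpgs),
                "train_mae": s.metrics["train"]["mae"],
                "train_r": s.metrics["train"]["pearson_r"],
                "val_mae": s.metrics["val"]["mae"],
                "val_r": s.metrics["val"]["pearson_r"],
                "test_mae": s.metrics["test"]["mae"],
                "test_r": s.metrics["test"]["pearson_r"],
                "retained": m in self.retained,
            })
        return pd.DataFrame(rows).set_index("marker")

    def summary(self) -> str:
        t = self.metrics_table()
        lines = [
            "Surrogate inflammatory-marker panel",
            f"  backend: {self.model.backend.kind}   "
            f"CpGs/marker: {self.model.n_cpgs}   "
            f"gate: test r >= {self.gate.threshold}",
            f"  retained {len(self.retained)} / {len(self.surrogates)} "
            f"markers; required CpG union: {len(self.required_cpgs())}",
            "",
            t.to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# level 2
# ---------------------------------------------------------------------------


class InflammAgeModel:
    """Level-2 model: chronological age from retained marker estimates.

    Trained on control samples only (when a ``Status`` column is present);
    case samples are predicted but never fitted on."""

    def __init__(self, estimates: pd.DataFrame, meta: pd.DataFrame,
                 backend: BackendSpec | None = None):
        self.estimates = estimates
        self.meta = validate_meta(meta).loc[estimates.index]
        self.backend = backend or BackendSpec.elasticnet()

    def fit(self, budget: SearchBudget | None = None, seed: int = 0
            ) -> "InflammAgeResults":
        budget = budget or SearchBudget()
        meta = self.meta
        if "Status" in meta.columns:
            train_meta = meta[meta["Status"].astype(str) == "control"]
        else:
            train_meta = meta
        plan = clock_mod.age_stratified_split(train_meta, seed=seed)
        clock = clock_mod.train_clock(self.estimates.loc[train_meta.index],
                                      train_meta, plan,
                                      spec=self.backend, budget=budget,
                                      seed=seed)
        predictions = clock_mod.predict_age(self.estimates, clock, meta)
        return InflammAgeResults(model=self, clock=clock, plan=plan,
                                 predictions=predictions, seed=seed)


@dataclass
class InflammAgeResults:
    """Fitted clock, its split plan, and the cohort prediction table."""

    model: InflammAgeModel
    clock: clock_mod.ClockModel
    plan: clock_mod.SplitPlan
    predictions: pd.DataFrame
    seed: int = 0
    _attrs: explain_mod.AttributionTable | None = field(default=None,
                                                        repr=False)

    def predict(self, estimates: pd.DataFrame, meta: pd.DataFrame
                ) -> pd.DataFrame:
        return clock_mod.predict_age(estimates, self.clock,
                                     validate_meta(meta))

    def metrics(self, by=None) -> pd.DataFrame:
        return clock_mod.cohort_metrics(self.predictions, by=by)

    def attributions(self, settings: explain_mod.ShapSettings | None = None,
                     estimates: pd.DataFrame | None = None
                     ) -> explain_mod.AttributionTable:
        """Shapley contributions (years); background = training samples."""
        settings = settings or explain_mod.ShapSettings(seed=self.seed)
        background = self.model.estimates.loc[self.plan.trainval_ids]
        est = self.model.estimates if estimates is None else estimates
        return explain_mod.attribute(self.clock, est, background, settings)

    def battery(self, alpha: float = 0.05,
                predictions: pd.DataFrame | None = None
                ) -> battery_mod.BatteryReport:
        pred = self.predictions if predictions is None else predictions
        return battery_mod.run_battery(pred, self.model.meta, alpha=alpha)

    def summary(self) -> str:
        lines = [
            "Inflammatory epigenetic age clock",
            f"  backend: {self.clock.backend}   features: "
            f"{len(self.clock.markers)} markers   seed: {self.seed}",
            f"  dataset dispositions: "
            + ", ".join(f"{d}={v}" for d, v in
                        sorted(self.plan.dispositions.items())),
            "",
            "  subset      n      MAE (y)   Pearson r   bias (y)",
        ]
        subset_ids = {"train": self.plan.trainval_ids,
                      "val": self.plan.trainval_ids,
                      "test": self.plan.test_ids}
        for sub, m in self.clock.metrics.items():
            ids = [s for s in subset_ids.get(sub, []) if
                   s in self.predictions.index]
            bias = float(self.predictions.loc[ids, "AgeAcceleration"].mean()) \
                if (ids and sub != "val") else float("nan")
            lines.append(f"  {sub:<9}{len(ids):>6}   {m['mae']:>8.3f}   "
                         f"{m['pearson_r']:>9.3f}   {bias:>8.3f}")
        return "\n".join(lines)
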