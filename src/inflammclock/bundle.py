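"""Text-only serialisation of trained model bundles.

A bundle directory holds everything needed to apply a trained two-level
model to new uploads: the per-marker CpG selections, gate report, frozen
standardisation statistics, regressor weights, metrics and seeds — all as
JSON/CSV so bundles diff cleanly and load bit-exactly. Regressors are
rebuilt as small forward-pass predictors (:class:`LinearPredictor`,
:class:`MLPPredictor`) rather than unpickled estimators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clock import ClockModel
from .feature_selection import SelectionMap
from .surrogate import GateReport, TrainedSurrogate

BUNDLE_VERSION = 1


@dataclass
class LinearPredictor:
    """w @ x + b; exposes coef_/intercept_ so closed-form Shapley applies."""

    coef_: np.ndarray
    intercept_: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


@dataclass
class MLPPredictor:
    """ReLU feed-forward network rebuilt from stored weight matrices."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def predict(self, X: np.ndarray) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < len(self.weights) - 1:
                h = np.maximum(h, 0.0)
        return h.ravel()


def _model_payload(model, backend: str) -> dict:
    if backend == "elasticnet":
        return {"coef": np.asarray(model.coef_, dtype=float).ravel().tolist(),
                "intercept": float(np.ravel(model.intercept_)[0])
                if np.ndim(model.intercept_) else float(model.intercept_)}
    return {"weights": [np.asarray(W, dtype=float).tolist()
                        for W in model.coefs_],
            "biases": [np.asarray(b, dtype=float).ravel().tolist()
                       for b in model.intercepts_]}


def _payload_model(payload: dict, backend: str):
    if backend == "elasticnet":
        return LinearPredictor(coef_=np.asarray(payload["coef"], dtype=float),
                               intercept_=float(payload["intercept"]))
    return MLPPredictor(
        weights=[np.asarray(W, dtype=float) for W in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]])


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def save_bundle(path: str | Path, panel_results, clock_results,
                profile: str = "desk") -> None:
    """Write a self-describing bundle for a fitted panel + clock."""
    path = Path(path)
    (path / "surrogates").mkdir(parents=True, exist_ok=True)
    meta = {
        "bundle_version": BUNDLE_VERSION,
        "profile": profile,
        "seed": panel_results.seed,
        "gate_threshold": panel_results.gate.threshold,
        "retained_markers": panel_results.retained,
        "required_cpgs": panel_results.required_cpgs(),
    }
    _write_json(path / "bundle.json", meta)
    panel_results.selection.to_frame().to_csv(path / "selection.csv",
                                              index=False)
    panel_results.gate.table.to_csv(path / "gate.csv", index=False)
    for name, s in sorted(panel_results.surrogates.items()):
        _write_json(path / "surrogates" / f"{name}.json", {
            "marker": s.marker,
            "cpgs": s.cpgs,
            "x_mean": s.x_mean.tolist(),
            "x_sd": s.x_sd.tolist(),
            "backend": s.backend,
            "params": s.params,
            "metrics": s.metrics,
            "transform": s.transform,
            "seed": s.seed,
            "model": _model_payload(s.model, s.backend),
        })
    c = clock_results.clock
    _write_json(path / "clock.json", {
        "markers": c.markers,
        "x_mean": c.x_mean.tolist(),
        "x_sd": c.x_sd.tolist(),
        "backend": c.backend,
        "params": c.params,
        "metrics": c.metrics,
        "seed": c.seed,
        "model": _model_payload(c.model, c.backend),
    })


@dataclass
class LoadedBundle:
    meta: dict
    selection: SelectionMap
    gate: GateReport
    surrogates: dict[str, TrainedSurrogate]
    clock: ClockModel

    @property
    def required_cpgs(self) -> list[str]:
        return list(self.meta["required_cpgs"])

    @property
    def retained(self) -> list[str]:
        return list(self.meta["retained_markers"])


def load_bundle(path: str | Path) -> LoadedBundle:
    path = Path(path)
    meta = json.loads((path / "bundle.json").read_text())
    selection = SelectionMap.from_frame(pd.read_csv(path / "selection.csv"))
    gate = GateReport(table=pd.read_csv(path / "gate.csv"),
                      threshold=float(meta["gate_threshold"]))
    surrogates = {}
    for f in sorted((path / "surrogates").glob("*.json")):
        d = json.loads(f.read_text())
        surrogates[d["marker"]] = TrainedSurrogate(
            marker=d["marker"], cpgs=list(d["cpgs"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            model=_payload_model(d["model"], d["backend"]),
            backend=d["backend"], params=d["params"], metrics=d["metrics"],
            transform=d["transform"], seed=int(d["seed"]),
        )
    cd = json.loads((path / "clock.json").read_text())
    clock = ClockModel(
        markers=list(cd["markers"]),
        x_mean=np.asarray(cd["x_mean"], dtype=float),
        x_sd=np.asarray(cd["x_sd"], dtype=float),
        model=_payload_model(cd["model"], cd["backend"]),
        backend=cd["backend"], params=cd["params"], metrics=cd["metrics"],
        seed=int(cd["seed"]),
    )
    return LoadedBundle(meta=meta, selection=selection, gate=gate,
                        surrogates=surrogates, clock=clock)
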