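"""Backend regressors and sequential model-based hyperparameter search.

Two backend families are supported for both pipeline levels:

* ``elasticnet`` — linear regression with combined L1/L2 penalty, the
  classical baseline for methylation clocks;
* ``mlp`` — a feed-forward neural network (multi-layer perceptron), the
  generic tabular deep-learning contract.

Hyperparameters are tuned by a budgeted sequential search in the
Tree-structured-Parzen-Estimator style: the first ``n_startup`` trials are
sampled uniformly at random from the search space; afterwards the trial
history is split into a "good" and a "bad" fraction by objective value, a
kernel density is built over each, and the candidate (out of
``n_candidates`` draws from the good density) with the highest good/bad
density ratio is evaluated next. All randomness derives from one seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.neural_network import MLPRegressor


def fit_quiet(est, X, y):
    """Fit an estimator, silencing per-trial convergence chatter.

    Weakly regularised trials may stop at max_iter; the search treats their
    validation score like any other, so the warning carries no signal."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est

# ---------------------------------------------------------------------------
# search-space distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Float:
    low: float
    high: float
    log: bool = False

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("Float range must satisfy low < high")

    def sample(self, rng: np.random.Generator) -> float:
        if self.log:
            return float(np.exp(rng.uniform(np.log(self.low),
                                            np.log(self.high))))
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class Int:
    low: int
    high: int  # inclusive

    def __post_init__(self):
        if not self.low <= self.high:
            raise ValueError("Int range must satisfy low <= high")

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.low, self.high + 1))


@dataclass(frozen=True)
class Choice:
    options: tuple

    def sample(self, rng: np.random.Generator):
        return self.options[int(rng.integers(len(self.options)))]


Space = dict[str, Float | Int | Choice]


@dataclass
class BackendSpec:
    """Backend kind plus its hyperparameter search space."""

    kind: str  # "elasticnet" | "mlp"
    space: Space = field(default_factory=dict)
    max_iter: int = 3000

    def __post_init__(self):
        if self.kind not in {"elasticnet", "mlp"}:
            raise ValueError(f"unknown backend kind {self.kind!r}")
        if not self.space:
            self.space = default_space(self.kind)
        for name, dist in self.space.items():
            if isinstance(dist, Choice) and not dist.options:
                raise ValueError(f"empty Choice for {name!r}")

    @classmethod
    def elasticnet(cls) -> "BackendSpec":
        return cls("elasticnet")

    @classmethod
    def mlp(cls) -> "BackendSpec":
        return cls("mlp")


def default_space(kind: str) -> Space:
    if kind == "elasticnet":
        return {
            "alpha": Float(1e-4, 10.0, log=True),
            "l1_ratio": Float(0.01, 1.0),
        }
    return {
        "n_layers": Int(1, 3),
        "width": Choice((16, 64, 256)),
        "weight_decay": Float(1e-6, 1e-3, log=True),
        "learning_rate": Float(1e-4, 1e-2, log=True),
    }


def make_estimator(spec: BackendSpec, params: dict[str, Any], seed: int):
    """Instantiate a fresh, unfitted estimator for one hyperparameter set."""
    if spec.kind == "elasticnet":
        return ElasticNet(alpha=params["alpha"], l1_ratio=params["l1_ratio"],
                          max_iter=spec.max_iter, tol=1e-5,
                          random_state=seed)
    hidden = tuple([int(params["width"])] * int(params["n_layers"]))
    return MLPRegressor(
        hidden_layer_sizes=hidden,
        alpha=params["weight_decay"],
        learning_rate_init=params["learning_rate"],
        max_iter=400,
        early_stopping=True,
        n_iter_no_change=20,
        validation_fraction=0.15,
        random_state=seed,
    )


# ---------------------------------------------------------------------------
# TPE-style sequential sampler
# ---------------------------------------------------------------------------


@dataclass
class Trial:
    params: dict[str, Any]
    score: float  # minimised


@dataclass
class SearchBudget:
    """Trial budget for one tune-and-train run.

    ``desk`` keeps unit-scale work tractable; ``paper`` mirrors the published
    protocol (1024 trials, 256 random startup, 16 candidate draws).
    """

    trials: int = 32
    startup_trials: int = 8
    n_candidates: int = 16

    @classmethod
    def profile(cls, name: str) -> "SearchBudget":
        if name == "desk":
            return cls()
        if name == "paper":
            return cls(trials=1024, startup_trials=256, n_candidates=16)
        raise ValueError(f"unknown budget profile {name!r}")


def _to_internal(dist, value) -> float:
    if isinstance(dist, Float):
        return math.log(value) if dist.log else float(value)
    if isinstance(dist, Int):
        return float(value)
    return float(dist.options.index(value))


def _kde_logpdf(x: float, obs: np.ndarray, lo: float, hi: float) -> float:
    """Gaussian Parzen estimator with a uniform prior component."""
    bw = max((hi - lo) / max(np.sqrt(len(obs)), 1.0), 1e-12)
    comps = -0.5 * ((x - obs) / bw) ** 2 - math.log(bw * math.sqrt(2 * math.pi))
    prior = -math.log(hi - lo) if hi > lo else 0.0
    all_comps = np.append(comps, prior)
    m = float(np.max(all_comps))
    return m + math.log(np.mean(np.exp(all_comps - m)))


class TPESampler:
    """Good/bad Parzen-density sampler over an independent per-dimension model."""

    def __init__(self, space: Space, budget: SearchBudget,
                 rng: np.random.Generator, gamma: float = 0.25):
        self.space = space
        self.budget = budget
        self.rng = rng
        self.gamma = gamma

    def suggest(self, history: list[Trial]) -> dict[str, Any]:
        finite = [t for t in history if np.isfinite(t.score)]
        if len(history) < self.budget.startup_trials or len(finite) < 4:
            return {n: d.sample(self.rng) for n, d in self.space.items()}
        order = sorted(finite, key=lambda t: t.score)
        n_good = max(1, math.ceil(self.gamma * len(order)))
        good, bad = order[:n_good], order[n_good:]
        best, best_ratio = None, -math.inf
        for _ in range(self.budget.n_candidates):
            cand = {}
            ratio = 0.0
            for name, dist in self.space.items():
                g_obs = np.array([_to_internal(dist, t.params[name])
                                  for t in good])
                b_obs = np.array([_to_internal(dist, t.params[name])
                                  for t in bad])
                if isinstance(dist, Choice):
                    counts = np.ones(len(dist.options))
                    for v in g_obs:
                        counts[int(v)] += 1
                    probs = counts / counts.sum()
                    idx = int(self.rng.choice(len(dist.options), p=probs))
                    cand[name] = dist.options[idx]
                    b_counts = np.ones(len(dist.options))
                    for v in b_obs:
                        b_counts[int(v)] += 1
                    ratio += math.log(probs[idx]) - math.log(
                        b_counts[idx] / b_counts.sum())
                else:
                    if isinstance(dist, Float):
                        lo = math.log(dist.low) if dist.log else dist.low
                        hi = math.log(dist.high) if dist.log else dist.high
                    else:
                        lo, hi = float(dist.low), float(dist.high)
                    # draw from the good mixture, clipped to the range
                    centre = float(self.rng.choice(g_obs)) if len(g_obs) else \
                        self.rng.uniform(lo, hi)
                    bw = max((hi - lo) / max(math.sqrt(len(g_obs)), 1.0), 1e-12)
                    x = float(np.clip(self.rng.normal(centre, bw), lo, hi))
                    ratio += _kde_logpdf(x, g_obs, lo, hi) - \
                        _kde_logpdf(x, b_obs, lo, hi)
                    if isinstance(dist, Int):
                        cand[name] = int(round(x))
                    else:
                        cand[name] = float(math.exp(x)) if dist.log else float(x)
            if ratio > best_ratio:
                best, best_ratio = cand, ratio
        return best


def run_search(objective: Callable[[dict[str, Any]], float], space: Space,
               budget: SearchBudget, seed: int) -> tuple[dict[str, Any],
                                                         list[Trial]]:
    """Minimise ``objective`` over ``space`` within ``budget`` trials.

    Returns the best parameter set and the full trial history. Raises if no
    trial produced a finite objective value.
    """
    if budget.trials < 1:
        raise ValueError("budget.trials must be >= 1")
    rng = np.random.default_rng(seed)
    sampler = TPESampler(space, budget, rng)
    history: list[Trial] = []
    for _ in range(budget.trials):
        params = sampler.suggest(history)
        score = float(objective(params))
        history.append(Trial(params=params, score=score))
    finite = [t for t in history if np.isfinite(t.score)]
    if not finite:
        raise RuntimeError("all search trials returned non-finite loss")
    best = min(finite, key=lambda t: t.score)
    return dict(best.params), history
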