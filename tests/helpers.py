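"""Independent oracles used by the test suite.

These deliberately re-derive each quantity from first principles (loops,
enumeration, closed forms) without touching the library's implementation
paths, so agreement is evidence rather than tautology.
"""

from itertools import combinations
from math import factorial

import numpy as np
from scipy import stats


def mrmr_greedy_oracle(X, y, k: int) -> list[str]:
    """Step-by-step greedy mRMR evaluated naively with scipy.stats.pearsonr.

    Relevance F = r^2 (n-2) / (1-r^2); redundancy = mean |r| with already
    selected; quotient criterion with eps=1e-6; lexicographic tie-break via
    initial column sort; first pick pure relevance."""
    cols = sorted(map(str, X.columns))
    y = np.asarray(y, dtype=float)
    n = len(y)
    def is_const(x):
        return np.std(x) <= 1e-12 * (abs(np.mean(x)) + 1.0)

    rel = {}
    for c in cols:
        x = X[c].to_numpy(dtype=float)
        if is_const(x):
            rel[c] = 0.0
            continue
        r = stats.pearsonr(x, y)[0]
        r = max(min(r, 1.0), -1.0)
        if abs(r) >= 1.0 - 1e-15:
            rel[c] = 1e12
        else:
            rel[c] = min(r**2 * (n - 2) / (1 - r**2), 1e12)
    usable = [c for c in cols if not is_const(X[c].to_numpy(dtype=float))]
    selected: list[str] = []
    for _ in range(k):
        best, best_score = None, -np.inf
        for c in usable:
            if c in selected:
                continue
            if not selected:
                score = rel[c]
            else:
                reds = []
                for s in selected:
                    xs = X[s].to_numpy(dtype=float)
                    xc = X[c].to_numpy(dtype=float)
                    reds.append(abs(stats.pearsonr(xc, xs)[0]))
                score = rel[c] / max(float(np.mean(reds)), 1e-6)
            if score > best_score:  # strict > keeps the lexicographic winner
                best, best_score = c, score
        selected.append(best)
    return selected


def mannwhitney_enum_oracle(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of labelings."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum((x > y) + 0.5 * (x == y) for x in group_a for y in group_b)

    u_obs = u_stat(a, b)
    us = []
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in idx if i not in comb]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    m = len(us)
    p_le = np.sum(us <= u_obs) / m
    p_ge = np.sum(us >= u_obs) / m
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def bh_stepup_oracle(pvals) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def bh_rejections_oracle(pvals, alpha: float) -> np.ndarray:
    """Classic step-up rejection set: largest i with p_(i) <= i*alpha/m."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def shapley_enum_oracle(predict, x: np.ndarray, background: np.ndarray
                        ) -> np.ndarray:
    """Exact Shapley values by subset enumeration, averaged over background
    rows used as the off-coalition reference."""
    d = len(x)
    total = np.zeros(d)
    for b in background:
        def value(subset):
            z = b.copy()
            for j in subset:
                z[j] = x[j]
            return float(predict(z[None, :])[0])

        phi = np.zeros(d)
        features = list(range(d))
        for j in features:
            others = [f for f in features if f != j]
            for size in range(d):
                w = factorial(size) * factorial(d - size - 1) / factorial(d)
                for S in combinations(others, size):
                    phi[j] += w * (value(set(S) | {j}) - value(set(S)))
        total += phi
    return total / len(background)
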