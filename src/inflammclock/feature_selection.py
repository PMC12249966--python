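"""Per-marker CpG selection with the mRMR (minimum redundancy, maximum
relevance) criterion.

Methylation arrays measure hundreds of thousands of probes; only a small
subset carries signal for any one inflammatory protein, and informative
probes are often mutually correlated. mRMR ranks features greedily:
relevance of a candidate probe is its univariate F-statistic against the
target, redundancy is its mean absolute Pearson correlation with the probes
already picked, and each step selects the candidate maximising the
relevance/redundancy quotient. The first pick is pure relevance.

Conventions fixed here (quotient form, absolute-correlation redundancy,
lexicographic tie-break, F capped at :data:`F_CAP`) make the selection
deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: cap applied to the F-statistic for numerically perfect correlations
F_CAP = 1e12
#: floor applied to the mean-redundancy denominator in the greedy quotient
REDUNDANCY_EPS = 1e-6


class SelectionError(ValueError):
    pass


def _standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns; returns (Z, sd with constant columns set to 0).

    A column is treated as constant when its SD is at rounding-noise scale
    relative to its mean, so e.g. a column of repeated 0.3s scores zero."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 1e-12 * (np.abs(mu) + 1.0), sd, 0.0)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return Z, sd


def relevance_scores(X: pd.DataFrame, y: np.ndarray | pd.Series) -> pd.Series:
    """Univariate F-statistic of each feature against the target.

    F_j = r_j^2 (n-2) / (1 - r_j^2) with r_j the Pearson correlation of
    feature j with y. Zero-variance features score 0; numerically perfect
    correlations are capped at :data:`F_CAP`.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise SelectionError("relevance requires at least 3 samples")
    if np.std(y) == 0:
        raise SelectionError("target is constant; relevance undefined")
    A = X.to_numpy(dtype=float)
    n = A.shape[0]
    Z, sd = _standardise(A)
    yz = (y - y.mean()) / y.std()
    r = Z.T @ yz / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        f = r**2 * (n - 2) / (1.0 - r**2)
    f = np.where(sd > 0, np.minimum(np.nan_to_num(f, posinf=F_CAP), F_CAP), 0.0)
    return pd.Series(f, index=X.columns, name="relevance")


def mrmr_select(X: pd.DataFrame, y: np.ndarray | pd.Series, k: int
                ) -> pd.DataFrame:
    """Greedy mRMR selection of ``k`` features.

    Step 1 takes the most relevant feature; step t maximises
    ``relevance_j / max(mean |corr(j, selected)|, eps)``. Ties break on
    lexicographic feature name. Returns a DataFrame with one row per pick in
    selection order: ``cpg_id``, ``relevance``, ``redundancy_at_selection``.
    """
    if k < 1:
        raise SelectionError("k must be >= 1")
    # lexicographic column order makes argmax resolve ties deterministically
    X = X.reindex(sorted(X.columns.astype(str)), axis=1)
    rel = relevance_scores(X, y)
    A = X.to_numpy(dtype=float)
    n = A.shape[0]
    Z, sd = _standardise(A)
    usable = sd > 0
    if int(usable.sum()) < k:
        raise SelectionError(
            f"k={k} exceeds the {int(usable.sum())} non-constant features"
        )
    relv = rel.to_numpy()
    names = X.columns.to_numpy()

    selected: list[int] = []
    rows = []
    redundancy_sum = np.zeros(A.shape[1])
    available = usable.copy()
    for step in range(k):
        if step == 0:
            score = np.where(available, relv, -np.inf)
            red_at = np.zeros(A.shape[1])
        else:
            mean_red = redundancy_sum / len(selected)
            red_at = np.maximum(mean_red, REDUNDANCY_EPS)
            score = np.where(available, relv / red_at, -np.inf)
        j = int(np.argmax(score))
        selected.append(j)
        available[j] = False
        rows.append((names[j], float(relv[j]),
                     float(red_at[j] if step else 0.0)))
        # update running sum of |corr| with the newly selected feature
        corr_new = np.abs(Z.T @ Z[:, j] / n)
        corr_new = np.clip(corr_new, 0.0, 1.0)
        redundancy_sum += np.where(usable, corr_new, 0.0)
    return pd.DataFrame(rows, columns=["cpg_id", "relevance",
                                       "redundancy_at_selection"])


@dataclass
class SelectionMap:
    """Ordered CpG selections per marker, with selection diagnostics."""

    per_marker: dict[str, pd.DataFrame] = field(default_factory=dict)

    def cpgs(self, marker: str) -> list[str]:
        return self.per_marker[marker]["cpg_id"].tolist()

    @property
    def markers(self) -> list[str]:
        return list(self.per_marker)

    def cpg_union(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.per_marker.values():
            for c in m["cpg_id"]:
                seen[c] = None
        return sorted(seen)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for marker, df in self.per_marker.items():
            part = df.copy()
            part.insert(0, "marker", marker)
            part.insert(1, "rank", np.arange(1, len(part) + 1))
            parts.append(part)
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SelectionMap":
        out = {}
        for marker, part in df.groupby("marker", sort=False):
            part = part.sort_values("rank")
            out[str(marker)] = part[
                ["cpg_id", "relevance", "redundancy_at_selection"]
            ].reset_index(drop=True)
        return cls(out)


def select_marker_cpgs(beta: pd.DataFrame, markers: pd.DataFrame,
                       k: int = 100, transform=None) -> SelectionMap:
    """Run mRMR once per marker column. Missing marker values drop that
    sample for that marker only. ``transform`` (e.g. log1p) is applied to the
    target before scoring."""
    out: dict[str, pd.DataFrame] = {}
    for marker in markers.columns:
        y = markers[marker]
        ok = y.notna()
        yv = y[ok].to_numpy(dtype=float)
        if transform is not None:
            yv = transform(yv)
        out[str(marker)] = mrmr_select(beta.loc[ok.index[ok]], yv, k)
    return SelectionMap(out)


def marker_cpg_correlation_map(beta: pd.DataFrame, markers: pd.DataFrame,
                               selection: SelectionMap) -> pd.DataFrame:
    """|Pearson r| between each marker and its rank-th selected CpG.

    Rows = markers, columns = selection rank (1-based)."""
    rows = {}
    for marker in selection.markers:
        cpgs = selection.cpgs(marker)
        y = markers[marker]
        ok = y.notna()
        yv = y[ok].to_numpy(dtype=float)
        sub = beta.loc[ok.index[ok], cpgs].to_numpy(dtype=float)
        Z, sd = _standardise(sub)
        yz = (yv - yv.mean()) / yv.std()
        r = np.abs(Z.T @ yz / len(yv))
        rows[marker] = np.clip(np.where(sd > 0, r, 0.0), 0.0, 1.0)
    k = max(len(v) for v in rows.values())
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=pd.RangeIndex(1, k + 1, name="rank"))
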