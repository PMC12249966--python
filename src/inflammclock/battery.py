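"""Case/control disease-sensitivity battery on age-acceleration values.

For every dataset that contains both controls and a case group, the
distribution of age acceleration in cases is compared to the same-dataset
controls with a two-sided Mann–Whitney U test (exact enumeration for small
tie-free groups, normal approximation with tie and continuity correction
otherwise). All raw p-values of one battery are adjusted jointly with the
Benjamini–Hochberg step-up procedure; a test passes when its adjusted
p-value falls below α (0.05 by default). Because the U test is direction
blind, each test also reports the signed bias difference (mean case
acceleration minus mean control acceleration, years). Results roll up into
per-ICD-chapter "passed / total" tallies.

The battery accepts any prediction table with the standard schema, so
externally computed clocks can be benchmarked with the same procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: minimum group size on each side for a U test to be attempted
MIN_GROUP = 3


class BatteryError(ValueError):
    pass


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of group a, p).

    Exact p by enumeration when both groups have at most 8 observations and
    no ties occur; otherwise the normal approximation with midrank tie
    correction and continuity correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise BatteryError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto",
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise BatteryError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class BatteryReport:
    """One row per (dataset, case-group) test plus ICD-chapter rollups."""

    results: pd.DataFrame
    alpha: float
    excluded: pd.DataFrame

    @property
    def n_passed(self) -> int:
        return int(self.results["passed"].sum())

    @property
    def n_total(self) -> int:
        return int(len(self.results))

    def chapter_rollup(self) -> dict[int, dict[str, int]]:
        out: dict[int, dict[str, int]] = {}
        for ch, sub in self.results.groupby("icd_chapter"):
            out[int(ch)] = {"passed": int(sub["passed"].sum()),
                            "total": int(len(sub))}
        return out

    def summary(self) -> str:
        lines = [f"disease-sensitivity battery: {self.n_passed} / "
                 f"{self.n_total} tests passed (alpha={self.alpha})"]
        for ch, tally in sorted(self.chapter_rollup().items()):
            lines.append(f"  ICD-11 chapter {ch}: {tally['passed']} / "
                         f"{tally['total']}")
        return "\n".join(lines)


def run_battery(pred: pd.DataFrame, meta: pd.DataFrame,
                alpha: float = 0.05, min_group: int = MIN_GROUP
                ) -> BatteryReport:
    """Run the full battery of one prediction model.

    ``pred`` must carry an ``AgeAcceleration`` column indexed by sample ID;
    ``meta`` supplies ``DatasetID``, ``Status`` and, for cases,
    ``ICDChapter``/``ICDCode``. A case group is one (dataset, chapter, code)
    cell; datasets lacking either side are excluded and logged."""
    common = pred.index.intersection(meta.index)
    if len(common) == 0:
        raise BatteryError("prediction table and metadata share no samples")
    acc = pred.loc[common, "AgeAcceleration"].astype(float)
    m = meta.loc[common]
    status = m["Status"].astype(str)

    rows, skipped = [], []
    for ds in sorted(m["DatasetID"].astype(str).unique()):
        in_ds = m["DatasetID"].astype(str) == ds
        ctrl_acc = acc[in_ds & (status == "control")].to_numpy()
        cases = m[in_ds & (status == "case")]
        if len(cases) == 0:
            continue
        if len(ctrl_acc) < min_group:
            skipped.append((ds, "all", "too few controls",
                            len(ctrl_acc)))
            continue
        key = cases["ICDChapter"].astype(int).astype(str)
        if "ICDCode" in cases.columns:
            key = key + ":" + cases["ICDCode"].fillna("").astype(str)
        for label in sorted(key.unique()):
            gidx = cases.index[key == label]
            case_acc = acc[gidx].to_numpy()
            if len(case_acc) < min_group:
                skipped.append((ds, label, "too few cases", len(case_acc)))
                continue
            U, p = mann_whitney_u(case_acc, ctrl_acc)
            rows.append({
                "dataset_id": ds,
                "case_group": label,
                "icd_chapter": int(label.split(":")[0]),
                "n_cases": len(case_acc),
                "n_controls": len(ctrl_acc),
                "U": U,
                "p_raw": p,
                "bias_difference_years": float(case_acc.mean()
                                               - ctrl_acc.mean()),
            })
    if not rows:
        raise BatteryError("no (dataset, case-group) pair eligible for testing")
    results = pd.DataFrame(rows)
    results["p_adjusted"] = bh_adjust(results["p_raw"].to_numpy())
    results["passed"] = results["p_adjusted"] < alpha
    excluded = pd.DataFrame(skipped, columns=["dataset_id", "case_group",
                                              "reason", "n"])
    for _, row in excluded.iterrows():
        logger.info("battery: excluded %s / %s (%s, n=%d)",
                    row["dataset_id"], row["case_group"], row["reason"],
                    row["n"])
    return BatteryReport(results=results, alpha=alpha, excluded=excluded)
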