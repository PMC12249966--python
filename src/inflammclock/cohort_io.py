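"""Cohort tables: methylation beta matrices, sample metadata, cytokine panels.

The three inputs of the two-level clock pipeline are plain CSV/TSV tables:

* a **beta matrix** — samples x CpG probes, methylated fraction in [0, 1],
  possibly with missing entries (failed probes);
* **sample metadata** — chronological age in years, sex, dataset of origin,
  and case/control status with an ICD-11 chapter/code for cases;
* an optional **marker table** — measured inflammatory protein levels in
  pg/mL, used only when training the level-1 surrogate models.

All tables are keyed by a ``SampleID`` column. Parsing and alignment are
delegated to pandas; this module adds validation, missing-value imputation
and deterministic cohort joining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)

SAMPLE_ID = "SampleID"
AGE = "Age"
#: extra missing-value spellings accepted on top of the pandas defaults
NA_TOKENS = ("", "NA", "NaN", "nan", "N/A", "null")
#: numerical slack allowed on the [0, 1] beta range
BETA_TOL = 1e-9

META_COLUMNS = (AGE, "Sex", "DatasetID", "Status", "ICDChapter", "ICDCode")


class CohortError(ValueError):
    """Raised when an input table violates a cohort invariant."""


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Samples x CpG probes matrix of methylation beta fractions.

    ``values`` is a float DataFrame indexed by sample ID with CpG probe IDs
    as columns; missing entries are NaN. Construction validates the [0, 1]
    range (within :data:`BETA_TOL`) and ID uniqueness.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate sample IDs: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise CohortError(f"duplicate CpG IDs: {dupes[:5]}")
        arr = df.to_numpy(dtype=float)
        bad = (arr < -BETA_TOL) | (arr > 1.0 + BETA_TOL)
        bad &= ~np.isnan(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CohortError(
                f"beta value out of [0, 1]: sample {df.index[i]!r}, "
                f"CpG {df.columns[j]!r}, value {arr[i, j]!r}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_samples(self, ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(ids)])


def read_beta_matrix(path: str | Path, delimiter: str | None = None,
                     na_tokens: Iterable[str] = NA_TOKENS) -> BetaMatrix:
    """Read a beta matrix from CSV/TSV (header = CpG IDs, first column = sample IDs)."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0,
                     na_values=list(na_tokens), keep_default_na=True)
    df.index = df.index.astype(str)
    df.index.name = SAMPLE_ID
    df.columns = df.columns.astype(str)
    return BetaMatrix(df.astype(float))


def write_beta_matrix(m: BetaMatrix, path: str | Path,
                      delimiter: str = ",") -> None:
    out = m.values.copy()
    out.index.name = SAMPLE_ID
    out.to_csv(path, sep=delimiter, na_rep="NA", float_format="%.17g")


def impute_missing(m: BetaMatrix, method: str = "knn", k: int = 5) -> BetaMatrix:
    """Fill missing beta entries by ``knn``, ``mean`` or ``median``.

    ``mean``/``median`` use the per-CpG column statistic of the observed
    entries. ``knn`` uses Euclidean distance over mutually observed CpGs
    normalised by the overlap count and averages the ``k`` nearest samples
    that observed the missing probe. Observed entries are never altered.
    """
    df = m.values
    empty = df.columns[df.notna().sum(axis=0) == 0].tolist()
    if empty:
        raise CohortError(f"CpG columns with no observed values: {empty[:10]}")
    if m.n_missing == 0:
        return m

    if method in {"mean", "median"}:
        stat = df.mean(axis=0) if method == "mean" else df.median(axis=0)
        filled = df.fillna(stat)
    elif method == "knn":
        if k < 1:
            raise CohortError("knn imputation requires k >= 1")
        donors = df.notna().sum(axis=0)
        has_na = df.isna().any(axis=0)
        thin = df.columns[has_na & (donors < k)].tolist()
        if thin:
            raise CohortError(
                f"knn with k={k} needs >= {k} observed samples per CpG; "
                f"too few for: {thin[:10]}"
            )
        imputer = KNNImputer(n_neighbors=k, weights="uniform")
        arr = imputer.fit_transform(df.to_numpy(dtype=float))
        filled = pd.DataFrame(arr, index=df.index, columns=df.columns)
    else:
        raise CohortError(f"unknown imputation method {method!r}")
    # observed entries pass through bitwise; only imputed cells are clamped
    filled = filled.clip(0.0, 1.0).where(df.isna(), df)
    return BetaMatrix(filled)


# ---------------------------------------------------------------------------
# sample metadata & marker table
# ---------------------------------------------------------------------------


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table (index or ``SampleID`` column = IDs)."""
    meta = meta.copy()
    if SAMPLE_ID in meta.columns:
        meta = meta.set_index(SAMPLE_ID)
    meta.index = meta.index.astype(str)
    meta.index.name = SAMPLE_ID
    if meta.index.has_duplicates:
        raise CohortError("duplicate sample IDs in metadata")
    if AGE not in meta.columns:
        raise CohortError(f"metadata must contain an {AGE!r} column")
    ages = pd.to_numeric(meta[AGE], errors="coerce")
    if ages.isna().any():
        raise CohortError("non-numeric or missing ages in metadata")
    if (ages < 0).any():
        raise CohortError("negative ages in metadata")
    meta[AGE] = ages.astype(float)
    if "Status" in meta.columns:
        bad = ~meta["Status"].isin(["control", "case"])
        if bad.any():
            raise CohortError(
                f"Status must be control|case; offending rows: "
                f"{meta.index[bad][:5].tolist()}"
            )
        if "ICDChapter" in meta.columns:
            cases = meta["Status"] == "case"
            missing = cases & meta["ICDChapter"].isna()
            if missing.any():
                raise CohortError(
                    "case samples lacking ICDChapter: "
                    f"{meta.index[missing][:5].tolist()}"
                )
    return meta


def read_meta(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=delimiter, na_values=list(NA_TOKENS))
    return validate_meta(df)


def validate_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Validate a marker table: samples x markers, positive pg/mL or missing."""
    markers = markers.copy()
    if SAMPLE_ID in markers.columns:
        markers = markers.set_index(SAMPLE_ID)
    markers.index = markers.index.astype(str)
    markers.index.name = SAMPLE_ID
    if markers.index.has_duplicates:
        raise CohortError("duplicate sample IDs in marker table")
    arr = markers.to_numpy(dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise CohortError("negative marker levels (pg/mL must be positive)")
    return markers.astype(float)


def read_markers(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=delimiter, na_values=list(NA_TOKENS))
    return validate_markers(df)


# ---------------------------------------------------------------------------
# joined cohort
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Beta matrix, metadata, and optional marker table aligned on sample ID."""

    beta: BetaMatrix
    meta: pd.DataFrame
    markers: pd.DataFrame | None = None
    dropped: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.sample_ids


def join_cohort(beta: BetaMatrix, meta: pd.DataFrame,
                markers: pd.DataFrame | None = None) -> Cohort:
    """Align tables on their common sample IDs, sorted for determinism.

    Samples absent from any required table are dropped (counts logged);
    an empty intersection is an error.
    """
    meta = validate_meta(meta)
    common = beta.sample_ids.intersection(meta.index)
    if markers is not None:
        markers = validate_markers(markers)
        common = common.intersection(markers.index)
    common = common.sort_values()
    if len(common) == 0:
        raise CohortError("no sample IDs shared by the input tables")
    dropped = {
        "beta": int(len(beta.sample_ids) - len(common)),
        "meta": int(len(meta.index) - len(common)),
    }
    if markers is not None:
        dropped["markers"] = int(len(markers.index) - len(common))
    for name, n in dropped.items():
        if n:
            logger.info("join_cohort: dropped %d sample(s) present only in %s",
                        n, name)
    return Cohort(
        beta=BetaMatrix(beta.values.loc[common]),
        meta=meta.loc[common],
        markers=None if markers is None else markers.loc[common],
        dropped=dropped,
    )
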