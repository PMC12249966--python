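"""Synthetic cohorts with known generative structure.

The generator follows the causal story the two-level clock inverts:

1. chronological age is drawn uniformly over the configured range;
2. each *informative* marker's log level rises (or falls) linearly with
   age, ``ln(level+1) = alpha_m + beta_m * age/10 + N(0, sigma_m^2)``; null
   markers have zero age slope;
3. each marker's *causal* CpG probes read out the realised log level
   through a logistic link, ``beta_j = logistic(gamma_j + delta_j * y_m +
   N(0, tau^2))``, which keeps beta values inside (0, 1) without clipping;
   remaining probes are pure Beta-distributed noise. A marker with zero
   causal CpGs is invisible to the methylome (a pure-noise marker that the
   surrogate gate should reject);
4. case samples receive a configured shift (in units of the marker noise
   SD) on selected markers *before* the CpG readout, so disease signal
   propagates into the methylation data exactly as the pipeline assumes.

Every latent quantity (true log levels, the causal map, link coefficients,
the analytic irreducible age-prediction error) is kept in
:class:`GroundTruth` so recovery tests compare against stored truth, never
against a re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import AGE, SAMPLE_ID, BetaMatrix

DEFAULT_SEED = 20250629


class SynthError(ValueError):
    pass


@dataclass
class CaseGroup:
    dataset_id: str
    icd_chapter: int
    icd_code: str
    marker_shifts: dict[str, float]  # marker -> shift in units of sigma_m
    n_cases: int


@dataclass
class SynthConfig:
    """Generative settings; the defaults define the bundled study cohort.

    500 control samples over ages 20-90 in 4 datasets; 8 markers of which 6
    are informative (log-level slope 0.3 per decade, alternating sign, 40
    causal CpGs each) and 2 are pure noise (slope 0, no causal CpGs); 2,000
    CpG probes total; two case groups of 30 with a +0.8 SD shift on three
    informative markers."""

    n_samples: int = 500
    n_cpgs: int = 2000
    n_markers: int = 8
    n_informative: int = 6
    n_causal_per_marker: int = 40
    age_range: tuple[float, float] = (20.0, 90.0)
    age_slope_per_decade: float = 0.3
    marker_noise_sd: float = 0.5
    link_noise_sd: float = 0.15
    link_slope_range: tuple[float, float] = (0.3, 0.8)
    n_datasets: int = 4
    case_groups: list[CaseGroup] | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.case_groups is None:
            # shift markers whose age slopes share a sign, so the induced
            # effect is a coherent age acceleration rather than a cancellation
            shifts = {"MK1": 0.8, "MK3": 0.8, "MK5": 0.8}
            self.case_groups = [
                CaseGroup("DS1", 1, "1A00", dict(shifts), 30),
                CaseGroup("DS3", 8, "8B20", dict(shifts), 30),
            ]
        if self.n_informative > self.n_markers:
            raise SynthError("n_informative exceeds n_markers")
        if self.n_informative * self.n_causal_per_marker > self.n_cpgs:
            raise SynthError("more causal CpGs requested than n_cpgs")
        if self.n_samples <= 0 or self.n_cpgs <= 0 or self.n_markers <= 0:
            raise SynthError("counts must be positive")

    @property
    def marker_names(self) -> list[str]:
        return [f"MK{i + 1}" for i in range(self.n_markers)]


@dataclass
class GroundTruth:
    """Latents sufficient to recompute every generated value."""

    log_levels: pd.DataFrame          # samples x markers, true ln(level+1)
    causal_map: dict[str, list[str]]  # marker -> causal CpG IDs
    age_slopes: dict[str, float]      # per decade, on the log scale
    intercepts: dict[str, float]
    noise_sds: dict[str, float]
    link_params: pd.DataFrame         # per causal CpG: marker, gamma, delta
    irreducible_mae_years: float
    level_age_correlation: dict[str, float]


@dataclass
class SynthCohort:
    beta: BetaMatrix
    markers: pd.DataFrame  # true levels, pg/mL
    meta: pd.DataFrame
    truth: GroundTruth
    config: SynthConfig


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _irreducible_mae(config: SynthConfig) -> float:
    """Analytic MAE of the best linear age predictor given *true* markers.

    Residual variance of age given the informative markers is
    ``(1/Var(age) + sum_m (beta_m/10)^2 / sigma_m^2)^{-1}``; the residual is
    approximately Gaussian, so MAE = sqrt(2/pi) * residual SD."""
    if config.marker_noise_sd == 0:
        return 0.0  # markers determine age exactly
    lo, hi = config.age_range
    var_age = (hi - lo) ** 2 / 12.0
    info = 1.0 / var_age
    per_year = config.age_slope_per_decade / 10.0
    info += config.n_informative * per_year**2 / config.marker_noise_sd**2
    return float(np.sqrt(2.0 / np.pi) * np.sqrt(1.0 / info))


def _level_age_correlation(config: SynthConfig, informative: bool) -> float:
    if not informative:
        return 0.0
    lo, hi = config.age_range
    sd_age = (hi - lo) / np.sqrt(12.0)
    signal = (config.age_slope_per_decade / 10.0) * sd_age
    return float(signal / np.hypot(signal, config.marker_noise_sd))


def generate(config: SynthConfig) -> SynthCohort:
    """Draw one cohort from the generative model; bit-reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    markers = config.marker_names
    informative = set(markers[: config.n_informative])

    n_cases = sum(g.n_cases for g in config.case_groups)
    n_total = config.n_samples + n_cases
    sample_ids = [f"S{i + 1:05d}" for i in range(n_total)]

    ages = rng.uniform(*config.age_range, size=n_total)
    datasets = np.empty(n_total, dtype=object)
    status = np.array(["control"] * n_total, dtype=object)
    chapters = np.full(n_total, np.nan)
    codes = np.empty(n_total, dtype=object)
    sexes = rng.choice(["F", "M"], size=n_total)

    ds_names = [f"DS{i + 1}" for i in range(config.n_datasets)]
    datasets[: config.n_samples] = [
        ds_names[i % config.n_datasets] for i in range(config.n_samples)]
    pos = config.n_samples
    case_rows: dict[int, CaseGroup] = {}
    for grp in config.case_groups:
        for _ in range(grp.n_cases):
            datasets[pos] = grp.dataset_id
            status[pos] = "case"
            chapters[pos] = grp.icd_chapter
            codes[pos] = grp.icd_code
            case_rows[pos] = grp
            pos += 1

    # marker coefficients; intercepts compensate negative slopes so log
    # levels stay well above zero across the age range
    lo_age, hi_age = config.age_range
    slopes, intercepts, sds = {}, {}, {}
    for i, mk in enumerate(markers):
        inf = mk in informative
        sign = 1.0 if i % 2 == 0 else -1.0
        slopes[mk] = sign * config.age_slope_per_decade if inf else 0.0
        base = float(rng.uniform(2.5, 4.0))
        if slopes[mk] < 0:
            base += -slopes[mk] * hi_age / 10.0
        intercepts[mk] = base
        sds[mk] = config.marker_noise_sd

    # true log levels, with case shifts applied before the CpG readout
    Y = np.empty((n_total, len(markers)))
    for j, mk in enumerate(markers):
        y = intercepts[mk] + slopes[mk] * ages / 10.0
        y = y + rng.normal(0.0, sds[mk], size=n_total)
        Y[:, j] = y
    for row, grp in case_rows.items():
        for mk, shift in grp.marker_shifts.items():
            j = markers.index(mk)
            Y[row, j] += shift * sds[mk]
    # positivity guard for the pg/mL view; binds with probability ~1e-7
    Y = np.maximum(Y, 1e-6)
    log_levels = pd.DataFrame(Y, index=sample_ids, columns=markers)

    # causal CpG assignment and logistic readout
    cpg_ids = [f"cg{i:08d}" for i in range(config.n_cpgs)]
    perm = rng.permutation(config.n_cpgs)
    causal_map: dict[str, list[str]] = {}
    link_rows = []
    used = 0
    B = np.empty((n_total, config.n_cpgs))
    causal_cols = set()
    for mk in markers:
        k = config.n_causal_per_marker if mk in informative else 0
        cols = perm[used: used + k]
        used += k
        causal_map[mk] = sorted(cpg_ids[c] for c in cols)
        y = log_levels[mk].to_numpy()
        for c in cols:
            causal_cols.add(int(c))
            lo_s, hi_s = config.link_slope_range
            delta = float(rng.uniform(lo_s, hi_s)) * \
                (1.0 if rng.random() < 0.5 else -1.0)
            gamma = float(-delta * y.mean() + rng.normal(0.0, 0.3))
            noise = rng.normal(0.0, config.link_noise_sd, size=n_total)
            B[:, c] = _logistic(gamma + delta * y + noise)
            link_rows.append((cpg_ids[c], mk, gamma, delta))
    for c in range(config.n_cpgs):
        if c not in causal_cols:
            a = float(rng.uniform(0.5, 3.0))
            b = float(rng.uniform(0.5, 3.0))
            B[:, c] = rng.beta(a, b, size=n_total)
    beta = BetaMatrix(pd.DataFrame(B, index=sample_ids, columns=cpg_ids))

    levels = pd.DataFrame(np.expm1(Y), index=sample_ids, columns=markers)
    levels.index.name = SAMPLE_ID
    meta = pd.DataFrame({
        AGE: ages,
        "Sex": sexes,
        "DatasetID": datasets,
        "Status": status,
        "ICDChapter": chapters,
        "ICDCode": codes,
    }, index=sample_ids)
    meta.index.name = SAMPLE_ID

    truth = GroundTruth(
        log_levels=log_levels,
        causal_map=causal_map,
        age_slopes=slopes,
        intercepts=intercepts,
        noise_sds=sds,
        link_params=pd.DataFrame(link_rows, columns=["cpg_id", "marker",
                                                     "gamma", "delta"]),
        irreducible_mae_years=_irreducible_mae(config),
        level_age_correlation={
            mk: _level_age_correlation(config, mk in informative)
            for mk in markers},
    )
    return SynthCohort(beta=beta, markers=levels, meta=meta, truth=truth,
                       config=config)


def mask_entries(m: BetaMatrix, fraction: float, seed: int = 0
                 ) -> tuple[BetaMatrix, pd.DataFrame]:
    """Mask a uniform random ``floor(fraction * n_entries)`` of the matrix.

    Returns the masked matrix and a record of the masked positions with
    their true values, for imputation-error scoring."""
    if not 0.0 < fraction < 1.0:
        raise SynthError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    arr = m.values.to_numpy(dtype=float).copy()
    n_entries = arr.size
    n_mask = int(np.floor(fraction * n_entries))
    flat = rng.choice(n_entries, size=n_mask, replace=False)
    i, j = np.unravel_index(flat, arr.shape)
    record = pd.DataFrame({
        SAMPLE_ID: m.values.index.to_numpy()[i],
        "cpg_id": m.values.columns.to_numpy()[j],
        "true_value": arr[i, j],
    })
    arr[i, j] = np.nan
    masked = BetaMatrix(pd.DataFrame(arr, index=m.values.index,
                                     columns=m.values.columns))
    return masked, record


def default_fixture(seed: int = DEFAULT_SEED) -> SynthCohort:
    """The packaged cohort profile (see :class:`SynthConfig` defaults)."""
    return generate(SynthConfig(seed=seed))
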