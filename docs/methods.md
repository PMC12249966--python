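# Methods

## The two-level model

The package treats inflammatory proteins as an interpretable intermediate
between the methylome and age. Level 1 learns, for each marker, a mapping
from CpG beta values to the marker's log concentration; level 2 learns a
mapping from the vector of *estimated* log concentrations to chronological
age. The decomposition buys interpretability (age acceleration can be
attributed to named inflammatory markers, in years) at the price of a
bottleneck: the clock can only use inflammation-related methylation signal.
Both levels share one training protocol — 80/20 train+validation/test
split, 4-fold (3:1) cross-validation inside the train+validation part,
budgeted hyperparameter search minimising mean validation MAE, refit of the
winning configuration on the full train+validation split, and final
reporting on the untouched test subset.

### Feature selection (mRMR)

Relevance of a probe is the univariate regression F-statistic
`F = r²(n−2)/(1−r²)` against the (log-transformed) target; redundancy is
the mean absolute Pearson correlation with the probes already selected; the
greedy step maximises the quotient `relevance / max(redundancy, 1e-6)`,
with the first pick taken on pure relevance. Conventions that the
literature leaves open were fixed as follows and are part of this package's
contract: quotient rather than difference scoring (the dominant convention
for F-statistic mRMR in regression), sign-agnostic redundancy, ties broken
by lexicographic probe ID, and F capped at 1e12 so numerically perfect
correlations stay finite while preserving argmax order. Selection runs on
the train+validation split only; the test subset never influences which
probes a surrogate sees, so the gate's held-out correlation is honest.

### Target transform and gating

Cytokine panels are heavy-tailed and can contain true zeros, so targets are
`y = ln(level + 1)` with levels in pg/mL; the inverse `exp(y) − 1` is exact.
A marker enters the clock only if its surrogate's test-subset Pearson r
reaches the gate threshold (default 0.5, inclusive, so the stated threshold
is attainable). The threshold is configurable; the inclusive boundary and
the choice of the *test* subset (rather than validation) are package
decisions.

### Backends and hyperparameter search

Two regressor families satisfy one backend contract: `elasticnet`
(combined L1/L2 linear model; search over penalty strength 1e-4…10
log-uniform and l1_ratio 0.01…1) and `mlp` (feed-forward network; 1–3
hidden layers, width ∈ {16, 64, 256}, L2 weight decay 1e-6…1e-3 and initial
learning rate 1e-4…1e-2, both log-uniform, with early stopping). The search
is a sequential model-based sampler in the Tree-structured Parzen Estimator
style, written for this package: the first `startup_trials` configurations
are drawn uniformly; afterwards finished trials are split into the best
25% ("good") and the rest ("bad"), per-dimension Parzen densities (Gaussian
kernels plus a uniform prior component; category counts with add-one
smoothing) are formed over each, and the best of 16 candidate draws by
good/bad density ratio is evaluated next. The desk budget is 32 trials with
8 startup trials — enough for the two- and four-dimensional spaces above —
and a `paper` profile (1024 trials, 256 startup, 16 candidates) mirrors the
published protocol for full-scale runs. Every run is reproducible from one
integer seed.

Inputs are standardised per feature with mean/SD frozen from the
train+validation split; the statistics ship inside the trained model, so
prediction-time inputs need no preprocessing beyond imputation.

### Level-2 splitting

Within each dataset, samples are assigned to five empirical age quintiles
(quantile edges by linear interpolation; a sample exactly on an edge falls
in the lower group). If any quintile has fewer than five samples the whole
dataset is assigned to the test pool and contributes nothing to training —
small or age-degenerate datasets are evaluation-only. Otherwise the dataset
is split 80/20 within each quintile and cross-validation folds are dealt
round-robin inside the shuffled train+validation part, keeping the age
distribution balanced across folds. The clock is fitted on control samples
only; case samples are always predicted, never trained on, so disease
sensitivity cannot come from leakage.

## Shapley attribution

Predictions decompose as `base + Σ_j contribution_j`, with `base` the mean
prediction over a background set (up to 256 training samples, subsampled by
seed) and contributions in years. For linear backends the closed form
`w_j (x_j − mean background x_j)` on the standardised design is used —
exact, so local accuracy holds to floating point. For arbitrary backends a
permutation-sampling estimator (default 2048 permutations) inserts features
in random order, drawing absent coalition members from a background row;
background rows are cycled deterministically so the per-sample telescoping
sum equals `f(x) − mean_b f(b)` exactly, making additivity hold regardless
of how many permutations are affordable — the permutation count only
controls how the total splits among markers. Exact enumeration of all 2^d
coalitions is not attempted at the default panel size.

Per-sample reports add a cohort percentile per marker: the share of
samples within ±5 years of chronological age (a package default — "similar
age" is not standardised anywhere) with a strictly lower estimated level,
ties counting half; an empty window is widened once to ±10 years before
failing. Case/control contribution deltas aggregate within a dataset first
(mean case contribution minus mean control contribution) and then across a
chapter's datasets by unweighted mean.

## Disease-sensitivity battery

One test per (dataset, case group): two-sided Mann–Whitney U of age
acceleration in cases versus same-dataset controls. The p-value is exact by
enumeration when both groups have ≤ 8 observations without ties, otherwise
the normal approximation with midrank-tie and continuity corrections.
Datasets lacking ≥ 3 usable samples on either side are excluded (logged,
not failed). All raw p-values of one battery form a single
Benjamini–Hochberg family; a test passes if its adjusted p < α = 0.05.
Because the U test is direction-blind, each row also carries the signed
bias difference (mean case minus mean control acceleration, years). The
battery takes any prediction table with the standard schema, so externally
computed clocks can be scored identically.

## The synthetic cohort generator

The generator follows the causal direction the clock inverts:
age ~ Uniform(20, 90); each informative marker's log level is
`α_m + β_m·age/10 + N(0, σ_m²)` with slope β_m = ±0.3 per decade
(alternating sign across markers) and σ_m = 0.5 — giving a true level–age
correlation of ≈ 0.77 and an analytic irreducible clock error of ≈ 5.1 y
MAE, the same order as real inflammatory clocks; each of the marker's 40
causal CpGs reads the realised log level through a logistic link
(slope magnitude U(0.3, 0.8) with random sign, intercept centring the
probe, link noise SD 0.15), which keeps betas strictly inside (0, 1)
without clipping; the remaining probes are independent Beta(a, b) noise
with per-probe shapes in U(0.5, 3). Null markers have zero age slope *and*
zero causal CpGs — they are invisible to the methylome, which is what makes
the gate's reject decision well-defined. Disease case groups receive a
configured shift (default +0.8 σ_m) on selected markers *before* the CpG
readout, so the disease signal propagates through methylation exactly as
the pipeline assumes; the default shifted markers (MK1, MK3, MK5) share a
slope sign so the induced effect is a coherent age acceleration rather than
a cancellation. The default profile is 500 controls in 4 datasets plus two
case groups of 30, 2,000 CpGs, 8 markers (6 informative), seed 20250629.

The stored ground truth (true log levels, causal map, link coefficients,
and the analytic irreducible MAE
`sqrt(2/π) · [1/Var(age) + Σ_m (β_m/10)²/σ_m²]^{-1/2}`) lets recovery tests
compare against latents rather than re-simulation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-type and batch effects, realistic
cytokine–cytokine covariance beyond the shared age factor, non-linear
age trajectories, assay floor/ceiling censoring, and the massive
probe count of real arrays (2,000 CpGs stand in for ~400k; mRMR's rank
ordering is the same algorithm either way, but selection noise differs).
Recovery results on this cohort demonstrate correctness of the machinery,
not clinical validity.

## Numerical and edge-case choices

- Beta values outside [0, 1] beyond 1e-9 are errors, never clamped;
  imputation is explicit (`knn` with k = 5 by default via nan-Euclidean
  distances, or per-CpG `mean`/`median`) and observed entries pass through
  bitwise. A fully missing CpG column is an error naming the probe.
- Missing marker levels drop that (sample, marker) pair; level-1 targets
  are never imputed.
- Zero-variance features score zero relevance and are never selected;
  a constant target is an error.
- Pearson r is reported as NaN with a warning when either side of a group
  is constant (degenerate for correlation).
- All splits, searches, maskings and attributions are driven by explicit
  integer seeds; repeated runs are bit-identical, and the CLI's bundle
  records seed, budget profile and package version.

## Problem sizes

Defaults are sized for a single-CPU desk run: the 560-sample, 2,000-CpG
cohort trains the full two-level pipeline (8 surrogate searches of 32
trials × 4 folds plus the clock search) in well under a minute per seed
with the ElasticNet backend; recovery properties are checked over 10
replicate seeds. The `paper` budget profile and larger `SynthConfig`
settings scale the same code up when more compute is available.

## Known limitations

- The neural backend is a generic multi-layer perceptron; specialised
  tabular architectures (attention- or gating-based) are intentionally out
  of scope, and the backend contract is what the package guarantees.
- The TPE-style sampler models dimensions independently; it will not
  exploit strong hyperparameter interactions.
- Surrogate and clock uncertainties are reported as held-out metrics, not
  per-sample prediction intervals.
- The battery treats tests as exchangeable within one BH family; no
  meta-analytic pooling across datasets is attempted.
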