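# Methods

This package implements, end to end, a neuroexposomic analysis: predicting
a resting-state brain-network summary (global efficiency) from multi-media
metal-exposure biomarkers with a gradient-boosted model, leave-one-out
cross validation, and Shapley attribution. Because the motivating cohort
data are available only on request, the package is driven by a synthetic
cohort generator whose statistical structure matches what the analysis
assumes, including a planted exposure effect used for recovery testing.
This note documents the models, the defaults and why they are what they
are, the numerical choices, and what the synthetic results do and do not
establish.

## Synthetic cohort

**Demographics.** `gen_cohort(n, female_frac, age_range, seed)` draws a
cohort with exactly `round(n * female_frac)` females and ages uniform on
`age_range`. Defaults (57% female, ages 13–25) match the adolescent cohort
the analysis emulates.

**Biomarkers.** Each of the 36 metal x medium cells is log-normal:
`ln(concentration) ~ Normal(ln GM, ln GSD)`, parameterised by the built-in
reference table (`neuroexposome.reference`) of geometric means, geometric
standard deviations and detection limits for Mn, Pb, Cr, Cu, Ni and Zn in
saliva, hair, fingernails, toenails, urine and blood. Units are µg/L for
fluids and µg/g for keratinous media. Media of one metal share a latent
standard-normal factor with loading `sqrt(corr)`, giving every
within-metal media pair log-scale correlation `corr` (default 0.3, a
moderate cross-media dependence; the single-factor form is the simplest
structure consistent with reporting correlations but no generative model).
Values below the cell's LOD keep their sampled value and are flagged
`censored`; the LOD-substitution stage later replaces them by LOD/√2.

One reference value required repair: the tabulated blood-nickel GSD of
0.136 is impossible (a geometric SD is `exp` of a standard deviation of
logs, hence always ≥ 1). The stored value 2.715 is imputed so that the
log-normal with the tabulated GM and LOD reproduces the tabulated
detection rate (81% above LOD) exactly, and sits inside the nickel GSD
range of the other five media (2.57–5.52).

**Planted effect.** `plant_effect` builds a latent per-subject *coupling*
score: baseline plus `sign * magnitude * z(ln concentration)` summed over
the target features (default: urinary Pb with sign −1, blood Zn with sign
+1, magnitude 1.0), plus small age and sex terms (0.2 SD each, so the
age/sex adjustment downstream has something real to remove). The
`threshold` link replaces `z` by its sign for hard exceedance effects. A
logistic transform of coupling is stored as the latent "true" efficiency;
it exists only for ground-truth checks and is never read by any analysis
stage — the effect must be recovered through the whole measurement chain.

**Time series.** Each subject gets a 111-node, 600-frame (TR = 1 s)
multivariate-normal series from a modular correlation matrix (4 modules).
Per-pair latent strengths are heterogeneous: within-module pairs ~
Normal(0.40, 0.06), between-module pairs ~ Normal(r_b, 0.08) with

    r_b = 0.25 + 0.10 * tanh(coupling / 2),

both clipped to [0, 0.9]. The heterogeneity is essential, not cosmetic:
proportional thresholding keeps a fixed *number* of edges, so any change
that preserves the rank order of edge strengths leaves the binary graph —
and hence global efficiency — untouched. A uniform shift of well-separated
between-module strengths does exactly that (we measured Spearman ≈ 0 from
such a design). With overlapping strength distributions, raising r_b moves
between-module pairs past within-module pairs in rank, the retained graph
gains inter-module shortcuts, and efficiency rises smoothly with coupling.
With the defaults the full chain transmits strongly: Spearman(measured GE,
coupling) ≈ 0.98 at n = 60–124, T = 600.

The innovation frames are filtered to AR(1) with coefficient `ar1`
(default 0.4, a typical short-TR BOLD value) in variance-preserving form
`x_t = φ x_{t−1} + sqrt(1−φ²) e_t`, which keeps lag-0 cross-correlations
equal to the latent matrix while giving every node lag-1 autocorrelation
φ. Nuisance contamination adds six motion series, one WM and one CSF
series — unit-variance smoothed random walks — through random node
loadings (SD 0.35) scaled by `nuisance_amp` (default 1.0, making nuisance
variance comparable to signal variance so the conditioning stage has real
work to do).

*Positive-definiteness.* Independent per-pair draws routinely make the
assembled matrix slightly indefinite (minimum eigenvalue of order
−sd·√N ≈ −0.9 at N = 111 — ordinary random-matrix spread, not a defect).
The repair is eigenvalue clipping at 1e−6 followed by diagonal
renormalization, applied silently in that regime; a minimum eigenvalue
beyond 2.5·sd·√N indicates a structural problem and warns first. The
repair preserves rank structure in practice (the ≈ 0.98 transmission
above is measured after repair).

## Conditioning (two-step GLM prewhitening)

Per subject and node: (1) residualize the raw series on the 6 motion
parameters; (2) estimate a per-node AR(1) coefficient as the lag-1
autocorrelation of those residuals, clipped to ±0.999; (3) remove the
AR(1) structure from the *raw* series, `y′_t = y_t − φ y_{t−1}` with the
first sample scaled by `sqrt(1−φ²)` (exact GLS whitening, keeping series
length); (4) residualize the whitened series on motion + WM + CSF. All
designs include an intercept; collinear columns are dropped with a
warning. Whitening the raw data (rather than the step-1 residuals) is
deliberate; `textbook_order=True` selects the textbook variant. Per-node
(not pooled) AR estimation reflects that autocorrelation genuinely varies
across regions. Measured on defaults, conditioning takes mean |lag-1
autocorrelation| from ≈ 0.65 to ≈ 0.03, and step-4 residuals are
orthogonal to all confounds at machine precision.

## Connectome and global efficiency

Pearson correlations between conditioned node series; proportional
thresholding keeps the top `round(density * N(N−1)/2)` positive
correlations (ties broken by larger r, then smaller node indices;
negative correlations are never retained — hop-count path language
presumes a binary graph of positive couplings). Default density 0.15,
the common middle of the proportional-thresholding range; the analysis
driver sweeps 0.05–0.40 and shows the efficiency *ranking* is stable
across 0.05–0.30 (rank correlation ≥ 0.93 vs the default) and only
degrades at 0.40 where the graph saturates.

Hop counts come from breadth-first search (`scipy.sparse.csgraph`);
global efficiency is the mean over ordered node pairs of inverse
distance, `GE = (1/(N(N−1))) Σ_{i≠j} 1/d_ij`, with disconnected pairs
contributing 0 (standard convention). GE is 1 iff the graph is complete
and 0 for an empty graph.

Cohort post-processing: min-max scaling to [0, 1] (`scale_mode="max"`
divides by the maximum only, for the alternative reading of "1 = cohort
maximum"), then age/sex adjustment as standardized OLS residuals (mean 0,
SD 1 with the sample SD) — the only adjustment consistent with reported
adjusted scores spanning roughly −2 to 4.

## Prediction

XGBoost regression behind a narrow wrapper (`GradientBooster`). The
estimand is out-of-sample: every subject's prediction comes from a model
trained on the other n−1 (LOOCV). Hyperparameters — learning rate and L1
penalty log-uniform on [0.01, 0.3] and [1e−3, 10], depth 2–6, subsample
0.5–1, 50–500 rounds — are chosen by random search, each candidate scored
by full-LOOCV mean squared error (MSE, not r: r is scale-free and can
reward degenerate constant-plus-noise predictors). The default budget is
500 candidates; the analysis driver uses 25 (with n = 124 that is already
3,100 model fits; the search surface is shallow enough that 25 draws find
a competitive optimum) and the tests use fewer still. Evaluation is
Pearson r between out-of-fold predictions and observations, the two-sided
p from the t transform with n−2 df, and explained variance VE = r².

Determinism contracts worth noting: training rows are canonically sorted
by subject id before every fit, so predictions are invariant to input row
order even with subsampling; per-fold seeds derive from (seed, held-out
position); and `base_score` is pinned to the training-label mean, so a
constant target is predicted exactly. The default target is the
age/sex-adjusted score (`ge_adj`); `ge_scaled` is accepted via config.

## Attribution

Interventional Shapley values with the training matrix as background: the
value of a coalition S is the model prediction averaged over background
rows with the features in S taken from the subject. Two independent
routes: `shapley_exact` enumerates all 2^M coalitions for any black-box
predictor (M ≤ 15) — the oracle; `tree_shap` computes the same quantity
exactly in polynomial time from the tree structure. For each (subject,
background row, leaf), the path constraints partition the path's features
into a set A that must come from the subject and a set B that must come
from the background row; the leaf value then contributes
`|A|!|B|!/(|A|+|B|+1)!`-weighted terms to each feature in closed form.
The two routes agree to ~1e−15 on small ensembles; local accuracy
(base value + Σ attributions = prediction) is asserted whenever an
`AttributionSet` is constructed.

Tree structure is read from the booster's raw JSON (exact float32 leaf
values) and split comparisons are evaluated in float32, matching the
booster's routing bit for bit; leaf sums accumulate in float64, so
agreement with the booster's own float32-accumulated output is ~1e−6 per
20 trees. Attributions are computed from the final model trained on all
subjects; global importance is mean |SHAP| per feature sorted descending
(ties alphabetical), and the beeswarm export carries a per-feature
Spearman(feature value, SHAP value) sign diagnostic.

Features enter the model as raw (LOD-substituted) concentrations, not
logs: tree ensembles are invariant to monotone transforms, so the choice
only affects the beeswarm x-axis, and both plots are exportable.

## What the generator does and does not emulate

Emulated: log-normal biomarker marginals with realistic parameters,
cross-media dependence, LOD censoring, modular functional connectivity,
AR(1) serial structure at TR = 1 s, additive motion/WM/CSF contamination,
age/sex effects on the outcome, and a monotone exposure → connectivity
effect.

Not emulated: spatial geometry of parcels (no distance-dependent
connectivity), hemodynamic response and nonstationarity, non-Gaussian
BOLD artifacts (spikes, scanner drift beyond smooth walks), rigid-body
motion (nuisance enters additively, not as resampling), richer
exposure-correlation structure across metals, and any real
exposure–brain effect size. Consequently, passing recovery tests shows
the *pipeline* is correct and that effects of the planted form and
magnitude are recoverable through it — not that real effects have that
magnitude, nor that the real analysis would reach the same feature
ranking. The performance reported for the original private-cohort
analysis (r = 0.36, VE = 13% at n = 124) is intentionally not a target
of any test; the synthetic chain at magnitude 1.0 transmits far more
signal than that.

## Problem sizes and runtime choices

Unit tests use the smallest sizes that make each contract sharp
(Monte-Carlo checks at T = 20,000–100,000 for scalar recoveries; n = 14–60
cohorts elsewhere). The end-to-end recovery tests run 10 cohorts of
n = 100 at full T = 600, N = 111 with a fixed, mid-range hyperparameter
configuration (learning rate 0.1, depth 3, α = 0.1, 120 rounds) rather
than re-tuning per seed — tuning is validated separately and would
multiply runtime ~25-fold without changing what the test demonstrates.
The whole suite runs in a few minutes on one CPU.

## Known limitations

- The exact enumeration oracle is limited to 15 features; `tree_shap`
  itself scales as subjects x background x leaves and is comfortable at
  124 x 124 x a few hundred trees, but is not optimised for thousands of
  subjects.
- Proportional thresholding at very high density (≥ 0.4) saturates the
  graph and destroys the efficiency ranking; the density sweep in the
  analysis driver quantifies this.
- LOOCV gives each model n−1 training rows but is known to have high
  variance as an estimator of generalization; k-fold/bootstrap
  alternatives are out of scope by design.
- `binarize_proportional` can return a sparser graph than requested when
  fewer positive correlations exist than the target edge count (it warns);
  at realistic densities this does not occur.
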