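# Methods

This note documents the models, the synthetic-data recipe, the feature
definitions and the numerical/design choices behind `sptclass`, in the
package's own terms.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Stochastic models and exact sampling

All trajectories are 2D with independent coordinates on the uniform grid
`t_i = i·Δt`, positions in μm, started at the origin.

**Fractional Brownian motion.**  `X = σ B^H` with
`E[B^H_t B^H_s] = (t^{2H} + s^{2H} − |t−s|^{2H})/2`.  Increments over the
grid are fractional Gaussian noise; we sample them *exactly* with
Davies–Harte circulant embedding: the 2N-point circulant extension of
the fGn autocovariance is diagonalised by the FFT and its (provably
nonnegative for H ∈ (0,1)) eigenvalues drive a complex-Gaussian
synthesis.  Cost is O(N log N) per coordinate, trivial at N ≤ 500.  A
Cholesky factorisation of the covariance matrix stands by for the case
of numerically negative eigenvalues (tolerance `1e-8` relative to the
largest; not expected to trigger in the supported H range).  Grid
self-similarity is used to scale unit-grid noise by `σ Δt^H`.  H = ½
short-circuits to i.i.d. Gaussian steps — same law, cheaper.  No
approximation scheme (Euler, truncated spectral) is used anywhere.

**Directed Brownian motion.**  `X_{i+1} = X_i + vΔt + σ√Δt ξ_i` — exact
for constant drift.

**Ornstein–Uhlenbeck.**  The exact Gaussian transition
`X_{t+Δt} = θ + (X_t − θ) e^{−λΔt} + η`,
`Var η = σ²(1 − e^{−2λΔt})/(2λ)` (Brownian limit `σ²Δt` at λ = 0),
evaluated per coordinate with an AR(1) filter.  Euler–Maruyama is
deliberately avoided: with Δt = 1 s and λ up to 1 s⁻¹ its one-step mean
factor `1 − λΔt` (down to 0) badly distorts the stationary law, while
the exact factor `e^{−λΔt}` ≥ 0.37.

**Seeding.**  Every trajectory owns a `numpy` generator seeded from
`(master_seed, trajectory_index)`, so datasets are reproducible,
order-independent, and dataset *variants* built from the same master
seed share their underlying draws (common random numbers).  That last
property is what makes small between-variant differences — e.g. the
accuracy ordering across cutoff values — measurable at reduced scale
without inflating the simulation budget.

## Dataset recipe

The base set (full scale) holds 120,000 trajectories, 40,000 per mode:

| mode   | model | parameters                  | count  |
|--------|-------|-----------------------------|--------|
| normal | FBM   | H ~ U[0.5−c, 0.5+c]         | 20,000 |
| normal | DBM   | v₁,v₂ ~ U[0, c]             | 10,000 |
| normal | OU    | λ₁,λ₂ ~ U[0, c], θ = 0      | 10,000 |
| sub    | FBM   | H ~ U[0.1, 0.5−c)           | 20,000 |
| sub    | OU    | λ₁,λ₂ ~ U(c, 1]             | 20,000 |
| super  | FBM   | H ~ U(0.5+c, 0.9]           | 20,000 |
| super  | DBM   | v₁,v₂ ~ U(c, 1]             | 20,000 |

with c = 0.1, σ = 1 μm·s^(−1/2) (D = 0.5 μm²/s), Δt = 1 s and lengths
uniform on 50..500 steps ("length" = number of steps; a track has L+1
positions).  Half-open ranges are sampled as closed uniforms with
rejection of the excluded endpoint — the endpoint has probability zero,
rejection keeps the stated set literally.  At c = 0 the normal cells
degenerate to exactly H = 0.5, v = 0, λ = 0.

The cutoff c is a *labelling* parameter: anomalous parameters inside the
band are deliberately labelled normal, because such weak anomaly is
statistically indistinguishable from Brownian motion at these lengths.
Ground truth attaches to the generating parameters, never to the
realised track, and is therefore invariant under noise injection.

**Variants.**
*Noise*: each coordinate of each position gets i.i.d. N(0, σ_Gn²) with
σ_Gn set from a per-track signal-to-noise ratio Q ~ U[1,9]:
`σ_Gn = √(DΔt + |v|²Δt²)/Q` for DBM and `√(DΔt)/Q` otherwise.
*Rescaled*: σ = 0.38, i.e. D = 0.0715 μm²/s, the regime typical of
membrane-protein data.
*Varying mobility*: D ~ U[1,9] per trajectory, σ = √(2D); the true D is
recorded with the generating spec but the feature `D` is always
estimated from the TAMSD.
*Cutoff sweep*: c ∈ {0, 0.001, 0.01, 0.1}.

**Split.**  70%/30% train/test, stratified by mode with per-class
rounding, so balanced sets stay exactly balanced.  (Plain shuffling
would only approximate the exactly balanced test support the evaluation
conventions assume.)

## Features (Set A)

For a track of N steps, with TAMSD
`ρ(n) = (1/(N−n+1)) Σᵢ ‖X_{i+n} − X_i‖²` computed for lags
`n = 1..n_max`, `n_max = max(2, ⌊0.1·N⌋)` (the 10% window; longer
windows average too few displacements at large lags and were found
slightly worse in the source analyses):

1. **α** — slope of the OLS fit of `log ρ(n)` on `log(nΔt)`.
2. **D** — `exp(intercept)/4` from the same joint fit (2D convention
   `ρ = 4Dt^α`).  Zero-valued lags are dropped; fewer than two positive
   lags returns (0, 0).
3. **MSD ratio** `κ = mean_n [ρ(n)/ρ(n+1) − n/(n+1)]`, n = 1..n_max−1;
   zero-denominator terms are skipped.  Note the ratio estimator keeps a
   small positive O(1/N) Jensen bias even for Brownian motion.
4. **Efficiency** `E = ‖X_N − X_0‖² / (N Σ‖X_i − X_{i−1}‖²)` ∈ [0, 1].
5. **Straightness** `S = ‖X_N − X_0‖ / Σ‖X_i − X_{i−1}‖` ∈ [0, 1].
6. **Velocity autocorrelation** `χ = (1/(N−2)) Σ (X_{i+2}−X_{i+1})·(X_{i+1}−X_i)`
   — un-normalised (μm²), lag 1 at point 1; strongly negative for
   anti-persistent (low-H) motion and the single most informative
   feature in practice.
7. **Maximal excursion** `ME = maxᵢ‖X_i − X_{i−1}‖ / ‖X_N − X_0‖` — the
   numerator is the largest *single step* ("jump"), distinguishing it
   from the mean-maximal-excursion statistic.
8. **p-variation statistic** P ∈ {−1, 0, +1}.  For each
   p ∈ {1, 2, 3, 4, 5}, `V_m(p) = Σ_{i=0}^{⌊N/m⌋−1} ‖X_{(i+1)m} − X_{im}‖^p`
   over block sizes m.  A profile "changes monotonicity" iff its
   successive differences contain both signs; among such p the largest
   is classified by the sign of the summed second differences (+1
   convex, −1 concave; an exact zero ties to 0), and P = 0 if no profile
   changes monotonicity.

Degenerate tracks use documented zero conventions (closed loop → ME = 0;
fully stationary → E = S = ME = 0 with a warning) rather than NaN, so
feature vectors are always finite.

**Open conventions made explicit.**  The m-grid is
`m ∈ {1..min(⌊N/2⌋, max(3, ⌊N/10⌋))}`, thinned evenly to ≤ 50 points:
⌊N/10⌋ keeps ≥ 10 blocks per scale, the floor of 3 grid points keeps
the monotonicity test defined down to the 10-step minimum, and the cap
bounds cost on long tracks.  D is fitted jointly with α (not with α
fixed at 1).  Norms are Euclidean over the 2D displacement everywhere.

## Classification

Random forest and gradient boosting from scikit-learn, wrapped as
`DiffusionModeClassifier` (model) / `DiffusionModeResults` (fitted
results).  Class probabilities are the ensembles' own
`predict_proba` — per-tree class-frequency averages for RF, normalised
staged scores for GB — so the argmax of the probabilities equals the
predicted label by construction.  The shipped defaults are the tuned
configurations for the base recipe (RF with D: 800 trees, max_depth 80,
√-feature subsampling, gini, min_samples_leaf 4; RF no-D: 600 trees,
depth 10, entropy; GB: 900/50 and 100/10).  The depth-80 setting is an
artefact of randomized tuning — the deepest tree actually grown is far
shallower — and is kept as the reference configuration rather than
"fixed".  GB learning rate and subsampling stay at library defaults.
Randomized search samples each hyperparameter uniformly from discrete
sets (n_estimators 100..1000, depth 10..110 or unlimited, etc.), scores
by k-fold CV accuracy, and breaks ties toward the earliest sample.

## Evaluation

Accuracy; per-class precision/recall/F1 with unweighted (macro)
averages — on exactly balanced test sets macro equals support-weighted
averaging; row-normalised confusion matrices stored unrounded (display
rounds to 2 decimals); permutation importance = baseline accuracy minus
mean accuracy over n shuffles of one column (default n = 5; computed on
the held-out partition, since train-side importances reward
overfitting); predicted-label histograms binned along a generating
parameter with the cutoff band attached for overlay.

## Problem sizes and reproducibility

The acceptance script and the end-to-end tests run every recipe at 1/10
of the full counts — 12,000 trajectories, 4,000 per mode, 3,600 test
tracks — which the package treats as its standard benchmark scale: the
binomial standard error on an accuracy of ~0.95 at n = 3,600 is ~0.004,
comfortably inside the ±0.015 band used by the end-to-end checks, and a
full run (simulate → featurize → train 800 trees → evaluate) takes well
under a minute per variant on one CPU.  Every random draw traces to one
master seed.

## What the synthetic data does and does not emulate

The generator reproduces homogeneous, uniformly sampled, 2D tracks of
three specific models with independent coordinates and (optionally)
i.i.d. Gaussian localisation error.  Real SPT data additionally show
mode switching within single tracks, motion blur and correlated
localisation error, drift of the field of view, and processes outside
the three-model family (CTRW-like trapping, heterogeneous D along a
track).  Passing benchmarks here therefore certifies the pipeline on
the stated model family, not classifier validity on arbitrary
experimental data — classifiers trained on one family are known not to
generalise automatically.  The CSV reader and `predict` subcommand
apply a 50-step minimum length by default because the TAMSD window and
p-variation profiles of shorter tracks are too noisy to trust.

## Known limitations

* Only 2D tracks on uniform grids; no gap handling beyond rejection.
* The three-model family excludes CTRW, Lévy flights, FLE/ARFIMA.
* Probabilities are raw ensemble votes/scores, not calibrated.
* Feature extraction is per-track Python/NumPy; ~2–3 ms per track is
  fine up to ~10⁵ tracks but not optimised beyond that.
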