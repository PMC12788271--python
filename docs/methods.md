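# Methods

This note documents the models implemented in `dynawa`, their assumptions,
the tunable parameters that matter, and the numerical choices made where
the design was genuinely open.

## Synthetic spectra generator

The generator emulates an arid-basin soil survey: SOM concentrations are
drawn from a Gaussian (mean 14.85 g kg⁻¹, sd 6.6 g kg⁻¹) truncated to
[0.09, 66.46] g kg⁻¹, so the sample mean, range and coefficient of
variation match the emulated survey's summary statistics. Reflectance on a
1-nm 400–2400 nm grid is

```
R(λ) = baseline(λ) − Σ_c a_c · (SOM/SOM_max)^γ · exp(−(λ−c)²/2σ_c²) + ε(λ)
```

with absorption centres c ∈ {580, 920, 1390, 1920} nm, widths σ_c ∈
{60, 80, 70, 90} nm, maximal depths a_c ∈ {0.08, 0.10, 0.14, 0.18}
reflectance units, nonlinearity γ = 1.5 and i.i.d. noise
ε ~ N(0, 0.005²), clipped to [0, 1]. The smooth SOM-independent baseline
rises from ~0.25 in the visible to ~0.52 in the NIR.

Choices and what they mean:

* **γ = 1.5** makes the spectra→SOM map monotone but curved, so flexible
  learners genuinely outperform purely linear ones — the regime the
  weighting strategies are designed to exploit.
* **noise_sd = 0.005** reflectance units is a realistic post-averaging
  noise level for contact-probe measurements (each real spectrum is a mean
  of ten scans); it was fixed once and applies to all experiments.
* **What the generator does *not* model:** per-sample multiplicative
  scatter and baseline drift, water-vapour artefacts, heteroscedastic
  assay error, and outlier samples. The synthetic task is therefore
  *cleaner* than real soil spectroscopy: absolute accuracies here are
  higher than on field data, and conclusions that depend on evaluation
  indices being unreliable (a property of noisy, heterogeneous real data)
  need not transfer — see "Known limitations".

## Preprocessing

Trimming keeps the closed interval [400, 2400] nm (the ends of the
instrument range are noise-dominated). Savitzky–Golay smoothing uses an
11-point window and polynomial order 2; the filter reproduces any
degree-≤2 signal exactly at interior points. Edges use mirror-reflect
padding so output length equals input length; the test-suite oracle (an
explicit windowed least-squares polyfit) uses the same convention.

## Kennard–Stone splitting

Distances are Euclidean on the (preprocessed) reflectance matrix. The seed
sample is the one closest to the mean spectrum; `classic_init=True` gives
the textbook variant that starts from the two mutually most distant
samples. Thereafter the greedy max-min rule adds, at each step, the sample
whose minimum distance to the current calibration set is largest. Ties
break to the lowest sample index, making the procedure fully
deterministic. The 2:1 rule takes validation = ⌊n/3⌋, which maps 704
samples to 470/234.

## GA band selection

Chromosomes are Boolean masks over wavelength columns; length is bound to
the actual grid (a printed chromosome length that disagrees with the grid
is rejected rather than padded). Reference configuration: population 135,
mutation rate 0.03 per bit, crossover rate 0.8, 100 generations,
roulette-wheel selection, single-point crossover, and elitism — the best
individual always survives, which guarantees a non-decreasing best-fitness
curve (asserted every run). Offspring that would select no band are
repaired by activating one random bit.

Fitness evaluators: cross-validated R² of lasso/ridge/plain linear fits on
the selected columns ("LR" is read as plain linear regression — logistic
regression is undefined for a continuous target); mean |Pearson r| with
zero-variance columns scoring 0; and a maximal-information-coefficient
estimate. The MIC is an equipartition approximation: quantile grids of
shape (nx, ny) with nx·ny ≤ n^0.6 are searched and MI/log(min(nx, ny))
maximised. The exact MIC additionally optimises partition boundaries, so
this estimate is a (close) lower bound; it is used only for ranking masks.

## The learner registry

Thirty-four regressors in three buckets: 9 tree-based (TM), 15 flexible
nonlinear (DL), 10 linear/regularised/instance-based (LRM). Printed
reference hyperparameters are the defaults (RF 770 trees depth 2, GBRT 560
trees lr 0.1, XGBoost 190 depth 3 lr 0.2, LightGBM 130 depth 4 lr 0.05,
ExtraTrees 330, HGBR 400 iterations with absolute-error loss, AdaBoost 480
lr 0.1; SVR linear kernel C=1.0, PLSR 3 components, Tweedie power 0, KNR
k=10 uniform, Ridge/Lasso/ENR α=1.2 with ENR mixing 0.65, GAM spline
smoothing 0.7, ARS per-feature polynomial degree 9 with a regularisation
grid [1e-4, 1e-3, 1e-2, 1e-1], RVR with an RBF kernel basis; MLP 100
hidden units, CNN with four convolution layers 16→128 of width 3, LSTM 60
/ RNN 64 units with dropout 0.2, ELM 64 hidden neurons, GAN generator
input 24 with 256 hidden units). A **fast profile** shrinks tree counts
(≈25–60) and training epochs (≈25) without changing the model set; all
desk-scale experiments and the acceptance script use it.

Composition notes:

* The DL bucket holds the neural members plus two non-neural flexible
  models (MARS-style hinge regression, Gaussian-mixture regression); the
  three-way bucket sizes 9/15/10 are a fixed registry invariant and the
  bucket is best read as "flexible nonlinear" rather than strictly "deep".
* The "CatBoost" slot is gradient boosting with CatBoost's printed
  hyperparameters on a scikit-learn backend (`backend` field says so).
* Neural members run on a small in-package numpy toolkit (`dynawa.nn`)
  with explicit forward/backward passes, trained by full-batch Adam on
  MSE; a finite-difference gradient check in the test suite guards every
  layer type. Activations are identity ("linear") as printed, with ReLU
  and tanh variants for diversity; the LSTM keeps sigmoid gates because a
  fully linear LSTM degenerates to a linear map. Recurrent models read a
  spectrum as a short sequence of contiguous wavelength chunks (10 steps
  by default) — sequence semantics at tractable cost.
* The extreme learning machine uses the classical closed form: a fixed
  random hidden layer plus a ridge readout. The autoencoder trains
  reconstruction by Adam and fits a ridge readout on the code (denoising
  variant adds input noise). The GAN regressor trains a generator on MSE
  plus a small adversarial term from a discriminator separating true from
  generated targets.
* RVR is realised as an RBF kernel basis with a sparse Bayesian
  (automatic-relevance-determination) linear fit — the standard
  relevance-vector construction.

Training protocol: each learner is trained on the calibration set with
k-fold cross-validation (10 folds by default; desk-scale experiments use
5). Out-of-fold predictions — every sample predicted by the model not
trained on its fold — feed the weighting strategies without leakage; a
refit on the full calibration set predicts validation samples. Folds are
balanced, assigned from a seeded permutation, deterministic in (seed, n,
folds). A learner whose fit raises is never dropped: its column falls back
to training-fold target means and the failure is recorded with a warning.

## The eight weighting strategies

All return a simplex vector (w ≥ 0, Σw = 1 within 1e-9). Strategies that
need targets use calibration out-of-fold predictions.

* **R² normalisation** — wᵢ = max(R²ᵢ, 0)/Σⱼ max(R²ⱼ, 0); equal weights if
  no learner beats the mean predictor. The evaluation-index baseline.
* **Adaptive learning** — per-learner scores Sᵢ = 1 − MAEᵢ/mean(MAE) from
  the training trace (the mean is across learners), min-max normalised to
  [0, 1], then sum-normalised. All-equal MAE degenerates to equal weights.
* **Self-attention** — each learner's prediction column is z-scored
  (zero-variance columns become all-zero feature vectors), optionally
  projected by a linear map, and scored against every column by the
  *scaled* dot product hᵢ·hⱼ/√d. Scores are reduced per learner by the row
  mean and softmax-normalised. The √d scaling (standard scaled-dot-product
  attention) is needed because raw dot products over hundreds of samples
  give softmax logits of order 10², collapsing the weights onto a single
  learner; it is a monotone per-run constant, so the ranking of learners
  is unchanged. By default the projection is the identity (the similarity
  structure of the predictions themselves); `AttentionConfig(trained=True)`
  instead learns a low-dimensional projection by Adam on the ensemble MSE.
* **Q-learning** — states are weight vectors discretised to a δ-grid
  (δ = 0.05; a tabular Q-function needs a finite state space), actions add
  δ to one coordinate and renormalise, the reward is the drop in ensemble
  MSE scaled by 1/var(y) (so rewards are dimensionless and comparable
  across data sets). The update is applied exactly as the source method
  prints it, Q ← (1−a)Q + (r + γ·maxQ′) — note the target term is *not*
  multiplied by the learning rate; `standard_update=True` gives the
  textbook rule Q ← Q + a(r + γ·maxQ′ − Q). ε-greedy exploration, start at
  1/K, stop on episode budget or weight change < 1e-4; the visited state
  with the best ensemble MSE is returned.
* **Adaptive filter** — projected gradient descent on J(w) = MSE(Pw, y)
  with ∇J = (2/N)Pᵀ(Pw − y); after each step negatives are clipped and the
  vector renormalised. Default step size is the inverse Lipschitz constant
  2σ_max(P)²/N. 100 iterations.
* **Adam** — the same objective and projection with bias-corrected moment
  estimates (lr 0.2, β₁ 0.7, β₂ 0.97, 120 iterations).
* **GA** — simplex-valued individuals (Dirichlet-initialised, the
  equal-weight vector always included), fitness −RMSE, roulette selection
  on shifted-positive fitness, arithmetic crossover, mutation replaces one
  coordinate with a uniform draw, elitism. 100 generations.
* **Meta-learning** — a depth-limited regression tree (depth 6) stacked on
  the K prediction columns; weights are its normalised impurity-reduction
  importances, so a column never used by any split gets weight 0. One
  global weight vector is produced (the per-instance reading of stacking
  is out of scope). Constant targets degenerate to equal weights.

The optimising strategies (af, adam, ga, ql) return the best iterate seen,
so their training MSE never exceeds the equal-weight start — this
"best-seen" contract is asserted by the test suite on fuzzed inputs.

## Ensemble utilities

`combine` checks learner-name alignment before computing Pw (positional
matching is never silent). `evaluate` reports R² = 1 − SSres/SStot and
RMSE, and raises on constant targets. The **weight history** is a singly
linked list of timestamped weight vectors with metric snapshots: head =
initial weights, appends at the tail with strictly increasing step ids,
`rollback_best` returns the node with minimal snapshot RMSE, and the whole
structure round-trips through JSON.

The **learner-count curve** ranks learners by individual validation R²
(ties: lower RMSE, then name) and recomputes the chosen strategy's weights
on the top-k calibration columns for k = 2..K. The plateau is the smallest
k after which R² changes stay below tol = 0.002 for 3 consecutive
increments (both configurable). On clean synthetic data the curve is flat
almost from the start — the top two learners already explain ~99 % of
variance — so detected plateaus are small; the gradual-rise-then-plateau
shape seen on real data needs learner errors that are larger and more
diverse than this generator produces.

**Loss tracking** runs an iterative strategy (af/adam/ql/ga) for up to 160
iterations, recording calibration MAE (averaged over CV folds when fold
assignments are known) and validation MAE per iteration, and early-stops
when validation MAE has not improved for `patience` iterations (default
15). Early stopping is the natural reading of a stop mechanism tied to a
configured maximum iteration count.

## Determinism

Every stochastic component takes an explicit seed. The pipeline fans one
global seed out to per-stage seeds by stable hashing (CRC32 of
"stage:seed", kept below 2³¹), so a fixed seed reproduces the entire run
bit-for-bit while stages remain independently re-runnable.

## Desk-scale problem sizes

The package's own experiments (tests, examples, acceptance script) run the
default study shape — 704 samples, 470/234 split, 34 learners — under the
fast profile with 5-fold CV and a 25-nm wavelength stride instead of GA
band selection. These are the package's standard desk-scale settings; the
full profile (printed tree counts, 10 folds, GA bands) is available
through the same interfaces.

## Known limitations

* Absolute accuracy on the synthetic task is optimistic: the generator
  omits scatter effects, outliers and assay noise, so validation R² ≈
  0.96–0.99 here versus ≈ 0.93 for the best ensembles on comparable real
  surveys.
* On this clean data, R²-proportional weighting is already near-optimal;
  the *advantage* of training-process weighting (notably self-attention)
  over the evaluation-index baseline is a property of noisy, heterogeneous
  real data and does not reproduce under the generator's conditions. What
  does reproduce robustly is the weight *pattern*: flexible learners
  receive systematically more weight than linear ones.
* The tabular Q-learning state space grows combinatorially with K; with
  the default δ the table stays small only because trajectories visit few
  states. A coarser δ trades resolution for coverage.
* The MIC fitness is an equipartition approximation (see above).
* Wall-clock/memory profiling of the strategies is out of scope.
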