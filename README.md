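# dynawa — dynamic weighted-averaging ensemble regression for Vis–NIR soil spectroscopy

Soil organic matter (SOM, g kg⁻¹) can be estimated rapidly and
non-destructively from visible–near-infrared (400–2400 nm) reflectance
spectra, but no single regression model captures both the broad linear
trends and the narrow nonlinear absorption responses in soil spectra. A
**weighted-averaging ensemble** predicts

```
ŷ = Σᵢ wᵢ ŷᵢ ,   wᵢ ≥ 0,  Σᵢ wᵢ = 1,
```

where ŷᵢ are the predictions of K base learners. Everything then hinges on
the weight vector **w**. `dynawa` implements eight weight-allocation
strategies that extract **w** from the training process itself — rather
than from a single evaluation index — together with the full supporting
pipeline:

| stage | what it does |
|---|---|
| `synthetic` | labelled synthetic Vis–NIR spectra (truncated-Gaussian SOM, absorption features at 580/920/1390/1920 nm) |
| `preprocess` | 400–2400 nm band trimming; Savitzky–Golay smoothing (11-point window, order 2) |
| `split` | deterministic Kennard–Stone 2:1 calibration/validation partition |
| `bands` | genetic-algorithm wavelength selection (lasso/ridge/linreg/MIC/corr fitness) |
| `learners` | registry of 34 base regressors (9 tree, 15 flexible/neural, 10 linear), grid search, k-fold out-of-fold training |
| `weights` | the eight strategies (below) |
| `ensemble` | weighted combiner, R²/RMSE metrics, linked-list weight history, learner-count curve, loss tracking with early stopping |

The eight strategies: **self-attention** (`sam`, softmax over scaled
dot-product similarities of learner prediction vectors), **Q-learning**
(`ql`, tabular RL over discretised weight states), **adaptive filter**
(`af`, projected gradient descent on ensemble MSE), **adaptive learning**
(`al`, MAE-based relative performance scores), **genetic algorithm**
(`ga`), **meta-learning** (`meta`, regression-tree importances),
**Adam** (`adam`), and the conventional baseline **R² normalisation**
(`r2`). All strategies that need targets are fitted on *out-of-fold*
calibration predictions, never on validation data.

## Worked example

```bash
python examples/04_weight_strategies.py
```

trains all 34 learners on 250 synthetic samples (167 calibration / 83
validation after the 2:1 Kennard–Stone split) and prints, per strategy, the
validation R² and RMSE of the weighted ensemble:

```
strategy      R2  RMSE g/kg
ga         0.986      0.545
meta       0.986      0.545
r2         0.977      0.690
sam        0.958      0.927
af         0.955      0.969
adam       0.945      1.065
ql         0.945      1.070
al         0.945      1.071

self-attention mean weight: flexible (TM+DL) 0.0341 vs linear (LRM) 0.0181
```

R² is the fraction of SOM variance explained on held-out validation
samples; RMSE is in g kg⁻¹ of SOM. The last line shows the central
qualitative behaviour: training-process weighting assigns roughly twice the
mean weight to flexible learners (trees and neural networks) as to linear
models, i.e. the weights track learner quality on nonlinear spectra. The
other examples (`examples/01…05`) walk through simulation/preprocessing,
the Kennard–Stone split, GA band selection, and the learner-count curve
with the dynamic weight history.

A thin CLI mirrors the library:

```bash
dynawa simulate --n 704 --seed 1 --out spectra.csv
dynawa preprocess --in spectra.csv --trim 400 2400 --out clean.csv
dynawa split --in clean.csv --out-cal cal.csv --out-val val.csv
dynawa run --n 704 --seed 1 --fast --out results/
```

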