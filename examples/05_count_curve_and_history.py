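"""Learner-count curve and the dynamic weight history.

How many base learners does the weighted ensemble need?  Rank learners by
individual validation R^2, add them one at a time, and watch the ensemble
R^2 plateau.  The linked-list weight history then shows dynamic updating
with rollback to the best-scoring weights.
"""

import warnings

import numpy as np

from dynawa import (
    EvalMetrics, RunConfig, WeightHistory, combine, count_curve, evaluate,
    update_weights, compute_weights, default_registry, fit_predict_all,
)
from dynawa.pipeline import prepare_data

warnings.filterwarnings("ignore")

cal, val = prepare_data(RunConfig(seed=2, n_samples=250, wavelength_stride=40))
P_oof, P_val, trace = fit_predict_all(default_registry(), cal, val,
                                      folds=3, fast=True, seed=2)

cc = count_curve(P_oof, cal.target, P_val, val.target, strategy="sam",
                 trace=trace, seed=2)
print("top of the ranking:", ", ".join(cc.ranking[:5]))
for k, r2 in cc.points[:6]:
    print(f"  k={k:2d}  ensemble R2={r2:.4f}")
print(f"plateau at k={cc.plateau_k}: beyond this size extra learners add "
      f"less than 0.002 R2 per step\n")

# dynamic weight store: append updates, roll back to the best snapshot
wv_sam = compute_weights("sam", P_oof, cal.target, seed=2)
hist = WeightHistory.init(wv_sam, evaluate(combine(P_val, wv_sam), val.target))
for strat in ("r2", "ga"):
    wv = compute_weights(strat, P_oof, cal.target, trace=trace, seed=2)
    update_weights(hist, wv, evaluate(combine(P_val, wv), val.target))
best = hist.rollback_best()
print(f"history holds {len(hist)} weight vectors; best snapshot is step "
      f"{best.step_id} ({best.weights.strategy}, RMSE "
      f"{best.metrics.rmse:.3f} g/kg)")
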