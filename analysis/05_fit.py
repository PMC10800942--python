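#!/usr/bin/env python
"""Tune and evaluate the gradient-boosted prediction of adjusted GE.

Random search (25 candidates here; each scored by full leave-one-out cross
validation MSE), then out-of-fold prediction with the winning
configuration and evaluation as Pearson r, its p-value, and explained
variance VE = r^2.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import json

import pandas as pd

from _common import WORKDIR, study_config
from neuroexposome.pipeline import stage_fit

cfg = study_config()
stage_fit(cfg, WORKDIR)

ev = json.loads((WORKDIR / "evaluation.json").read_text())
best = json.loads((WORKDIR / "best_params.json").read_text())
scores = pd.read_csv(WORKDIR / "score_table.csv")

print(f"tuning: {len(scores)} candidates, LOOCV MSE "
      f"{scores.loocv_mse.min():.3f} (best) .. {scores.loocv_mse.max():.3f} (worst)")
print("winning configuration:", {k: round(v, 4) if isinstance(v, float) else v
                                 for k, v in best.items()})
print(f"\nout-of-fold performance (n = {ev['n']}):")
print(f"  r = {ev['r']:.3f}, p = {ev['p']:.2e}, VE = {ev['ve_percent']}%")
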