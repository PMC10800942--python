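# neuroexposome

Predicting resting-state brain-network **global efficiency** from
multi-media **metal-exposure biomarkers**, with a fully synthetic,
fully tested pipeline.

## The problem

Resting-state fMRI assumes the environment's influence on brain dynamics
is concurrent with the scan. But chemical exposures experienced weeks or
months earlier — metals in particular — may shape the functional
connectome measured today. The analysis this package implements asks: how
much of the variation in a whole-brain graph metric can be predicted from
36 exposure features (6 metals — Mn, Pb, Cr, Cu, Ni, Zn — measured in 6
biological media — saliva, hair, fingernails, toenails, urine, blood)?

It is written for researchers at the intersection of environmental
epidemiology and network neuroscience who want a reproducible, inspectable
implementation of this kind of neuroexposomic workflow. The cohort data
the analysis was designed around are not public, so the package ships a
synthetic-data generator that emulates their statistical structure —
log-normal biomarkers with cohort-realistic geometric means/SDs and detection
limits, censoring, AR(1) ROI time series with motion/WM/CSF contamination
— and plants a known exposure → connectivity effect (urinary Pb down,
blood Zn up) so every stage can be validated by recovery.

## The method

1. **Conditioning.** Per-node ROI series are prewhitened by a two-step
   GLM: residualize on 6 motion parameters, estimate a per-node AR(1)
   coefficient φ from the residuals, remove it from the raw series
   (y′ₜ = yₜ − φyₜ₋₁), then regress out motion + WM + CSF.
2. **Connectome.** Pearson correlations between conditioned series are
   thresholded proportionally (top 15% positive edges) into a binary
   graph. Global efficiency is the mean inverse hop count over ordered
   node pairs:

       GE = (1/(N(N−1))) Σ_{i≠j} 1/d_ij ,  1/∞ = 0

   then min-max scaled across the cohort and adjusted for age and sex
   (standardized residuals).
3. **Prediction.** XGBoost regression of adjusted GE on the 36 features
   (named `UPb`, `BZn`, `SCu`, … — medium letter + metal symbol).
   Hyperparameters by random search, each candidate scored by full
   leave-one-out cross validation MSE; performance is the Pearson r
   between out-of-fold predictions and observations, with explained
   variance **VE = r²**.
4. **Attribution.** Interventional SHAP values (background = training
   matrix), computed by an exact polynomial-time tree algorithm that is
   verified against a brute-force 2^M coalition-enumeration oracle; global
   importance is mean |SHAP| per feature.

Values below a biomarker's limit of detection are substituted with
LOD/√2; descriptive statistics are geometric (GM, GSD) as appropriate for
log-normal concentrations.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
124-subject cohort (seed 1) and write their tables under
`results/pipeline/`. The same chain is available as a CLI
(`neuroexposome run-all --config config.yaml --workdir out/`) or in
Python:

```python
from neuroexposome.pipeline import RunConfig, run_all
report = run_all(RunConfig(seed=1, n_subjects=124, n_iter=25), "out/")
```

What the scripts print (abridged):

```
$ python analysis/01_simulate.py
cohort: 124 subjects, 57% female, mean age 18.8 y

$ python analysis/02_prewhiten.py
mean AR(1) coefficient estimated: 0.413
mean |lag-1 autocorrelation| (first 10 subjects): 0.650 raw -> 0.032 conditioned

$ python analysis/03_connectome.py
global efficiency: mean 0.510, range [0.396, 0.556] at density 0.15
Spearman(measured GE, latent coupling) = 0.984  (recovery check)

$ python analysis/05_fit.py
tuning: 25 candidates, LOOCV MSE 0.109 (best) .. 0.272 (worst)
out-of-fold performance (n = 124):
  r = 0.944, p = 8.19e-61, VE = 89%

$ python analysis/06_explain.py
top features by mean |SHAP|:
    BZn         0.4975     1
    UPb         0.3924     2
    SPb         0.0621     3
sign diagnostics for the planted features:
  UPb: rank 2, Spearman(value, SHAP) = -0.981
  BZn: rank 1, Spearman(value, SHAP) = +0.962
```

Reading this: conditioning removed the serial autocorrelation it was
supposed to remove; measured efficiency tracks the latent coupling the
generator planted; the model predicts held-out adjusted GE almost
perfectly at planted magnitude 1.0 (real exposure effects are far
weaker — the synthetic effect is deliberately strong so recovery is a
sharp test, see `docs/methods.md`); and attribution surfaces exactly the
two planted features, with the planted signs (urinary lead pushing
predicted efficiency down, blood zinc up).

## Layout

```
src/neuroexposome/   library: reference, synthetic, prewhiten, connectome,
                     features, predictor, attribution, io, pipeline, cli
analysis/            numbered narrative drivers (01_simulate ... 06_explain)
tests/               pytest suite (unit, property, acceptance)
scripts/             acceptance.py
docs/methods.md      models, defaults, numerical choices, limitations
```
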