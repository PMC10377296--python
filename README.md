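# gbm-growth

Bayesian quantification of glioblastoma (GBM) growth: given step-wise
counts of tumor cells detected as the tumor migrates into new brain
regions, predict the eventual volume the malignant cell population will
attain by the tumor's survival time, together with the probability that
no malignant cell went undetected. The package also ships the
surrounding pipeline: K-means localization of the tumor on multimodal
MRI, canonical-correlation / Wilks' Λ screens between tumor volume and
radiomic feature blocks, and an SEM-structured Bayesian regression that
conditions the predicted volume on radiomic covariates — plus
synthetic-data generators so everything runs and is tested without
patient data.

## The model

At migration step *t* the tumor occupies voxel set *R(t)*; the
incremental region Δ*R(t)* = *R(t)* − *R(t−1)* receives *m<sub>t</sub>*
newly proliferating cells, *m\*<sub>t</sub>* of them malignant. With
ν total and ν\* malignant cells able to proliferate by the final step,
and cumulative detected counts *M<sub>t</sub>*, *M\*<sub>t</sub>*:

- **Detection**: *m\*<sub>t</sub>* | *m<sub>t</sub>* is hypergeometric —
  drawing *m<sub>t</sub>* cells from the ν − *M<sub>t−1</sub>* still
  undetected, of which ν\* − *M\*<sub>t−1</sub>* are malignant.
- **Proliferation**: *m<sub>t</sub>* is Poisson with mean
  (ν − *M<sub>t−1</sub>*)λ (default; the constant-mean νλ variant is
  retained for likelihood evaluation, but its MLE is degenerate — see
  `docs/methods.md`).
- **Estimation**: Newton–Raphson on the continuous relaxation of
  (ν, ν\*), with λ concentrated out in closed form.
- **Prior and posterior**: per-step weights
  g<sub>t</sub>(m\*) = Poisson(m\*; (ν\* − M\*<sub>t−1</sub>)λ\*) × c.v.,
  where the Poisson coefficient of variation c.v. = mean<sup>−1/2</sup> < 1
  requires (ν\* − M\*)λ\* > 1. Normalized across steps these give
  H<sub>t</sub>, the posterior mean H<sub>mean</sub> = Σ m\*<sub>t</sub> H<sub>t</sub>,
  and the eventual volume **V<sub>new</sub> = c · H<sub>mean</sub> · V<sub>initial</sub>**
  (c = 1 by default).
- **Completeness probability**: for a detected count *k*, the
  probability that no malignant cell went undetected is the geometric
  survival value (k/(k+1))², e.g. k = 3 → 0.5625, k = 6 → 0.7347.

The Bayesian regression stage reads its Bernoulli(0.5) coefficient
prior as spike-and-slab variable selection (a literal
{0,1}-coefficient mode is also provided), restructures heterogeneous
radiomic covariates through a latent-factor measurement model
(x = γ + Λη + δ, diagonal Θ), and is compared against a plain Gaussian
GLM by R², AIC and ABC cross-validation error.

## Worked example

```bash
gbmgrowth simulate --out cohort --subjects 3 --seed 1
gbmgrowth predict --trajectory cohort/trajectories/S000.csv \
    --v-initial 107000 --out pred.json
```

prints

```
posterior mean 6.028, eventual volume 644987.9 mm^3, P(no cell undetected) 0.7347
```

Subject S000 was simulated with ν = 670.0, ν\* = 286.5, λ = 0.181; the
fit recovers ν̂ = 659.6, ν̂\* = 276.3, λ̂ = 0.194 (`pred.json` carries the
full posterior: step weights, the fitted parameters and a convergence
report). The posterior mean 6.03 says about six malignant cells are
expected to proliferate per unit of the initial tumor; scaled by the
107,000 mm³ initial volume this predicts an eventual malignant volume of
≈ 645,000 mm³, and the rounded count k = 6 gives
(6/7)² = 0.7347 as the probability that no malignant cell went
undetected. The same objects are available programmatically:

```python
from gbmgrowth import TumorGrowthModel, CellTrajectory
model = TumorGrowthModel().fit(CellTrajectory.from_csv("cohort/trajectories/S000.csv"))
summary = model.summarize(v_initial=107000.0)
```

Other stages: `gbmgrowth segment` (NIfTI in/out), `gbmgrowth regress`,
`gbmgrowth compare` (the R²/AIC/CV-error table), `gbmgrowth fixture`
and `gbmgrowth pipeline` (deterministic simulate → fit → predict run).

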