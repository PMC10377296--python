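# Methods

## The growth model

One subject's data is a trajectory of migration steps
t = 1..T with counts (m_t, m*_t) — total and malignant cells detected in
the incremental region ΔR(t) — and the region sizes |ΔR(t)|. The joint
step pmf factorizes into a hypergeometric detection term (drawing m_t
cells without replacement from the ν − M_{t−1} still-undetected cells,
ν* − M*_{t−1} of them malignant) and a Poisson proliferation term. Two
conventions exist for the Poisson mean and the package implements both:

* `literal` — mean νλ, constant across steps;
* `depleted` — mean (ν − M_{t−1})λ, the removal-sampling form.

**Why estimation defaults to `depleted`.** Under the literal mean the
MLE is degenerate: λ concentrates to mean(m)/ν, which makes the Poisson
factor independent of ν, and the hypergeometric factor alone is maximized
at the boundary ν = M_T for *any* data (a smaller population always
explains an observed malignant/benign split at least as well). The
global maximizer is therefore ν̂ = M_T, λ̂ = 1/T regardless of the data —
verified here by dense profile grids and an independent Nelder–Mead
cross-check. The depleted mean restores a proper interior optimum
because the likelihood then rewards the observed *decline* in catches,
the classic catch-effort identification. `literal` remains available
for pmf/likelihood evaluation and simulation.

**Newton–Raphson.** The integer parameters are relaxed through
gamma-function binomials. The iteration runs in unconstrained
coordinates ν = M_T + e^u, ν* = M*_T + e^u·σ(v), which satisfy every
feasibility constraint identically (so the −∞ barrier of the raw
parametrization is never hit), with λ profiled out in closed form at
each trial point (literal: λ̂(ν) = mean(m)/ν; depleted:
λ̂(ν) = M_T / Σ(ν − M_{t−1})). Gradients and Hessians are central
differences with relative step 1e−5; the Newton step falls back to a
scaled gradient step when the Hessian is singular or non-ascending, with
step-halving (up to 40 halvings) on likelihood decrease. Convergence:
gradient norm below `tol` (default 1e−8), a relative step below 1e−12,
or a likelihood gain below 1e−10·(1+|ℓ|); `max_iter` 200. When the data
carry no depletion signal ν̂ drifts to a hard cap of 1e8 and the report
is flagged `boundary` ("no depletion signal").

**Estimator accuracy.** At (ν = 500, ν* = 200, λ = 0.05, λ* = 2), with
the self-consistent generative model, median relative errors of λ̂ over
100 replicates are ≈ 1.6 at T = 3, ≈ 0.34 at T = 10 and ≈ 0.13 at
T = 20 — decreasing with follow-up length, as removal-type information
accumulates (≈ 14% / 40% / 64% of the population removed). These are
the *true MLE's* sampling errors: the fitted likelihood beats the
generating parameters in 100/100 replicates and matches independent
optimizers. Only about 40% of the population is removed by T = 10, so
substantially tighter recovery at that horizon is not achievable from
this likelihood.

**Prior, posterior, volume.** The per-step prior weight is the Poisson
pmf at mean (ν* − M*_{t−1})λ* times the Poisson coefficient of
variation mean^(−1/2); the constraint mean > 1 (equivalently c.v. < 1)
is enforced with a named error. λ* itself is estimated by
Newton–Raphson on the 1-D Poisson likelihood with exposures
ν̂* − M*_{t−1}; the optimum has the closed form Σm*_t / Σ exposures, and
values at or below 1 return the boundary 1 + 1e−6 with a flag. The
posterior weight of step t is H_t ∝ g_t(m*_t); the likelihood factor
L(ν̂, ν̂*; λ̂) is constant across steps and cancels — both the cancelled
and the explicit (log-space) routes are computed and agree to < 1e−10.
The posterior mean H_mean = Σ m*_t H_t scales the initial ROI volume:
V_new = c·H_mean·V_initial with c = 1 by default, optionally rounded to
whole mm³ (`discrete_volumes`).

Because detection itself never involves λ*, λ*-recovery experiments
draw counts from the prior law at the trajectory's own exposures
(`simulate_prior_counts` + the `counts` argument of `fit_lambda_star`);
recovery is then within ~1% (median, 100 replicates).

**Completeness probability.** A detected count k maps to
P = (k/(k+1))^r with r = 2 — the survival function at r of a geometric
law with success probability 1/(k+1). At subject level k is the rounded
posterior mean. P is zero at k = 0, strictly increasing in k, and
independent of the step index; time labels never enter the model, so
relabeling steps cannot change any output.

## Simulator

Forward reading of the same model: per step, Poisson draw clipped to
the undetected remainder (feasibility), then a hypergeometric malignant
split; exhaustion truncates the trajectory with a flag. Cohorts draw
subject parameters uniformly from configurable ranges — defaults
ν ∈ [500, 10000], ν*/ν ∈ [0.2, 0.8], λ ∈ [0.01, 0.2], λ* ∈ [1.1, 3],
T ∈ [3, 12], n = 102 subjects — with per-subject seeds spawned from the
master seed. Initial ROI volumes are lognormal, moment-matched to a
whole-tumor scale of 107,999.84 ± 52,700.74 mm³.

## Segmentation

Per-modality K-means (k = 4: background / CSF-like / tissue-like /
lesion-like) on T1, T1-Gd, T2 and FLAIR intensities; the highest-mean
cluster per modality is the lesion candidate; voxels flagged by ≥ 2
modalities survive fusion; morphological opening + closing with a
radius-1 ball and largest-connected-component selection clean the mask.
Constant volumes and empty post-cleaning masks raise `EmptyMaskError`.
ROI volume is voxel count × voxel volume (equal to the count at 1 mm³
resampling). On a noise-free ellipsoid phantom Dice is 0.998 and does
not degrade at 5%-of-contrast Gaussian noise; the mask volume is within
0.3% of the analytic ellipsoid volume.

## Canonical metrics

Canonical correlations come from the SVD of Q_x'Q_y (orthonormal bases
of the centered blocks) — numerically equivalent to the
cross-covariance eigenproblem, and cross-checked against statsmodels'
`CanCorr` to 1e−10. Wilks' Λ = Π(1 − ρ_i²) with Rao's F approximation
(m = n − 3/2 − (p+q)/2; exact for min(p, q) ≤ 2); empirical type-I
error at α = 0.05 is ≈ 0.047 over 2000 null simulations at n = 200,
p = q = 3. Correlation screens are pairwise-complete Pearson r with
0.05/0.01/0.001 significance stars; constant columns are flagged, not
propagated.

## SEM measurement model

Per block (endogenous radiomic features; exogenous survival length and
age), x = γ + Λη + δ with δ ~ N(0, Θ), Θ diagonal, estimated by EM on
the Gaussian factor-analysis likelihood (monotone log-likelihood,
asserted in tests). Identification fixes the first loading per factor
to 1; the latent variance is free. Heywood cases floor the error
variance at 1e−8 and set a flag. Latent d1 = d2 = 1 by default.
Posterior-mean scores feed the regression.

## Bayesian regression

A Bernoulli(0.5) prior on (α, β) is not usable literally for
real-valued effects, so the default reading is spike-and-slab:
inclusion indicators ~ Bernoulli(0.5), included coefficients get a
normal-inverse-gamma slab (standardized-coefficient sd τ = 10 in units
of σ; intercept sd 100σ; a0 = b0 = 1e−3). Sampling is collapsed Gibbs
over the indicator vector — coefficients and σ² integrated out
analytically, then drawn conjugately per retained sweep — which needs
no tuning and mixes freely at these dimensions; a flip-rate diagnostic
warns when the chain churns. The literal mode (coefficients in {0,1}
with Bernoulli(0.5) mass, fixed plug-in σ²) is kept for fidelity and
matches exhaustive 2^p enumeration within Monte-Carlo error. On
y = 2 + 3x + ε (σ = 0.5, n = 200), 95% credible intervals cover the
truth in 93/100 seeded replicates with median bias ≈ 0.02.

The growth posterior enters the regression only through its mean (the
response is the predicted eventual volume); the response distribution is
approximated by a Gaussian likelihood with constant variance — the
minimal consistent reading of a "posterior-distribution response" for
sampling purposes. Volumes being lognormal-scale, the adjustment study
regresses log volume and exponentiates predictions, which keeps implied
counts positive. Re-derived probabilities use the same geometric map on
round(predicted volume / initial volume); on the 102-subject synthetic
cohort the regression-adjusted minimum probability is never below the
unadjusted minimum and the mean rises.

## GLM baseline and comparison harness

The baseline is ordinary least squares (statsmodels) with
AIC = n·log(RSS/n) + 2p; rank-deficient designs fall back to the
pseudo-inverse with a warning. The comparison table has one row per ROI
(ED, ET, NET, TC, WT) and columns (R², AIC, C.V. error) × (GLM,
Bayesian). ABC cross-validation error: per held-out subject, posterior-
predictive draws (plug-in Gaussian draws for the GLM — the harness is
deliberately symmetric) are accepted when their normalized distance to
the observed response falls below the 0.1 distance quantile; the error
is the mean accepted distance, averaged over subjects and folds
(k = 5). Each model sees identical per-(ROI, fold) random streams, so
identical adapters produce identical columns. The Bayesian model's AIC
uses 1 + expected included-coefficient count as its parameter count.

## Synthetic data

Feature tables induce correlation only through two latent factors
(tumor burden; clinical frailty): ROI volumes are lognormal
moment-matched to realistic GBM magnitudes, spatial/histology scores
load on the burden factor (clipped at 0), survival length is lognormal
(1.5 ± 1.4 years) on the clinical factor, age ~ 58 ± 12 (negatively
loaded). Phantoms are four co-registered modality arrays with an
ellipsoidal lesion (strongest contrast on T1-Gd and FLAIR) plus
Gaussian noise, returned with their ground-truth mask. What passing
tests show is therefore structural correctness — estimator consistency,
calibration, pipeline determinism — not performance on real MRI texture,
real radiomic distributions, registration error or missingness patterns,
none of which the generators attempt to emulate beyond first/second
moments.

## Problem sizes and numerical choices

Validation studies use 100 replicate trajectories per recovery setting,
a 102-subject cohort, 2000 null simulations for calibration, 50 SEM
seeds, 100 coverage replicates, 48³-voxel phantoms and 5-fold
comparison runs — sizes chosen so the full suite and the acceptance
script each complete in a couple of minutes while keeping Monte-Carlo
error well inside the asserted margins. All randomness flows from
explicit seeds (cohorts via `SeedSequence.spawn`); JSON output uses
shortest round-trip float repr, making repeat runs byte-identical.

## Known limitations

* ν is weakly identified at low depletion (short T, small λT): the
  likelihood is nearly flat in ν above M_T, and the fit flags such runs
  rather than manufacturing precision.
* The literal-mode MLE degeneracy above is a property of the
  constant-mean model variant, not of the optimizer.
* λ̂* frequently sits at its lower boundary on detection-only data
  (flagged); the prior rate is informative only for prior-law counts.
* No spatial model of where migrated cells land; region sizes |ΔR(t)|
  are carried but never enter the likelihood.
* Registration, skull stripping and texture-feature extraction are out
  of scope; the segmentation stage assumes co-registered inputs.
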