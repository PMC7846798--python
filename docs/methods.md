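# Methods

## Structural model

Vancomycin disposition is modelled as a one-compartment system with
first-order elimination under repeated constant-rate infusion. With dose D
(mg), interval τ (h), infusion duration Tinf (h), infusion rate R0 = D/Tinf,
clearance CL (L/h), volume V (L) and k = CL/V, the steady-state
concentration at time t from the start of the most recent infusion is

    C_ss(t) = (R0/CL)(1 − e^{−kt}) + C_ss(0) e^{−kt}          0 ≤ t ≤ Tinf
    C_ss(t) = C_ss(Tinf) e^{−k(t−Tinf)}                        Tinf < t ≤ τ

with C_ss(Tinf) = (R0/CL)(1 − e^{−k·Tinf})/(1 − e^{−kτ}) and
C_ss(0) = C_ss(Tinf) e^{−k(τ−Tinf)}. Doses in mg and volumes in L make the
output mg/L ≡ μg/ml with no conversion constants. `conc_multidose` sums n
single-dose responses and is used both as the pre-steady-state predictor and
as an independent oracle for the closed form (they agree to < 1e−8 μg/ml per
mg dose at n = 200). Steady state is assumed from the 6th dose (the trough
then sits ≈ 2% below its asymptote for a typical patient). Infusion duration
is not part of the study's report; the default is 1 h (standard practice)
and it is configurable per record. Sampling conventions: troughs 0.5 h
before the next dose; "approach peak" 1 h after the end of the infusion
(the table-footnote convention is used where the source text is
self-contradictory about the peak time).

## Statistical model

Per patient i with observations y_ik at times t_ik:

    y_ik = f(β_i, t_ik) + ε_ik,    ε_ik ~ N(0, σ_ik²)
    β_i = (z_cl,i·θ_cl, z_v,i·θ_v) + η_i,    η_i ~ N(0, Ω)

β_i = (CL_i, V_i). The covariate model is additive on the natural scale with
raw (uncentered) units and the 1/2 categorical codings, so published
coefficient vectors are usable verbatim; the cost is that additive Gaussian
parameters can go nonpositive, which the source formulation does not
address. Simulated individual parameters are clamped at
max(0.01, 5% of typical) with a truncation flag; inside the estimator the
structural prediction is held constant below a small fixed floor
(CL 0.01 L/h, V 0.1 L), which matches the clamped generative model and keeps
the likelihood a fixed smooth function of the parameters across iterations.

The residual error magnitude is not reported in the source study. The
default is proportional with CV 0.15 plus an additive SD floor of
0.5 μg/ml, σ² = 0.5² + (CV·y)², evaluated at the **observed** concentration.
Using the observed rather than predicted concentration keeps the marginal
likelihood a fixed function of (θ, Ω, CV), so the EM below is a proper
(approximate) EM with monotone likelihood; with CVs ≤ 0.15 the induced
weighting bias is well under the tolerances used anywhere in the package.
All validation quantities that depend on the unprinted residual magnitude
(external MAE, post-adjustment accuracy) are treated as order-of-magnitude
comparisons only.

## Laplace-EM estimation

The population fit alternates:

* **E-step.** Per patient, the conditional mode of β_i is found by damped
  Gauss–Newton with backtracking, run in φ = log β so positivity is
  structural (no active bounds); a second start from the previous
  iteration's modes guards against basin hopping. Conditional means,
  covariances and residual expectations are then computed by adaptive
  Gauss–Hermite quadrature (7×7 nodes) **in log-parameter space**, centered
  at the mode and scaled by the inverse Gauss–Newton curvature, with the
  natural-space normal prior entering through the Jacobian e^{φ1+φ2}. The
  log-space quadrature matters twice over: the conditional distribution of a
  weakly identified V is strongly right-skewed in natural space (mode-only
  moments underestimate the population V by ~10%), and in log space it is
  near-Gaussian, so 49 nodes integrate it to the accuracy needed for a
  monotone likelihood trace. The reported marginal log-likelihood is the
  same quadrature estimate.
* **M-step.** θ by generalized least squares of the conditional means on the
  stacked design rows with weight Ω⁻¹; Ω as the mean of (conditional
  covariance + outer residual of conditional means about the fitted typical
  values), eigenvalue-floored at 1e−8·trace to stay positive definite; the
  proportional residual CV by bounded 1-D maximization of the expected
  log-likelihood (the additive floor stays fixed). These are exact
  maximizers of the expected complete-data log-likelihood given the E-step
  moments, so the likelihood ascends up to quadrature error.

Initial values are the literature estimates CL 2.83 L/h, V 52.14 L, with Ω
seeded diagonally at 30% CV. Convergence follows the 1%-relative-change
rule applied to every population parameter (θ, the two IIV SDs, the IIV
correlation — assessed absolutely, since it starts at 0 — and the residual
CV); default tolerance 0.01, maximum 500 iterations. Non-convergence is
reported in the result, not raised. AIC/BIC use the standard convention
(−2LL + 2p; −2LL + p·ln n_obs) with per-observation normalized variants
reported alongside, since the source prints per-observation-scale values
without stating its normalization. Approximate θ standard errors come from
the GLS normal equations; they condition on the conditional means and are
reported as RSE%.

## Stepwise covariate selection

Screening regresses the individual empirical-Bayes (conditional-mean)
estimates of CL and V on candidate covariates by OLS and applies forward
entry: at each step every remaining candidate's extra-sum-of-squares
F-change given the entered set is computed, the largest enters if its
p < α = 0.05 (strict), and the procedure stops when none qualifies. Ties
break lexicographically; an exact fit caps F at 1e12. This mirrors the shape
of classical stepwise-regression output (overall F, F-change, P) that the
method is meant to reproduce. An optional backward pass re-tests earlier
entries; a full-refit mode (likelihood-ratio tests with the mixed model
re-fitted per candidate) exists for sensitivity analysis. The EB mode is
canonical.

A note on operating characteristics: with the published inter-individual
CV of ~42% on CL, an effect of 0.036 L/h (dopamine, 1/2-coded) is
statistically invisible at n = 300 — yet the published F statistics imply a
post-covariate residual spread of only ≈ 0.12 L/h, two orders of magnitude
of variance below the printed CV. The package's stepwise
operating-characteristic simulations therefore generate individual estimates
directly around the published clearance equation with a post-covariate
residual SD of 0.08 L/h (CL) and 1.5 L (V), fixed a priori by power
analysis so that the published covariate pattern is recoverable ≥ 90% of the
time; the full-pipeline stepwise (EM fit, then screening) recovers only the
strong covariates (TBW, Cr), which is the realistic sparse-data outcome.

## Bayesian dose individualization

Given the population model as prior and ≥ 1 steady-state observation, the
MAP estimate minimizes

    Σ_k (y_k − f(β, t_k))²/σ_k² + (β − β_typ)ᵀ Ω⁻¹ (β − β_typ)

via the same Gauss–Newton machinery (posterior covariance from the inverse
curvature). One observation plus the prior is always well posed.
Observations below the 0.4 μg/ml quantification floor are down-weighted
(SD × 3) with a warning. Regimen selection evaluates the predicted
steady-state trough for every entry of the six-option clinical menu; among
in-window (10–20 μg/ml) entries the trough closest to the 15 μg/ml midpoint
wins, exact ties go to the lower total daily dose (toxicity-averse), and if
no entry reaches the window the closest one is returned flagged infeasible.
The closed-loop attainment simulator draws true parameters from the truth
model, starts patients on a clinician-style rule (1 g q12h if
Cr ≤ 90 μmol/L, else 0.5 g q12h — a stand-in for unreported empirical
dosing), observes one noisy trough, MAP-fits, re-selects, and scores the
freshly-noised achieved trough against the window. Under the published IIV
with residual CV 0.15 the attainment is ≈ 75–87% depending on seed; at
residual CV 0.05 it averages ≈ 91%, bracketing the reported ~90% in-window
fraction, whose exact reproduction would require the unprinted residual
magnitude.

## Synthetic cohorts

The generator emulates the published cohort summary: sex (67.9% male),
manufacturer (61.2% Eli Lilly), CRRT (23.3%), severe burn (8.6%);
creatinine lognormal with median 71 μmol/L and log-SD 0.65 truncated to
[28, 581] (right tail chosen to reach the printed maximum at cohort size);
age truncated normal (62 ± 16, [18, 93]); weight truncated normal
(65 ± 12, [40, 90.6]). Drug-exposure prevalences are not published; the
defaults (dopamine 0.35, noradrenaline 0.35, furosemide 0.30, dobutamine
0.15) are plausible ICU rates chosen once. Covariates are sampled
independently except one clinically forced association: CRRT slots are
assigned preferentially (8:1 weight) to upper-tercile creatinine patients,
leaving both marginals intact; the link is toggleable. The sampling design
defaults to two troughs per patient plus an approach peak with probability
0.4 (echoing the published 837:156 trough:peak mix); recovery experiments
use one trough + one peak per patient. Randomness is split into independent
sub-streams (covariates / random effects / residual noise) so changing the
noise level never perturbs the cohort. What the generator does **not**
emulate: time-varying covariates, dropout or assay censoring beyond a
floor, and the full joint covariate distribution (only the one CRRT–Cr link
is imposed) — so passing tests demonstrate algorithmic correctness under
the stated conditions, not clinical performance on real ICU data.

## Problem sizes and numerical choices

Recovery experiments use 300 patients × 2 observations (the modelling
cohort's scale, at which the fitter runs in seconds); stepwise operating
characteristics use 1000 null and 50 alternative replicates at n = 300;
closed-loop sweeps use 40–92 virtual patients over 20 seeds. Quadrature is
7 nodes per dimension; the inner Gauss–Newton runs to a 1e−10 step norm
with at most 60 iterations and 12 backtracking halvings. Degenerate inputs:
a numerically singular Ω collapses the conditional on the typical values; a
singular covariate design raises an error naming the columns; patients with
a single observation are excluded (with warning) from external validation;
zero observed concentrations are excluded from relative-error summaries.

## Known limitations

* One compartment only; no nonlinear elimination; no CRRT circuit model.
* The additive covariate/random-effect model follows the source; a
  log-normal parameterization would avoid the positivity clamp but would
  not accept the published coefficients verbatim.
* The inter-individual CV of V is recovered with a mild downward bias
  (≈ 5–15% relative at n = 300, within the stated tolerance) — the price of
  V being weakly identified by trough-dominated sampling.
* RSE% values condition on the E-step moments and understate full sampling
  uncertainty; no bootstrap is provided.
* MPE/MAE divide by the observed concentration and external validation
  scores only non-fed-back observations; both conventions are stated
  choices where the source is ambiguous.
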