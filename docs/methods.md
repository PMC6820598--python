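# Methods

## Structural model

Disposition is a sum of exponentials. For two compartments the macro
constants come from the micro constants k10 = CL/V1, k12 = Q/V1,
k21 = Q/V2: α and β are the roots of s² − (k10+k12+k21)s + k10·k21 = 0 and
the unit-bolus amplitudes are A = (α−k21)/(V1(α−β)), B = (k21−β)/(V1(α−β)).
Infusions are zero-order inputs over the recorded duration (default 0.25 h
when a record omits it); multiple doses superpose. Units are IU, L, h and
IU/mL, with the single 1000-fold L→mL conversion applied at the
concentration interface.

Observed activity adds an endogenous baseline (0.005 IU/mL — half the most
common LLOQ — when not recorded) and, when a pre-dose activity is recorded,
a residual (predose − endogenous) that decays at the terminal rate β from
the pre-dose sampling time. The residual term is applied exactly as
written, so it may be negative if the pre-dose observation sits below the
endogenous level; reported profiles are floored at zero because activities
cannot be negative, while the likelihood uses the unfloored prediction
(guarded against non-positive values).

TAT2 — time above 0.02 IU/mL — is evaluated from the last dose over a
configurable window (default 168 h; whether routine reporting truncates at
the next scheduled dose is not standardized, hence the knob) on a 0.1 h
grid with linear interpolation of threshold crossings. Against a 0.001 h
brute-force scan this is accurate to well under 0.05 h.

## Covariate model

Fat-free mass uses the maturation-weighted Al-Sallami form built on the
Janmahasatian adult equation, the standard choice for body-size scaling
across the paediatric–adult range; male constants (γ∞ = 0.88, τ = 13.4 y,
δ = 12.7, 9270·BW/(6680 + 216·BMI)) apply to this all-male indication, and
the female constants are included but unused. The exact FFM equation used
when the shipped model was developed is not printed in its source, so this
choice is an explicit, documented assumption; the constants are
configurable. Note the adult form crosses BW near BMI ≈ 12, so FFM < BW is
guaranteed only on the physiologic BMI range.

Covariate effects are power functions of covariate/median; the age effect
on CL is piecewise linear with the breakpoint frozen at the population
median age (25 y), flat below it. Inside the shipped model the medians are
frozen at 50.5 kg FFM / 25 y; refits recompute medians from the data at
hand (they can be pinned, e.g. when comparing refit estimates directly to
the shipped values). Missing height is imputed by OLS of HT on BW and age
fitted on the complete records (≥ 10 required), clipped to 40–210 cm.

## Estimation

The marginal likelihood per subject is approximated by the Laplace method:
h(η) = log p(y|η) + log N(η; 0, ω) is maximized by damped Newton iterations
started from η = 0 (no warm starts, for reproducibility), and the OFV
contribution is −2[h(η̂) + log 2π − ½ log det H] with H the negative
Hessian of h at the mode. Numerical choices:

* η-gradients by complex-step differentiation (the disposition algebra is
  holomorphic; the censored term uses an exact first-order chain rule
  through log Φ), so gradients carry no truncation error;
* Hessians by finite differences of that gradient with step 1e−4 —
  forward differences while stepping, central at the converged mode for
  the log-determinant — eigenvalue-floored at 1e−10 (1e−2 for step
  computation) with Newton steps capped at norm 2;
* inner convergence at gradient norm < 1e−8, or a Newton step below
  1e−10 (a scale-invariant fallback for very sharp likelihoods);
* all subjects are solved simultaneously as one vectorized batch.

Censored (BLQ) observations contribute log Φ((LLOQ − f)/sd) — the M3
method; the residual model y = f(1+ε_prop) + ε_add supports proportional,
additive and combined error.

The outer problem minimizes the total OFV over log structural parameters,
free covariate coefficients, a log-Cholesky factor of ω and log residual
SDs with L-BFGS-B inside wide sanity bounds (BSV SDs are kept above 1e−3,
where variability is indistinguishable from none). The OFV gradient is
computed by forward differences evaluated in a single batched inner solve:
the base point and all perturbed parameter vectors are stacked as virtual
copies of the dataset, which makes one gradient roughly the price of two
function evaluations. The OFV includes its Gaussian constants, so values —
not only differences — equal −2 log marginal likelihood.

Model comparison uses the conventional OFV-drop thresholds 3.84 (forward,
p < 0.05) and 6.63 (backward, p < 0.01) at 1 df, with "3.84 or more"
counted as significant. Stepwise covariate search adds the best
significant candidate per round, retires candidates on the same parameter
whose covariate is Spearman-correlated (|ρ| > 0.6, configurable — no
canonical value exists) with the accepted one, tries age in linear and
piecewise form and keeps the better, then backward-eliminates. Shrinkage
is 1 − SD(EBE)/ω_SD per η (sample SD, ddof 1) and 1 − SD(IWRES) for ε,
with > 35% flagging over-parameterization. The bootstrap resamples
subjects with replacement within age strata (< 12, 12–18, > 18 y by
default; the exact stratification used for the shipped model is not
published) and reports percentile 95% CIs.

## Forecasting

MAP estimation fixes the population model as the prior and returns the
posterior mode of (η_CL, η_V1); with no observations the prior mode
(typical subject) is returned and flagged. Half-life and TAT2 are derived
from the individual macro constants with the subject's own doses and
baseline. Relative errors are always 100(pred − ref)/ref.

## Synthetic cohort

Only marginal summaries of the development population are available, so
the joint demographic model is a constructed one: age from a log-normal
(μ = ln 29, σ = 0.85) truncated to [1.7, 72] y; height from a male
growth-curve interpolant plus 6 cm noise, clipped to the observed range;
body weight through an age-dependent median BMI (15.5 + 11·age/(age+10))
with 18% log-normal spread, clipped to [9.68, 119] kg. At n = 2000 this
reproduces the published medians (age ≈ 25 y, BW ≈ 64 kg, FFM ≈ 52 kg)
though the age mean runs ~2 y high and the SD ~1 y low — a single
log-normal cannot match all three summaries under truncation.
Development-like occasions use one 20–50 IU/kg infusion and 1–8 samples
(distribution matched to the reported mean 4.2 / median 5) drawn from
routine follow-up times ≤ 72 h; with LLOQ 0.01 IU/mL this yields ≈ 3–4%
censored observations, as in the development data. What the generator does
not emulate: inter-centre assay differences, dose-rounding to vial sizes,
correlated sampling-time patterns within centres, and any covariate the
source did not report (VWF, blood group). Passing tests therefore
demonstrate internal consistency of the method under the stated design,
not robustness to those real-data features.

The LSA cohort gives every subject 50 IU/kg Mon/Wed/Fri (0, 48, 96 h
weekly) for 4 weeks and samples at −0.5, 1, 3, 6, 12, 24, 30, 48, 54, 72 h
around the last Friday dose.

## Problem sizes used in the shipped checks

Defaults follow the source procedures (500 pcVPC replicates, 100
cross-validation repeats, 1000 LSA subjects, 1000 bootstrap runs). The
shipped acceptance checks run the same pipelines at sizes chosen to keep a
complete verification run comfortable on a laptop: 250 LSA subjects
(errors of the summary percentiles at 250 vs 1000 subjects are well inside
the decision margins), 5 recovery cohorts of the full development size
n = 92, 200 simulated cohorts of 48 subjects (3 samples each) for the
χ²(1) null of the likelihood-ratio test (the asymptotic reference needs a
few dozen subjects per cohort), and single-repeat cross-validation on a
one-compartment cohort. The methods themselves are unchanged by these
sizes.

## Known limitations

* Exact OFV equality with NONMEM's Laplacian implementation is not
  promised (interaction handling internals are not public); agreement is
  instead demonstrated against adaptive Gauss–Hermite quadrature
  (32 nodes/dimension, within 0.5 OFV units on small instances).
* Between-occasion variability is not modeled (one occasion per subject),
  and three-compartment disposition is not fitted, though the
  sum-of-exponentials container would extend to it.
* Only (η_CL, η_V1) are random effects; BSV on Q or V2 was rejected in the
  source for shrinkage above the 35% rule.
* The bootstrap can be slow at its default 1000 runs with the full model;
  replicates that fail to converge are skipped and logged.
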