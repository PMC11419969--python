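# Methods

## Structural model and units

Tacrolimus kinetics follow a one-compartment model with first-order oral
absorption and first-order elimination.  With apparent volume V/F (L),
apparent clearance CL/F (L/h), absorption constant ka (1/h) and
ke = CL/V, the concentration after repeated dosing is the superposition of
Bateman terms over all administered doses; doses are in mg, times in h,
and the single mg/L → ng/mL conversion (×1000) is applied in one place
(`model.concentration`).  A dose of 1 mg into 2690 L sets the scale:
0.372 ng/mL per unit of the accumulation sum.  When ka and ke coincide to
within 1e−8 relative, the analytic limit D·ka·Δt·e^(−ka·Δt)/V is used.
Concentrations are never negative and are zero before the first dose;
an observation exactly at a dose time excludes that dose (trough
convention).

Defaults reproduce the published final model: ka = 8.39 h⁻¹ (fixed in
estimation), tvV = 2690 L, tvCL = 42.87 L/h, ω²_V = 0.02, ω²_CL = 0.16
(lognormal inter-individual variability), σ = 3.50 ng/mL additive residual
error.  The implied elimination half-life is ≈ 43 h, so a q12h regimen is
far from steady state on day 3 — the day-3 trough is deliberately defined
as the concentration at t = 72 h after doses at 0, 12, …, 60 h rather than
as a steady-state trough.

## Covariate model

The published analysis identified voriconazole concentration (C_VRC,
µg/mL) and serum creatinine (CREA, µmol/L) as covariates, with negative
coefficients on V/F (C_VRC, CREA) and CL/F (C_VRC), but did not state the
functional family, and a pure power law in C_VRC is undefined at the
observed median C_VRC = 0.  The default family is therefore exponential in
C_VRC and a power of CREA/237 (the cohort median) for creatinine:

    CL/F = tvCL · exp(θ_VRC-CL·C_VRC),
    V/F  = tvV · exp(θ_VRC-V·C_VRC) · (CREA/237)^θ_CREA-V.

Two alternative families are implemented and selectable — `power_shifted`
((1+C_VRC)^θ) and `linear` (1+θ·C_VRC, floored at a small positive value) —
and a calibration utility refits each family's coefficients against the
published day-3 trough tables and reports the residual log-deviation.  No
implemented family reproduces those tables exactly: the published
covariate-to-trough relationship grows super-exponentially above
C_VRC ≈ 5 µg/mL (a region the source itself flags as extrapolation beyond
the observed 0–3.38 µg/mL), and the published cell means at the reference
covariates are closer to steady-state troughs than to six-dose day-3
troughs.  The comparison is surfaced (`compare_with_reference`,
`calibrate_covariate_family`) rather than hidden; PTA consistency checks
are parameterised by the published cell means/SDs directly.

## Time-varying covariates: piecewise state propagation

Covariates are time-varying within subject (piecewise-constant between
visits).  Predictions propagate the depot and central *amounts* exactly
through a per-subject event schedule (doses and observations): within a
segment all parameters are constant and the state advances in closed form;
at a covariate change the amounts are continuous, so a drop in V/F raises
concentration immediately while the new ke takes over the subsequent
decay.  Each segment takes the covariate value recorded at the next
observation (carried backward).  With constant covariates this reduces
exactly to the multiple-dose superposition closed form (tested).  This
convention matters: near steady state a trough is almost insensitive to
V/F (the accumulation factor cancels the 1/V scale), so the information
about V-side covariate effects lives almost entirely in the transients
that follow covariate changes; applying each observation's covariates to
the whole dose history (a quasi-steady shortcut) erases most of it.

## Estimation

The marginal likelihood integrates the per-subject random effects
η = (η_V, η_CL) out of the joint density.  Per subject, a damped-Newton
search (analytic gradient and Hessian for the additive-error model;
central differences for proportional/combined) locates the joint-density
mode, and the Laplace approximation supplies

    −2·log L_i ≈ h(η̂) + log det(∇²h(η̂)/2) − q·log 2π,

with h the −2 log joint density and q the number of active random
effects; OFV = Σ_i −2 log L_i, with all constants retained, so that
OFV = −2·log-likelihood exactly.  The inner search always starts from
η = 0 so the OFV is a pure function of the parameters; subjects whose
joint density is genuinely multimodal are resolved to the zero-basin mode
(a known limitation of mode-based approximations).  Non-convergent inner
searches are flagged, and their contributions inflated by a fixed penalty,
never silently dropped.  On small datasets the Laplace OFV agrees with a
40-point tensor Gauss–Hermite quadrature to well under 0.5 units
(tested).

The outer problem minimises OFV over log-transformed positive parameters
(tvV, tvCL, ω², σ; θ untransformed in [−5, 5]) with L-BFGS-B.  The
gradient differences the Laplace objective with the inner modes
warm-refined by two Newton iterations per perturbation — numerically
indistinguishable from differencing full inner solves at a fraction of the
cost.  Multi-start (default 5, jittered ±50 %) guards against local
minima; fits are bitwise reproducible given the seed.  Standard errors
come from the observed information (finite-difference Hessian of OFV/2,
delta method back to the natural scale); a singular information matrix
leaves SEs unavailable but returns the fit.

AIC = OFV + 2k and BIC = OFV + k·ln(n_obs) count only estimated
quantities (a fixed ka is excluded) and use the number of observation
records for n; both identities are validated against the published
model-comparison arithmetic.  Shrinkage is 100·(1 − SD(η̂)/ω) with the
(n−1) SD.  CWRES linearise the model about the EBEs and standardise by
JΩJᵀ + R; with ω² = 0 they reduce exactly to (DV − PRED)/σ.

## Stepwise covariate selection

Forward inclusion adds, one at a time, the candidate with the largest OFV
drop while that drop exceeds 6.635 (χ², p ≤ 0.01); backward elimination
then removes the effect whose removal raises OFV least while that rise
stays below 10.828 (p < 0.001).  Ties break by candidate declaration
order.  Candidate fits warm-start from the parent model, with the new
coefficient initialised from a regression of the parent's EBEs on the
subject-mean covariate transform — at the parent optimum the profile in a
new θ is typically flat (the η's already absorb the covariate pattern),
and the EBE slope supplies the descent direction that a zero start lacks.
Every evaluated step is recorded in the selection trace.

## Synthetic cohorts

The generator emulates the study conditions: 19 subjects (default), q12h
oral dosing over 15 days with per-subject doses drawn from an empirical
distribution matched to the reported median 3 mg and IQR 1.5–3.5 mg
(0.25 mg grid), 7–11 observations per subject on distinct days 1–15 (≈167
total), 90 % taken 5–30 min before a scheduled dose and the rest at random
clock times.  Voriconazole exposure is an on/off course (start day 1–10,
3–8 days long) with per-visit lognormal concentrations capped at the
observed maximum 3.38 µg/mL, reproducing the sample-level summaries
(median 0, Q3 ≈ 0.5 µg/mL); creatinine combines between-subject
(log-SD 0.9 around median 237) and per-visit (log-SD 0.35) variation.
Observations are simulated through the same piecewise engine the estimator
uses and carry additive Gaussian noise; negative simulated concentrations
are retained by default (truncation is opt-in and counted).

What passing tests on these cohorts do show: the estimation machinery
recovers known generating parameters at realistic design, noise and
covariate structure, and the selection thresholds behave as specified.
What they do not show: recovery of the published estimates from the real
19-patient dataset (not deposited), robustness to model misspecification
(the generator and estimator share the structural model by construction),
dose titration by clinicians (doses are static per subject), or
assay-specific error structure.

At 100 subjects the selection of the V-side voriconazole effect is
right at the edge of its likelihood-ratio threshold: the median LRT for
θ_VRC-V ≈ 20, but per-cohort draws below 10.828 occur in roughly a fifth
of replicates (the published bootstrap SD of 0.08 for this coefficient
implies an LRT near 6 at the original n = 19, below the same threshold).
Full-set recovery therefore succeeds in most but not reliably ≥9/10
replicate cohorts.

## Validation

Bootstrap resamples subjects (the exchangeable unit in hierarchical data)
with replacement, refits warm-started from the original estimates, and
summarises converged refits with empirical percentile intervals; failed
refits are dropped and counted, with a prominent flag above 20 % failures.
The VPC simulates replicate datasets with design, dosing and covariates
fixed at observed values, bins by time after dose (deciles, small bins
merged), and compares observed 5/50/95th percentiles with the 5th–95th
band of the simulated percentiles; prediction correction (the default)
rescales by the bin-median population prediction.

## Monte Carlo simulation and PTA

Trough tables draw n = 1000 (default) individual (η_V, η_CL) pairs per
covariate level — common random numbers across dose levels, making dose
proportionality exact and the whole table reproducible bit-for-bit from
its seed — and evaluate the day-3 trough.  Residual (assay) error is
excluded from simulated troughs: the published low-dose cell SDs
(≈0.22 ng/mL) are far below σ = 3.50, so the published simulations
evidently propagate inter-individual variability only.  PTA is the
percentage of troughs inside the closed interval [5, 10] ng/mL;
recommended doses are those attaining PTA ≥ 70 %, reported per covariate
level with the minimal attaining dose.  The creatinine grid fixes
C_VRC = 0.

## Problem sizes used in checks

Parameter-recovery and selection checks use 100-subject cohorts (10
replicates / 10 seeds); bootstrap checks use 30–50 resamples at 60–100
subjects; PTA consistency uses 10⁵ draws; the ODE cross-check uses 50
random parameter sets at 20 time points.  These sizes make every check a
from-scratch computation while keeping a full run in the minutes range.

## Known limitations

- The Laplace approximation is mode-based; sporadic subjects with
  near-tied joint-density modes contribute a basin-dependent term
  (resolved deterministically from the zero start).
- ω²_V = 0.02 is small enough that its estimate often collapses to the
  boundary; V-side shrinkage is correspondingly high.
- No inter-occasion variability, off-diagonal Ω, two-compartment
  structure, absorption lag, or food/genotype effects.
- The covariate functional family above the observed C_VRC range is an
  extrapolation; the published tables cannot be reproduced there by any
  implemented family, and the calibration report quantifies the gap.
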