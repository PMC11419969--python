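# tacropk

Population pharmacokinetics of tacrolimus in renal-transplant recipients
receiving voriconazole co-therapy: a reusable implementation of the full
analysis pipeline — structural PK model, nonlinear mixed-effects estimation
with stepwise covariate selection, bootstrap and visual-predictive-check
validation, and Monte Carlo trough simulation with probability-of-target-
attainment (PTA) dose recommendation.

Tacrolimus has a narrow therapeutic window (trough target 5–10 ng/mL) and
its clearance is strongly inhibited by the azole antifungal voriconazole, a
CYP3A4 inhibitor commonly co-prescribed after renal transplantation.  The
package is aimed at pharmacometricians and clinical-pharmacology researchers
who want to fit, validate, or interrogate this interaction model, or to
stress-test the estimation workflow on simulated cohorts with known truth.

## Model

One-compartment oral kinetics with first-order absorption and elimination.
For individual *i* with voriconazole concentration C_VRC (µg/mL) and serum
creatinine CREA (µmol/L):

```
CL/F_i = tvCL · exp(θ_VRC-CL · C_VRC) · e^η_CL,     η_CL ~ N(0, ω²_CL)
V/F_i  = tvV  · exp(θ_VRC-V  · C_VRC) · (CREA/237)^θ_CREA-V · e^η_V
C(t)   = Σ_doses D·ka / (V/F_i·(ka−ke)) · (e^−ke·Δt − e^−ka·Δt) · 1000,   ke = CL/V
y_ij   = C(t_ij) + ε_ij,                            ε ~ N(0, σ²)
```

Reference typical values (used as package defaults and as the
synthetic-cohort generating truth): ka = 8.39 h⁻¹ (fixed), tvV = 2690 L,
tvCL = 42.87 L/h, θ_VRC-V = −0.20, θ_VRC-CL = −0.28, θ_CREA-V = −0.40,
ω²_V = 0.02, ω²_CL = 0.16, σ = 3.50 ng/mL.  All three covariate
coefficients are negative: higher voriconazole exposure or creatinine means
lower clearance/volume and therefore higher troughs.

Estimation maximises the marginal likelihood by a per-subject Laplace
approximation (inner damped-Newton mode search with analytic derivatives);
covariate selection uses forward inclusion (ΔOFV > 6.635, p ≤ 0.01) then
backward elimination (ΔOFV > 10.828, p < 0.001).

## Worked example

```python
import tacropk as tp
from tacropk import estimate

# a study-like synthetic cohort (19 subjects, ~167 trough samples)
data, truth = tp.generate_cohort(n_subjects=19, seed=1234)

spec = tp.ModelSpec(covariates=(("vrc", "v"), ("vrc", "cl"), ("crea", "v")))
res = estimate.fit(spec, data, n_starts=1, seed=0,
                   start={"tvV": 2690, "tvCL": 42.87, "omega2_v": 0.02,
                          "omega2_cl": 0.16, "sigma_add": 3.5})
print(f"OFV {res.ofv:.2f}  AIC {res.aic:.2f}  BIC {res.bic:.2f}")
print({k: round(v, 3) for k, v in res.params.items() if k.startswith("theta")})
```

prints

```
OFV 971.81  AIC 987.81  BIC 1013.44
{'theta_vrc_v': -0.186, 'theta_vrc_cl': -0.162, 'theta_crea_v': -0.487}
```

i.e. on this simulated replicate the three covariate effects are recovered
near their generating values (−0.20, −0.28, −0.40) at study scale (19
subjects); the OFV/AIC/BIC obey AIC = OFV + 2k and
BIC = OFV + k·ln(n_obs) with k = 8 estimated quantities and 182
observations.

Dose recommendation by Monte Carlo PTA:

```python
grid = tp.SimulationGrid(n_subjects=1000, seed=0)
table = tp.run_grid(grid, which="cvrc")          # day-3 troughs, mean/SD/PTA
rec = tp.recommend_dose(table)                   # doses with PTA >= 70 %
print(rec[rec.c_vrc == 0.0].iloc[0].attaining_doses_mg)
```

prints `[5.0, 5.5]`: at C_VRC = 0 the simulated day-3 PTA for the
5–10 ng/mL window exceeds 70 % at 5 mg q12h (the published
recommendation, 4–5 mg, sits slightly lower because the published troughs
run closer to steady state than six-dose day-3 troughs), and the attaining
dose shifts far lower as C_VRC rises.

The command line mirrors the library
(`tacropk generate|fit|select|bootstrap|vpc|simulate|recommend|recover`);
each run writes its resolved configuration and seed next to its outputs.

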