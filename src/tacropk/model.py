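"""One-compartment oral pharmacokinetic model for tacrolimus.

Closed-form multiple-dose kinetics with first-order absorption and
elimination, covariate scaling of the typical parameters, lognormal
inter-individual variability, and an additive residual error model.

Units are fixed package-wide: dose in mg, volume in L, clearance in L/h,
time in h, tacrolimus concentration in ng/mL, voriconazole concentration
(``c_vrc``) in ug/mL, serum creatinine (``crea``) in umol/L.  The single
mg/L -> ng/mL conversion (x1000) lives in :func:`concentration`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StructuralParams",
    "CovariateEffects",
    "RandomEffectSpec",
    "SubjectCovariates",
    "DosingRegimen",
    "COVARIATE_FORMS",
    "UNIT_SCALE_NG_PER_MG_L",
    "concentration",
    "apply_covariates",
    "covariate_multipliers",
    "individual_params",
    "predict_observation",
    "day3_regimen",
    "day3_trough",
]

#: ng/mL per (mg dose / L volume); applied in exactly one place.
UNIT_SCALE_NG_PER_MG_L = 1000.0

#: Relative tolerance below which ka and ke are treated as coincident and
#: the analytic limit of the absorption term is used.
_KA_KE_DEGENERACY_RTOL = 1e-8

#: Supported functional families for the voriconazole-concentration effect.
#: The creatinine effect is always a power of CREA/crea_ref (defined and
#: positive on the whole covariate domain).
COVARIATE_FORMS = ("exponential", "power_shifted", "linear")


@dataclass(frozen=True)
class StructuralParams:
    """Typical structural parameters of the one-compartment oral model.

    Attributes
    ----------
    ka : float
        First-order absorption rate constant, 1/h.
    v_f : float
        Apparent volume of distribution V/F, L.
    cl_f : float
        Apparent oral clearance CL/F, L/h.
    """

    ka: float
    v_f: float
    cl_f: float

    def __post_init__(self) -> None:
        if not (self.ka > 0 and self.v_f > 0 and self.cl_f > 0):
            raise ValueError(
                f"structural parameters must be strictly positive, got "
                f"ka={self.ka}, v_f={self.v_f}, cl_f={self.cl_f}"
            )

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/F / (V/F), 1/h."""
        return self.cl_f / self.v_f


@dataclass(frozen=True)
class CovariateEffects:
    """Covariate effect coefficients on the typical parameters.

    With the default ``exponential`` family::

        CL/F = tvCL * exp(theta_vrc_cl * c_vrc) * (crea/crea_ref)**theta_crea_cl
        V/F  = tvV  * exp(theta_vrc_v  * c_vrc) * (crea/crea_ref)**theta_crea_v

    ``power_shifted`` replaces exp(theta*x) by (1 + x)**theta and ``linear``
    by max(1 + theta*x, eps); all three are defined at the observed median
    c_vrc = 0 and reproduce the sign structure of the final model
    (negative thetas: higher voriconazole exposure -> lower CL/F and V/F).
    """

    theta_vrc_v: float = 0.0
    theta_vrc_cl: float = 0.0
    theta_crea_v: float = 0.0
    theta_crea_cl: float = 0.0
    crea_ref: float = 237.0
    form: str = "exponential"

    def __post_init__(self) -> None:
        if self.crea_ref <= 0:
            raise ValueError("crea_ref must be > 0")
        if self.form not in COVARIATE_FORMS:
            raise ValueError(
                f"unknown covariate form {self.form!r}; expected one of {COVARIATE_FORMS}"
            )


@dataclass(frozen=True)
class RandomEffectSpec:
    """Inter-individual variability and residual error magnitudes.

    ``omega2_v`` and ``omega2_cl`` are variances of the log-scale random
    effects on V/F and CL/F; ``sigma_add`` is the additive residual SD in
    ng/mL.
    """

    omega2_v: float = 0.02
    omega2_cl: float = 0.16
    sigma_add: float = 3.50

    def __post_init__(self) -> None:
        if self.omega2_v < 0 or self.omega2_cl < 0:
            raise ValueError("omega2 variances must be >= 0")
        if self.sigma_add <= 0:
            raise ValueError("sigma_add must be > 0")


@dataclass(frozen=True)
class SubjectCovariates:
    """Covariate values for one subject (or one observation record)."""

    c_vrc: float = 0.0
    crea: float = 237.0

    def __post_init__(self) -> None:
        if self.c_vrc < 0:
            raise ValueError("c_vrc must be >= 0")
        if self.crea <= 0:
            raise ValueError("crea must be > 0")


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated oral dosing: ``n_doses`` doses of ``dose_mg`` every ``tau_h``."""

    dose_mg: float
    tau_h: float = 12.0
    n_doses: int = 6
    t_first: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise ValueError("dose_mg must be >= 0")
        if self.tau_h <= 0:
            raise ValueError("tau_h must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    @property
    def dose_times(self) -> np.ndarray:
        return self.t_first + self.tau_h * np.arange(self.n_doses)


def day3_regimen(dose_mg: float, tau_h: float = 12.0) -> DosingRegimen:
    """q12h regimen whose trough at t = 72 h is the day-3 trough (6 doses at
    0, 12, ..., 60 h; the observation falls immediately before the 7th dose).
    Steady state is deliberately not assumed (typical t1/2 ~ 43 h)."""
    return DosingRegimen(dose_mg=dose_mg, tau_h=tau_h, n_doses=6, t_first=0.0)


def _absorption_term(ka: float, ke: np.ndarray | float, dt: np.ndarray) -> np.ndarray:
    """Per-dose unit-dose absorption profile ka/(ka-ke)*(e^-ke*dt - e^-ka*dt),
    with the analytic limit ka*dt*e^-ka*dt when ka ~= ke."""
    ke = np.asarray(ke, dtype=float)
    dt = np.asarray(dt, dtype=float)
    degenerate = np.abs(ka - ke) < _KA_KE_DEGENERACY_RTOL * ka
    ke_safe = np.where(degenerate, ka * 0.5, ke)
    regular = ka / (ka - ke_safe) * (np.exp(-ke_safe * dt) - np.exp(-ka * dt))
    limit = ka * dt * np.exp(-ka * dt)
    return np.where(degenerate, limit, regular)


def concentration(
    params: StructuralParams,
    regimen: DosingRegimen,
    t: float | np.ndarray,
) -> float | np.ndarray:
    """Concentration (ng/mL) at time(s) ``t`` under multiple oral dosing.

    Superposition over all doses administered at or before ``t`` of the
    standard first-order absorption term

        D * ka / (V * (ka - ke)) * (e^(-ke*dt) - e^(-ka*dt)),  ke = CL/V,

    evaluated in mg/L and returned in ng/mL.  Returns 0 before the first
    dose and is never negative.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    dt = t_arr[:, None] - regimen.dose_times[None, :]
    live = dt > 0
    terms = np.where(live, _absorption_term(params.ka, params.ke, np.where(live, dt, 0.0)), 0.0)
    conc = regimen.dose_mg / params.v_f * terms.sum(axis=1) * UNIT_SCALE_NG_PER_MG_L
    conc = np.maximum(conc, 0.0)
    return conc if np.ndim(t) else float(conc[0])


def covariate_multipliers(
    effects: CovariateEffects,
    c_vrc: float | np.ndarray,
    crea: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative covariate factors ``(g_v, g_cl)`` on V/F and CL/F.

    Vectorised over covariate arrays; raises on non-positive creatinine.
    """
    c_vrc = np.asarray(c_vrc, dtype=float)
    crea = np.asarray(crea, dtype=float)
    if np.any(crea <= 0):
        raise ValueError("crea must be > 0")
    if np.any(c_vrc < 0):
        raise ValueError("c_vrc must be >= 0")
    if effects.form == "exponential":
        fv = np.exp(effects.theta_vrc_v * c_vrc)
        fcl = np.exp(effects.theta_vrc_cl * c_vrc)
    elif effects.form == "power_shifted":
        fv = (1.0 + c_vrc) ** effects.theta_vrc_v
        fcl = (1.0 + c_vrc) ** effects.theta_vrc_cl
    else:  # linear, floored away from zero to stay positive
        fv = np.maximum(1.0 + effects.theta_vrc_v * c_vrc, 1e-6)
        fcl = np.maximum(1.0 + effects.theta_vrc_cl * c_vrc, 1e-6)
    ratio = crea / effects.crea_ref
    g_v = fv * ratio**effects.theta_crea_v
    g_cl = fcl * ratio**effects.theta_crea_cl
    return g_v, g_cl


def apply_covariates(
    typical: StructuralParams,
    effects: CovariateEffects,
    cov: SubjectCovariates,
) -> StructuralParams:
    """Covariate-adjusted typical parameters for one subject.

    Ka is never covariate-scaled.  At the reference covariates
    (c_vrc = 0, crea = crea_ref) the typical values are returned unchanged.
    """
    g_v, g_cl = covariate_multipliers(effects, cov.c_vrc, cov.crea)
    return replace(typical, v_f=typical.v_f * float(g_v), cl_f=typical.cl_f * float(g_cl))


def individual_params(
    typical_adj: StructuralParams,
    eta_v: float = 0.0,
    eta_cl: float = 0.0,
) -> StructuralParams:
    """Apply log-scale random effects: V/F_i = V/F*e^eta_v, CL/F_i = CL/F*e^eta_cl.

    With eta ~ N(0, omega2) the median individual parameter equals the
    typical value (lognormal median property).
    """
    return replace(
        typical_adj,
        v_f=typical_adj.v_f * float(np.exp(eta_v)),
        cl_f=typical_adj.cl_f * float(np.exp(eta_cl)),
    )


def predict_observation(
    conc_true: float | np.ndarray,
    sigma_add: float,
    rng: np.random.Generator,
) -> float | np.ndarray:
    """Observed concentration under the additive residual model.

    observed = conc_true + eps, eps ~ N(0, sigma_add^2).  Negative simulated
    observations are retained; the cohort generator may truncate them as an
    explicitly flagged option.
    """
    if sigma_add <= 0:
        raise ValueError("sigma_add must be > 0")
    conc_true = np.asarray(conc_true, dtype=float)
    if np.any(conc_true < 0):
        raise ValueError("conc_true must be >= 0")
    out = conc_true + rng.normal(0.0, sigma_add, size=conc_true.shape)
    return out if out.ndim else float(out)


def day3_trough(
    typical: StructuralParams,
    effects: CovariateEffects,
    cov: SubjectCovariates,
    dose_mg: float,
    eta_v: float = 0.0,
    eta_cl: float = 0.0,
) -> float:
    """Day-3 trough (t = 72 h, q12h doses at 0..60 h) for one individual."""
    p = individual_params(apply_covariates(typical, effects, cov), eta_v, eta_cl)
    return float(concentration(p, day3_regimen(dose_mg), 72.0))


#: Typical values of the published final model (reference defaults used
#: across the package and the synthetic-cohort generator).
FINAL_STRUCTURAL = StructuralParams(ka=8.39, v_f=2690.0, cl_f=42.87)
FINAL_EFFECTS = CovariateEffects(
    theta_vrc_v=-0.20, theta_vrc_cl=-0.28, theta_crea_v=-0.40, crea_ref=237.0
)
FINAL_RANEF = RandomEffectSpec(omega2_v=0.02, omega2_cl=0.16, sigma_add=3.50)

__all__ += ["FINAL_STRUCTURAL", "FINAL_EFFECTS", "FINAL_RANEF"]
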