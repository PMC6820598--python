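"""Covariate model mapping demographics to typical PK parameters.

The published model for the plasma-derived factor VIII/VWF concentrate is a
two-compartment model with fat-free mass (FFM) as a power covariate on CL,
V1 and V2 and a piecewise-linear age effect on CL above the population
median age:

    CL = CL_pop (FFM/50.5)^theta_FFM-CL (1 + theta_AGE-CL max(0, AGE-25)/25) e^eta_CL
    V1 = V1_pop (FFM/50.5)^theta_FFM-V1 e^eta_V1
    Q  = Q_pop
    V2 = V2_pop (FFM/50.5)^theta_FFM-V2

Between-subject variability is log-normal on CL and V1 with correlated
random effects; residual error is proportional.

Fat-free mass is computed with the maturation-weighted model of Al-Sallami
et al. (itself built on the Janmahasatian adult form), the standard choice
for pharmacokinetic body-size scaling across the paediatric-to-adult age
range.  The male constants are used throughout (haemophilia A cohorts are
male); the female form is provided for completeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .structural_pk import DispositionParams, MacroDisposition, micro_to_macro, terminal_half_life

__all__ = [
    "Covariates",
    "CovariateEffect",
    "PopulationModel",
    "IndividualEstimate",
    "compute_ffm",
    "impute_height",
    "typical_values",
    "individual_params",
    "omega_from_cv",
    "published_model",
    "PUBLISHED_MEDIANS",
]

# Al-Sallami maturation-weighted fat-free mass constants.
# gamma_inf: adult plateau of the maturation factor; tau (y) and delta shape
# the Hill-type maturation curve; c1, c2 are the Janmahasatian adult
# denominator constants (FFM_adult = 9270 BW / (c1 + c2 BMI)).
FFM_CONSTANTS = {
    "male": {"gamma_inf": 0.88, "tau": 13.4, "delta": 12.7, "c1": 6680.0, "c2": 216.0},
    "female": {"gamma_inf": 1.11, "tau": 7.1, "delta": 1.1, "c1": 8780.0, "c2": 244.0},
}

#: covariate medians frozen inside the published model: FFM 50.5 kg, age 25 y
PUBLISHED_MEDIANS = {"FFM": 50.5, "age": 25.0}


@dataclass(frozen=True)
class Covariates:
    """Demographics of one subject; FFM is derived, not measured."""

    BW: float
    age: float
    HT: float | None = None
    sex: Literal["male", "female"] = "male"
    FFM: float | None = None

    def __post_init__(self) -> None:
        if self.BW <= 0:
            raise ValueError(f"BW must be positive, got {self.BW}")
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.HT is not None and self.HT <= 0:
            raise ValueError(f"HT must be positive, got {self.HT}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    def with_ffm(self) -> "Covariates":
        """Return a copy with FFM filled in (no-op if already present)."""
        if self.FFM is not None:
            return self
        return replace(self, FFM=compute_ffm(self))


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relationship.

    forms:
      * ``power``:         TVP = P_pop (cov/median)^theta
      * ``linear_age``:    TVP = P_pop (1 + theta (age - median)/median)
      * ``piecewise_age``: TVP = P_pop (1 + theta max(0, age - median)/median)
    """

    parameter: Literal["CL", "V1", "Q", "V2"]
    covariate: Literal["FFM", "BW", "HT", "age"]
    form: Literal["power", "linear_age", "piecewise_age"]
    theta: float
    median: float

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError(f"median must be positive, got {self.median}")
        if self.form in ("linear_age", "piecewise_age") and self.covariate != "age":
            raise ValueError(f"form {self.form} requires covariate 'age'")

    def factor(self, cov_value: float) -> float:
        if self.form == "power":
            return (cov_value / self.median) ** self.theta
        if self.form == "linear_age":
            return 1.0 + self.theta * (cov_value - self.median) / self.median
        # piecewise_age: flat below the median-age breakpoint
        return 1.0 + self.theta * max(0.0, cov_value - self.median) / self.median


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, covariate effects, BSV covariance and residual error.

    ``fixed`` holds typical disposition parameters at the median covariates;
    ``omega`` is the 2x2 covariance of (eta_CL, eta_V1); the residual model
    is ``y = f (1 + eps_prop) + eps_add``.
    """

    fixed: DispositionParams
    effects: tuple[CovariateEffect, ...] = ()
    omega: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    name: str = "unnamed"
    version: str = "0"

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (2, 2):
            raise ValueError(f"omega must be 2x2, got shape {om.shape}")
        if not np.allclose(om, om.T):
            raise ValueError("omega must be symmetric")
        if np.min(np.linalg.eigvalsh(om)) < -1e-12:
            raise ValueError("omega must be positive-semidefinite")
        object.__setattr__(self, "omega", om)
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual SDs must be non-negative")
        if self.sigma_prop == 0 and self.sigma_add == 0:
            raise ValueError("at least one residual error component must be positive")

    @property
    def cv_cl(self) -> float:
        return float(np.sqrt(self.omega[0, 0]))

    @property
    def cv_v1(self) -> float:
        return float(np.sqrt(self.omega[1, 1]))

    @property
    def corr_cl_v1(self) -> float:
        denom = self.cv_cl * self.cv_v1
        return float(self.omega[0, 1] / denom) if denom > 0 else 0.0


@dataclass(frozen=True)
class IndividualEstimate:
    """Individual random effects and the PK parameters and metrics they imply."""

    eta: tuple[float, float]
    params: DispositionParams
    half_life: float | None = None
    tat2: float | None = None


def compute_ffm(c: Covariates) -> float:
    """Maturation-weighted fat-free mass (kg) from BW, HT, age and sex.

    FFM = [gamma_inf + (1 - gamma_inf)/(1 + (age/tau)^-delta)]
          * 9270 BW / (c1 + c2 BMI),   BMI = BW/(HT/100)^2.
    """
    if c.HT is None:
        raise ValueError(
            "height is required to compute FFM; impute it first (impute_height)"
        )
    k = FFM_CONSTANTS[c.sex]
    bmi = c.BW / (c.HT / 100.0) ** 2
    maturation = k["gamma_inf"] + (1.0 - k["gamma_inf"]) / (
        1.0 + (c.age / k["tau"]) ** (-k["delta"])
    )
    return maturation * 9270.0 * c.BW / (k["c1"] + k["c2"] * bmi)


def fit_height_regression(records: Sequence[tuple[float, float, float]]) -> np.ndarray:
    """OLS of HT on (1, BW, age) from (BW, age, HT) triples with observed HT."""
    if len(records) < 10:
        raise ValueError(
            f"need at least 10 complete records to fit the height regression, got {len(records)}"
        )
    arr = np.asarray(records, dtype=float)
    X = np.column_stack([np.ones(len(arr)), arr[:, 0], arr[:, 1]])
    coef, *_ = np.linalg.lstsq(X, arr[:, 2], rcond=None)
    return coef


def impute_height(BW: float, age: float, regression: np.ndarray) -> float:
    """Height (cm) from the fitted multilinear regression, clipped to [40, 210]."""
    b0, b1, b2 = regression
    return float(np.clip(b0 + b1 * BW + b2 * age, 40.0, 210.0))


def typical_values(model: PopulationModel, c: Covariates) -> DispositionParams:
    """Typical disposition parameters for a subject's covariates."""
    c = c.with_ffm()
    factors = {"CL": 1.0, "V1": 1.0, "Q": 1.0, "V2": 1.0}
    for eff in model.effects:
        value = {"FFM": c.FFM, "BW": c.BW, "HT": c.HT, "age": c.age}[eff.covariate]
        if value is None:
            raise ValueError(f"covariate {eff.covariate} missing for subject")
        factors[eff.parameter] *= eff.factor(value)
    cl = model.fixed.CL * factors["CL"]
    if cl <= 0:
        raise ValueError(
            f"covariate model drives CL non-positive (age={c.age}); check age effect"
        )
    v1 = model.fixed.V1 * factors["V1"]
    if model.fixed.Q is None:
        return DispositionParams(CL=cl, V1=v1)
    return DispositionParams(
        CL=cl, V1=v1, Q=model.fixed.Q * factors["Q"], V2=model.fixed.V2 * factors["V2"]
    )


def individual_params(
    model: PopulationModel, c: Covariates, eta: Sequence[float]
) -> IndividualEstimate:
    """Individual parameters: CL, V1 scaled by exp(eta); Q, V2 at typical values."""
    tv = typical_values(model, c)
    eta = (float(eta[0]), float(eta[1]))
    params = replace(tv, CL=tv.CL * math.exp(eta[0]), V1=tv.V1 * math.exp(eta[1]))
    return IndividualEstimate(eta=eta, params=params)


def omega_from_cv(cv_CL: float, cv_V1: float, corr: float) -> np.ndarray:
    """BSV covariance from the reported CVs (SDs of eta) and correlation."""
    if cv_CL < 0 or cv_V1 < 0:
        raise ValueError("CVs must be non-negative")
    if not -1.0 <= corr <= 1.0:
        raise ValueError(f"correlation must be in [-1, 1], got {corr}")
    off = corr * cv_CL * cv_V1
    return np.array([[cv_CL**2, off], [off, cv_V1**2]])


def published_model() -> PopulationModel:
    """The published population model for the plasma-derived FVIII concentrate.

    Typical values refer to the median subject (FFM 50.5 kg, age 25 y).
    """
    return PopulationModel(
        fixed=DispositionParams(CL=0.195, V1=2.30, Q=0.078, V2=0.449),
        effects=(
            CovariateEffect("CL", "FFM", "power", 0.701, PUBLISHED_MEDIANS["FFM"]),
            CovariateEffect("V1", "FFM", "power", 0.726, PUBLISHED_MEDIANS["FFM"]),
            CovariateEffect("V2", "FFM", "power", 0.842, PUBLISHED_MEDIANS["FFM"]),
            CovariateEffect("CL", "age", "piecewise_age", -0.302, PUBLISHED_MEDIANS["age"]),
        ),
        omega=omega_from_cv(0.456, 0.542, 0.797),
        sigma_prop=0.205,
        sigma_add=0.0,
        name="pdFVIII-VWF concentrate, routine clinical care development",
        version="1",
    )


def individual_half_life(model: PopulationModel, c: Covariates, eta: Sequence[float]) -> float:
    """Terminal half-life implied by a subject's individual parameters."""
    est = individual_params(model, c, eta)
    return terminal_half_life(micro_to_macro(est.params))
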