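"""Laplacian nonlinear mixed-effects estimation with censored observations.

The marginal likelihood of each subject's observations is approximated by
the Laplace method: the joint log-density

    h(eta) = log p(y | eta) + log N(eta; 0, omega)

is maximized over the subject's random effects (inner optimization, Newton
iterations started from eta = 0), and the subject's -2 log-likelihood
contribution is

    -2 [ h(eta_hat) + (d/2) log 2 pi - (1/2) log det H ],

with ``H`` the negative Hessian of ``h`` at the mode (central finite
differences, eigenvalue-floored to stay positive-definite).  Observations
below the limit of quantification enter the likelihood as left-censored
values through the Gaussian CDF at the LLOQ (the M3 method); all other
observations contribute Gaussian densities with proportional, additive or
combined residual error.

Population parameters are estimated by minimizing the total objective
function value (OFV) over log-transformed structural parameters,
unconstrained covariate coefficients, a log-Cholesky parameterization of
the between-subject covariance, and log residual SDs.  Model selection
(likelihood-ratio test with the conventional 3.84 / 6.63 thresholds),
stepwise covariate search, shrinkage diagnostics and an age-stratified
nonparametric bootstrap complete the estimation toolbox.

Implementation notes: subject predictions are evaluated in one vectorized
pass over all observation rows; gradients with respect to eta use
complex-step differentiation (the disposition algebra is holomorphic), so
inner Newton steps cost a handful of array passes regardless of the number
of subjects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr
from scipy.stats import spearmanr

from .population_model import (
    Covariates,
    CovariateEffect,
    PopulationModel,
    omega_from_cv,
)
from .structural_pk import DispositionParams
from .structural_pk import _dose_terms
from .synthetic_cohort import SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorModel",
    "FitResult",
    "BootstrapResult",
    "InnerOptimizationError",
    "subject_loglik",
    "laplace_ofv",
    "fit_population",
    "lrt_select",
    "stepwise_covariates",
    "shrinkage",
    "bootstrap",
]

#: complex-step size for eta gradients (exact to machine precision)
_CS_STEP = 1e-100
#: central-difference step for the eta Hessian
_FD_STEP = 1e-4
#: eigenvalue floor keeping the Laplace Hessian positive-definite
_EIG_FLOOR = 1e-10
#: gradient-norm tolerance of the inner optimization
_INNER_GTOL = 1e-8
#: trust-region style cap on one Newton step in eta space
_MAX_STEP = 2.0
#: relative forward-difference step for the outer OFV gradient
_GRAD_STEP = 1e-6

_LOG_2PI = float(np.log(2.0 * np.pi))


class InnerOptimizationError(RuntimeError):
    """Raised when a subject's random-effect optimization fails to converge."""


@dataclass(frozen=True)
class ErrorModel:
    """Residual unexplained variability: y = f (1 + eps_prop) + eps_add."""

    kind: Literal["additive", "proportional", "combined"]
    sigma_add: float = 0.0
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("residual SDs must be non-negative")
        if self.kind == "additive" and self.sigma_prop != 0:
            raise ValueError("additive error model cannot carry sigma_prop")
        if self.kind == "proportional" and self.sigma_add != 0:
            raise ValueError("proportional error model cannot carry sigma_add")


@dataclass
class FitResult:
    """Estimated population model with diagnostics."""

    model: PopulationModel
    ofv: float
    ebe: np.ndarray  # (n_subjects, 2) MAP eta
    eta_shrinkage: tuple[float, float]
    eps_shrinkage: float
    converged: bool
    n_blq: int
    subject_ids: tuple[str, ...] = ()
    n_obs: int = 0
    message: str = ""

    def params(self) -> dict[str, float]:
        """Named parameter estimates (structural, covariate, BSV, residual)."""
        return _model_param_dict(self.model)


@dataclass
class BootstrapResult:
    """Percentile confidence intervals from stratified resampling."""

    n_runs: int
    ci: dict[str, tuple[float, float]]
    rse: dict[str, float]
    estimates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ci.items():
            if lo > hi:
                raise ValueError(f"CI for {name} has lower > upper")


# ---------------------------------------------------------------------------
# dataset compilation: flat arrays for vectorized likelihood evaluation


@dataclass
class _Compiled:
    n_subj: int
    subject_ids: tuple[str, ...]
    # per-subject covariates
    ffm: np.ndarray
    age: np.ndarray
    bw: np.ndarray
    ht: np.ndarray
    # per-subject baseline
    endo: np.ndarray
    predose: np.ndarray  # nan when absent
    predose_time: np.ndarray
    # per-subject doses, zero-padded
    dose_amt: np.ndarray
    dose_start: np.ndarray
    dose_dur: np.ndarray
    # observation rows, grouped contiguously by subject
    obs_subj: np.ndarray
    obs_time: np.ndarray
    obs_y: np.ndarray  # lloq for BLQ rows (unused there)
    obs_blq: np.ndarray
    obs_lloq: np.ndarray
    row_starts: np.ndarray  # (n_subj,) offsets for add.reduceat


def _compile(dataset: Sequence[SubjectRecord]) -> _Compiled:
    records = [r for r in dataset if len(r.observations) > 0]
    dropped = len(dataset) - len(records)
    if dropped:
        warnings.warn(f"excluded {dropped} subject(s) without observations")
    if not records:
        raise ValueError("dataset has no subjects with observations")
    S = len(records)
    dmax = max(len(r.doses) for r in records)
    dmax = max(dmax, 1)
    dose_amt = np.zeros((S, dmax))
    dose_start = np.zeros((S, dmax))
    dose_dur = np.full((S, dmax), 1.0)  # padded doses have amount 0
    ffm = np.empty(S)
    age = np.empty(S)
    bw = np.empty(S)
    ht = np.empty(S)
    endo = np.empty(S)
    predose = np.full(S, np.nan)
    predose_time = np.zeros(S)
    rows_subj, rows_t, rows_y, rows_blq, rows_lloq = [], [], [], [], []
    row_starts = np.zeros(S, dtype=np.intp)
    pos = 0
    for s, r in enumerate(records):
        c = r.covariates.with_ffm()
        ffm[s], age[s], bw[s] = c.FFM, c.age, c.BW
        ht[s] = c.HT if c.HT is not None else np.nan
        endo[s] = r.baseline.endogenous
        if r.baseline.predose is not None:
            predose[s] = r.baseline.predose
            predose_time[s] = r.baseline.predose_time
        for j, d in enumerate(r.doses):
            dose_amt[s, j] = d.amount
            dose_start[s, j] = d.start
            dose_dur[s, j] = d.duration
        row_starts[s] = pos
        for o in r.observations:
            rows_subj.append(s)
            rows_t.append(o.time)
            rows_y.append(o.lloq if o.blq else o.value)
            rows_blq.append(o.blq)
            rows_lloq.append(o.lloq)
            pos += 1
    return _Compiled(
        n_subj=S,
        subject_ids=tuple(r.id for r in records),
        ffm=ffm,
        age=age,
        bw=bw,
        ht=ht,
        endo=endo,
        predose=predose,
        predose_time=predose_time,
        dose_amt=dose_amt,
        dose_start=dose_start,
        dose_dur=dose_dur,
        obs_subj=np.asarray(rows_subj, dtype=np.intp),
        obs_time=np.asarray(rows_t),
        obs_y=np.asarray(rows_y),
        obs_blq=np.asarray(rows_blq, dtype=bool),
        obs_lloq=np.asarray(rows_lloq),
        row_starts=row_starts,
    )


# ---------------------------------------------------------------------------
# vectorized structural prediction


def _macro_vec(CL, V1, Q, V2):
    """Batched micro-to-macro conversion; complex dtypes pass through.

    Returns (amps, rates) of shape (S, n_terms) with the terminal term last.
    """
    if Q is None:
        amps = (1.0 / V1)[:, None]
        rates = (CL / V1)[:, None]
        return amps, rates
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    b = k10 + k12 + k21
    disc = b * b - 4.0 * k10 * k21
    root = np.sqrt(disc)
    alpha = 0.5 * (b + root)
    beta = 0.5 * (b - root)
    A = (alpha - k21) / (V1 * (alpha - beta))
    B = (k21 - beta) / (V1 * (alpha - beta))
    amps = np.stack([A, B], axis=-1)
    rates = np.stack([alpha, beta], axis=-1)
    return amps, rates


def _predict_rows(comp: _Compiled, CL, V1, Q, V2):
    """Model prediction (IU/mL) at every observation row."""
    amps, rates = _macro_vec(CL, V1, Q, V2)
    s = comp.obs_subj
    conc = (
        _dose_terms(
            amps[s],
            rates[s],
            comp.dose_amt[s],
            comp.dose_start[s],
            comp.dose_dur[s],
            comp.obs_time,
        )
        / 1000.0
    )
    f = conc + comp.endo[s]
    has_pre = np.isfinite(comp.predose[s])
    if np.any(has_pre):
        beta = rates[s, -1]
        resid = np.where(has_pre, np.nan_to_num(comp.predose[s] - comp.endo[s]), 0.0)
        f = f + resid * np.exp(-beta * (comp.obs_time - comp.predose_time[s]))
    return f


def _log_ndtr_cs(z):
    """log Phi(z), complex-step aware: exact chain rule through the CDF."""
    if np.iscomplexobj(z):
        zr = z.real
        lc = log_ndtr(zr)
        ratio = np.exp(-0.5 * zr * zr - 0.5 * _LOG_2PI - lc)
        return lc + 1j * (z.imag * ratio)
    return log_ndtr(z)


def _row_loglik(f, y, blq, lloq, sigma_prop, sigma_add):
    """Per-row log-likelihood; M3 censoring for BLQ rows; complex-safe."""
    var = (sigma_prop * f) ** 2 + sigma_add**2
    freal = f.real if np.iscomplexobj(f) else f
    bad = (freal <= 0.0) & (sigma_add == 0.0)
    var = np.where(bad, 1.0, var)
    sd = np.sqrt(var)
    z_obs = (y - f) / sd
    l_obs = -0.5 * _LOG_2PI - np.log(sd) - 0.5 * z_obs * z_obs
    l_blq = _log_ndtr_cs((lloq - f) / sd)
    out = np.where(blq, l_blq, l_obs)
    # non-positive prediction with proportional-only error: steep penalty
    penalty = -1e8 * (1.0 + np.abs(freal))
    return np.where(bad, penalty, out)


def _tv_params(model: PopulationModel, comp: _Compiled):
    """Typical-value arrays per subject under the model's covariate effects."""
    cov_map = {"FFM": comp.ffm, "age": comp.age, "BW": comp.bw, "HT": comp.ht}
    fac = {"CL": 1.0, "V1": 1.0, "Q": 1.0, "V2": 1.0}
    for eff in model.effects:
        v = cov_map[eff.covariate]
        if eff.form == "power":
            f = (v / eff.median) ** eff.theta
        elif eff.form == "linear_age":
            f = 1.0 + eff.theta * (v - eff.median) / eff.median
        else:  # piecewise_age
            f = 1.0 + eff.theta * np.maximum(0.0, v - eff.median) / eff.median
        fac[eff.parameter] = fac[eff.parameter] * np.maximum(f, 1e-8)
    tvcl = model.fixed.CL * fac["CL"] * np.ones(comp.n_subj)
    tvv1 = model.fixed.V1 * fac["V1"] * np.ones(comp.n_subj)
    if model.fixed.Q is None:
        return tvcl, tvv1, None, None
    tvq = model.fixed.Q * fac["Q"] * np.ones(comp.n_subj)
    tvv2 = model.fixed.V2 * fac["V2"] * np.ones(comp.n_subj)
    return tvcl, tvv1, tvq, tvv2


def _subject_loglik_vec(comp: _Compiled, tv, sigma_prop, sigma_add, eta):
    """Per-subject sum of observation log-likelihoods; eta (S, 2), complex ok.

    ``sigma_prop``/``sigma_add`` may be scalars or per-subject arrays (used
    when several candidate parameter vectors are stacked as virtual copies
    of the dataset).
    """
    tvcl, tvv1, tvq, tvv2 = tv
    CL = tvcl * np.exp(eta[:, 0])
    V1 = tvv1 * np.exp(eta[:, 1])
    f = _predict_rows(comp, CL, V1, tvq, tvv2)
    sp = sigma_prop[comp.obs_subj] if np.ndim(sigma_prop) else sigma_prop
    sa = sigma_add[comp.obs_subj] if np.ndim(sigma_add) else sigma_add
    rows = _row_loglik(f, comp.obs_y, comp.obs_blq, comp.obs_lloq, sp, sa)
    return np.add.reduceat(rows, comp.row_starts)


def _loglik_and_grad(comp, tv, sp, sa, eta):
    """Value and eta-gradient of the per-subject log-likelihood (complex step)."""
    S = eta.shape[0]
    g = np.empty((S, 2))
    val = None
    for k in range(2):
        etac = eta.astype(complex)
        etac[:, k] = etac[:, k] + 1j * _CS_STEP
        l = _subject_loglik_vec(comp, tv, sp, sa, etac)
        g[:, k] = l.imag / _CS_STEP
        if val is None:
            val = l.real
    return val, g


def _loglik_hess_fd(comp, tv, sp, sa, eta, g0=None):
    """Finite-difference Hessian of the log-likelihood wrt eta, symmetrized.

    Central differences by default; passing the already-known gradient
    ``g0`` switches to cheaper forward differences (used for Newton
    stepping, where O(step) Hessian error only affects the search
    direction, not the converged mode or the final log-determinant).
    """
    S = eta.shape[0]
    H = np.empty((S, 2, 2))
    for k in range(2):
        ep = eta.copy()
        ep[:, k] += _FD_STEP
        _, gp = _loglik_and_grad(comp, tv, sp, sa, ep)
        if g0 is None:
            em = eta.copy()
            em[:, k] -= _FD_STEP
            _, gm = _loglik_and_grad(comp, tv, sp, sa, em)
            H[:, k, :] = (gp - gm) / (2.0 * _FD_STEP)
        else:
            H[:, k, :] = (gp - g0) / _FD_STEP
    return 0.5 * (H + np.transpose(H, (0, 2, 1)))


def _floor_pd(H: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Floor eigenvalues of symmetric (S,2,2) matrices at ``floor``."""
    w, v = np.linalg.eigh(H)
    if np.any(w < floor):
        logger.debug("Laplace Hessian eigenvalues floored (min %.3g)", w.min())
    w = np.maximum(w, floor)
    return np.einsum("sij,sj,skj->sik", v, w, v)


def _inner_solve(comp, tv, sp, sa, omega, gtol=_INNER_GTOL, max_iter=60):
    """Vectorized MAP optimization of all subjects' eta from eta = 0.

    Returns (eta_hat, h_hat, H_neg, converged) where ``H_neg`` is the exact
    finite-difference negative Hessian of h at the mode.
    """
    S = comp.n_subj
    omega = np.asarray(omega, dtype=float)
    if omega.ndim == 2:
        omega = np.broadcast_to(omega, (S, 2, 2))
    oinv = np.linalg.inv(omega)
    _, logdet_om = np.linalg.slogdet(omega)
    prior_const = -_LOG_2PI - 0.5 * logdet_om

    def h_of(eta):
        l = _subject_loglik_vec(comp, tv, sp, sa, eta)
        quad = np.einsum("si,sij,sj->s", eta, oinv, eta)
        return l + prior_const - 0.5 * quad

    eta = np.zeros((S, 2))
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        h_val = h_of(eta)
        converged = np.zeros(S, dtype=bool)
        H = None
        halved = True
        for it in range(max_iter):
            l_val, g_l = _loglik_and_grad(comp, tv, sp, sa, eta)
            g = g_l - np.einsum("sij,sj->si", oinv, eta)
            if H is None or halved or it % 2 == 0:
                H_l = _loglik_hess_fd(comp, tv, sp, sa, eta, g0=g_l)
                # stepping Hessian is floored harder than the log-det one so
                # that flat or wrongly-curved subjects take damped, bounded steps
                H = _floor_pd(oinv - H_l, floor=1e-2)
            step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
            # converged when the gradient is tiny in absolute terms or the
            # Newton step no longer moves eta (scale-invariant criterion for
            # near-degenerate, very sharp likelihoods)
            converged = (np.linalg.norm(g, axis=1) < gtol) | (
                np.linalg.norm(step, axis=1) < 1e-10
            )
            if converged.all():
                break
            norm = np.linalg.norm(step, axis=1, keepdims=True)
            step = np.where(norm > _MAX_STEP, step * (_MAX_STEP / norm), step)
            step[converged] = 0.0
            new_eta = eta + step
            h_new = h_of(new_eta)
            halved = False
            for _halve in range(25):
                worse = ~(h_new >= h_val - 1e-13) & ~converged
                if not worse.any():
                    break
                halved = True
                step[worse] *= 0.5
                new_eta = eta + step
                h_new = h_of(new_eta)
            keep = h_new >= h_val - 1e-13
            eta = np.where(keep[:, None], new_eta, eta)
            h_val = np.where(keep, h_new, h_val)
        H_l = _loglik_hess_fd(comp, tv, sp, sa, eta)
        H = _floor_pd(oinv - H_l)
        return eta, h_of(eta), H, converged


def _ofv_from_solution(h_hat: np.ndarray, H: np.ndarray) -> float:
    """Total OFV from per-subject modes and negative Hessians (d = 2)."""
    _, logdet = np.linalg.slogdet(H)
    return float(np.sum(-2.0 * h_hat - 2.0 * _LOG_2PI + logdet))


def _expand_compiled(comp: _Compiled, k: int) -> _Compiled:
    """Stack ``k`` virtual copies of the dataset along the subject axis.

    Used to evaluate the OFV at several candidate parameter vectors in a
    single vectorized inner solve (the per-copy parameters enter through
    the typical-value, sigma and omega arrays, not through the data).
    """
    from dataclasses import replace as _dc_replace

    S = comp.n_subj
    N = len(comp.obs_time)

    def rep(a):
        return np.concatenate([a] * k, axis=0)

    return _dc_replace(
        comp,
        n_subj=S * k,
        subject_ids=comp.subject_ids * k,
        ffm=rep(comp.ffm),
        age=rep(comp.age),
        bw=rep(comp.bw),
        ht=rep(comp.ht),
        endo=rep(comp.endo),
        predose=rep(comp.predose),
        predose_time=rep(comp.predose_time),
        dose_amt=rep(comp.dose_amt),
        dose_start=rep(comp.dose_start),
        dose_dur=rep(comp.dose_dur),
        obs_subj=np.concatenate([comp.obs_subj + j * S for j in range(k)]),
        obs_time=rep(comp.obs_time),
        obs_y=rep(comp.obs_y),
        obs_blq=rep(comp.obs_blq),
        obs_lloq=rep(comp.obs_lloq),
        row_starts=np.concatenate([comp.row_starts + j * N for j in range(k)]),
    )


# ---------------------------------------------------------------------------
# public likelihood API


def subject_loglik(
    model: PopulationModel, record: SubjectRecord, eta: Sequence[float]
) -> float:
    """Log-likelihood of one subject's observations given random effects.

    Non-censored observations contribute Gaussian densities (SD per the
    residual model); BLQ observations contribute ``log Phi((LLOQ - f)/sd)``.
    """
    if not record.observations:
        raise ValueError(f"subject {record.id} has no observations")
    comp = _compile([record])
    tv = _tv_params(model, comp)
    eta_arr = np.asarray(eta, dtype=float).reshape(1, 2)
    return float(
        _subject_loglik_vec(comp, tv, model.sigma_prop, model.sigma_add, eta_arr)[0]
    )


def laplace_ofv(model: PopulationModel, dataset: Sequence[SubjectRecord]) -> float:
    """Laplace-approximate OFV (-2 log marginal likelihood) of a dataset."""
    comp = _compile(dataset)
    return _laplace_ofv_compiled(model, comp)


def _laplace_ofv_compiled(model: PopulationModel, comp: _Compiled) -> float:
    if np.min(np.linalg.eigvalsh(model.omega)) <= 0:
        raise ValueError("omega must be positive-definite for Laplacian estimation")
    tv = _tv_params(model, comp)
    eta, h_hat, H, conv = _inner_solve(
        comp, tv, model.sigma_prop, model.sigma_add, model.omega
    )
    if not conv.all():
        bad = [comp.subject_ids[i] for i in np.flatnonzero(~conv)]
        raise InnerOptimizationError(
            f"inner optimization failed to converge for subject(s): {bad[:5]}"
        )
    return _ofv_from_solution(h_hat, H)


def batch_map(model: PopulationModel, dataset: Sequence[SubjectRecord]) -> np.ndarray:
    """MAP random effects for every subject under a fixed population model."""
    comp = _compile(dataset)
    tv = _tv_params(model, comp)
    eta, _, _, conv = _inner_solve(
        comp, tv, model.sigma_prop, model.sigma_add, model.omega
    )
    if not conv.all():
        bad = [comp.subject_ids[i] for i in np.flatnonzero(~conv)]
        raise InnerOptimizationError(f"MAP estimation failed for subject(s): {bad[:5]}")
    return eta


# ---------------------------------------------------------------------------
# population fit


@dataclass
class _ParamLayout:
    structure: str
    error: str
    n_effects: int

    @property
    def names(self) -> list[str]:
        out = ["log_CL", "log_V1"]
        if self.structure == "2cpt":
            out += ["log_Q", "log_V2"]
        out += [f"theta_{i}" for i in range(self.n_effects)]
        out += ["om_a", "om_b", "om_c"]
        if self.error in ("proportional", "combined"):
            out.append("log_sigma_prop")
        if self.error in ("additive", "combined"):
            out.append("log_sigma_add")
        return out


def _omega_from_chol(a: float, b: float, c: float) -> np.ndarray:
    L = np.array([[np.exp(a), 0.0], [b, np.exp(c)]])
    return L @ L.T


def _chol_from_omega(om: np.ndarray) -> tuple[float, float, float]:
    L = np.linalg.cholesky(om)
    return float(np.log(L[0, 0])), float(L[1, 0]), float(np.log(L[1, 1]))


def _build_model(
    x: np.ndarray,
    layout: _ParamLayout,
    effect_templates: Sequence[CovariateEffect],
) -> PopulationModel:
    i = 0
    CL = np.exp(x[i]); i += 1
    V1 = np.exp(x[i]); i += 1
    if layout.structure == "2cpt":
        Q = np.exp(x[i]); i += 1
        V2 = np.exp(x[i]); i += 1
        fixed = DispositionParams(CL=CL, V1=V1, Q=Q, V2=V2)
    else:
        fixed = DispositionParams(CL=CL, V1=V1)
    effects = tuple(
        replace(t, theta=float(x[i + j])) for j, t in enumerate(effect_templates)
    )
    i += layout.n_effects
    omega = _omega_from_chol(x[i], x[i + 1], x[i + 2]); i += 3
    sp = sa = 0.0
    if layout.error in ("proportional", "combined"):
        sp = float(np.exp(x[i])); i += 1
    if layout.error in ("additive", "combined"):
        sa = float(np.exp(x[i])); i += 1
    return PopulationModel(
        fixed=fixed, effects=effects, omega=omega, sigma_prop=sp, sigma_add=sa
    )


def _model_param_dict(model: PopulationModel) -> dict[str, float]:
    out = {"CL_pop": model.fixed.CL, "V1_pop": model.fixed.V1}
    if model.fixed.Q is not None:
        out["Q_pop"] = model.fixed.Q
        out["V2_pop"] = model.fixed.V2
    for eff in model.effects:
        out[f"theta_{eff.covariate}_{eff.parameter}"] = eff.theta
    out["omega_CL_sd"] = model.cv_cl
    out["omega_V1_sd"] = model.cv_v1
    out["corr_CL_V1"] = model.corr_cl_v1
    if model.sigma_prop > 0:
        out["sigma_prop"] = model.sigma_prop
    if model.sigma_add > 0:
        out["sigma_add"] = model.sigma_add
    return out


def _dataset_medians(comp: _Compiled) -> dict[str, float]:
    return {
        "FFM": float(np.median(comp.ffm)),
        "age": float(np.median(comp.age)),
        "BW": float(np.median(comp.bw)),
        "HT": float(np.median(comp.ht[np.isfinite(comp.ht)]))
        if np.any(np.isfinite(comp.ht))
        else 1.0,
    }


def fit_population(
    dataset: Sequence[SubjectRecord],
    structure: Literal["1cpt", "2cpt"] = "2cpt",
    error: Literal["additive", "proportional", "combined"] = "proportional",
    effects: Sequence[CovariateEffect] = (),
    init: PopulationModel | None = None,
    bounds: Sequence[tuple[float, float]] | None = None,
    medians: dict[str, float] | None = None,
    maxiter: int = 500,
    gtol: float = 1e-4,
) -> FitResult:
    """Maximum-likelihood population fit by the Laplacian method.

    ``effects`` are covariate-effect templates whose ``theta`` values serve
    as initial estimates; their ``median`` is overridden by the dataset
    medians unless ``medians`` is supplied.  ``init`` optionally provides
    initial structural/BSV/residual values (e.g. a published model when
    refitting or bootstrapping).
    """
    comp = _compile(dataset)
    if comp.n_subj < 20:
        warnings.warn(
            f"only {comp.n_subj} subjects; population estimates will be unstable"
        )
    med = medians if medians is not None else _dataset_medians(comp)
    effect_templates = tuple(replace(e, median=med[e.covariate]) for e in effects)
    layout = _ParamLayout(structure=structure, error=error, n_effects=len(effect_templates))

    x0 = _initial_vector(layout, effect_templates, init)
    if bounds is None:
        bounds = _default_bounds(layout)
    n_blq = int(comp.obs_blq.sum())

    best: dict = {"x": x0, "ofv": np.inf}
    p = len(x0)
    comp_k = _expand_compiled(comp, p + 1)
    S = comp.n_subj

    def _models_at(xs: list[np.ndarray]):
        models = []
        for xc in xs:
            try:
                models.append(_build_model(xc, layout, effect_templates))
            except ValueError:
                models.append(None)
        return models

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        """OFV and its forward-difference gradient in one batched inner solve."""
        zeros = np.zeros(p)
        steps = _GRAD_STEP * np.maximum(1.0, np.abs(x))
        xs = [x] + [x + steps[j] * np.eye(p)[j] for j in range(p)]
        models = _models_at(xs)
        if models[0] is None:
            return 1e12, zeros
        models = [m if m is not None else models[0] for m in models]
        tvs = [_tv_params(m, comp) for m in models]
        if tvs[0][2] is None:
            tv_k = (
                np.concatenate([t[0] for t in tvs]),
                np.concatenate([t[1] for t in tvs]),
                None,
                None,
            )
        else:
            tv_k = tuple(np.concatenate([t[i] for t in tvs]) for i in range(4))
        sp = np.concatenate([np.full(S, m.sigma_prop) for m in models])
        sa = np.concatenate([np.full(S, m.sigma_add) for m in models])
        om = np.concatenate(
            [np.broadcast_to(m.omega, (S, 2, 2)) for m in models], axis=0
        )
        if np.min(np.linalg.eigvalsh(om)) <= 0:
            return 1e12, zeros
        try:
            eta, h_hat, H, conv = _inner_solve(comp_k, tv_k, sp, sa, om)
        except (ValueError, np.linalg.LinAlgError, FloatingPointError):
            return 1e12, zeros
        if not conv.reshape(p + 1, S)[0].all():
            return 1e12, zeros
        _, logdet = np.linalg.slogdet(H)
        contrib = (-2.0 * h_hat - 2.0 * _LOG_2PI + logdet).reshape(p + 1, S)
        ofvs = contrib.sum(axis=1)
        if not np.all(np.isfinite(ofvs)):
            return 1e12, zeros
        grad = (ofvs[1:] - ofvs[0]) / steps
        if ofvs[0] < best["ofv"]:
            best["ofv"] = ofvs[0]
            best["x"] = x.copy()
        return float(ofvs[0]), grad

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": gtol},
        )
    x_hat = best["x"] if best["ofv"] < res.fun else res.x
    model = _build_model(x_hat, layout, effect_templates)
    tv = _tv_params(model, comp)
    eta, h_hat, H, conv = _inner_solve(
        comp, tv, model.sigma_prop, model.sigma_add, model.omega
    )
    ofv = _ofv_from_solution(h_hat, H)
    converged = bool(res.success) and bool(conv.all()) and np.isfinite(ofv)
    fit = FitResult(
        model=model,
        ofv=ofv,
        ebe=eta,
        eta_shrinkage=(np.nan, np.nan),
        eps_shrinkage=np.nan,
        converged=converged,
        n_blq=n_blq,
        subject_ids=comp.subject_ids,
        n_obs=len(comp.obs_time),
        message=str(res.message),
    )
    eta_shr, eps_shr = _shrinkage_from_fit(fit, comp)
    fit.eta_shrinkage = eta_shr
    fit.eps_shrinkage = eps_shr
    if not converged:
        logger.warning("fit did not converge: %s", res.message)
    return fit


def _default_bounds(layout: _ParamLayout) -> list[tuple[float, float]]:
    """Wide box bounds keeping the search inside a numerically sane region.

    BSV standard deviations are kept above 1e-3 (a variance the data cannot
    distinguish from zero) so the log-Cholesky factor stays invertible.
    """
    out: list[tuple[float, float]] = []
    for name in layout.names:
        if name.startswith("log_sigma"):
            out.append((np.log(1e-4), np.log(5.0)))
        elif name in ("om_a", "om_c"):
            out.append((np.log(1e-3), np.log(5.0)))
        elif name == "om_b":
            out.append((-10.0, 10.0))
        elif name.startswith("log_"):
            out.append((np.log(1e-6), np.log(1e4)))
        else:  # covariate theta
            out.append((-50.0, 50.0))
    return out


def _initial_vector(
    layout: _ParamLayout,
    effect_templates: Sequence[CovariateEffect],
    init: PopulationModel | None,
) -> np.ndarray:
    if init is not None:
        fixed = init.fixed
        omega = init.omega
        sp = init.sigma_prop if init.sigma_prop > 0 else 0.2
        sa = init.sigma_add if init.sigma_add > 0 else 0.02
        theta0 = []
        init_thetas = {(e.parameter, e.covariate): e.theta for e in init.effects}
        for t in effect_templates:
            theta0.append(init_thetas.get((t.parameter, t.covariate), t.theta))
    else:
        fixed = DispositionParams(CL=0.2, V1=2.5, Q=0.1, V2=0.5)
        omega = omega_from_cv(0.3, 0.3, 0.0)
        sp, sa = 0.2, 0.02
        theta0 = [t.theta for t in effect_templates]
    x = [np.log(fixed.CL), np.log(fixed.V1)]
    if layout.structure == "2cpt":
        q = fixed.Q if fixed.Q is not None else 0.1
        v2 = fixed.V2 if fixed.V2 is not None else 0.5
        x += [np.log(q), np.log(v2)]
    x += list(theta0)
    om = np.asarray(omega, dtype=float)
    if np.min(np.linalg.eigvalsh(om)) <= 1e-8:
        om = om + np.eye(2) * 1e-4
    x += list(_chol_from_omega(om))
    if layout.error in ("proportional", "combined"):
        x.append(np.log(sp))
    if layout.error in ("additive", "combined"):
        x.append(np.log(sa))
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# model selection


def lrt_select(
    fit_a: FitResult, fit_b: FitResult, df: int = 1, threshold: float = 3.84
) -> dict:
    """Likelihood-ratio comparison of a reduced (a) vs extended (b) model.

    ``dOFV = ofv_a - ofv_b``; the extension is significant when the OFV
    drops by the threshold or more (3.84 for p < 0.05 forward, 6.63 for
    p < 0.01 backward, at 1 df).
    """
    dofv = fit_a.ofv - fit_b.ofv
    significant = dofv >= threshold
    return {
        "better": "b" if significant else "a",
        "dOFV": float(dofv),
        "significant": bool(significant),
        "df": df,
    }


FORWARD_THRESHOLD = 3.84
BACKWARD_THRESHOLD = 6.63


def stepwise_covariates(
    dataset: Sequence[SubjectRecord],
    candidates: Sequence[tuple[str, str]] = (
        ("CL", "FFM"),
        ("V1", "FFM"),
        ("V2", "FFM"),
        ("CL", "BW"),
        ("V1", "BW"),
        ("CL", "age"),
    ),
    structure: Literal["1cpt", "2cpt"] = "2cpt",
    error: Literal["additive", "proportional", "combined"] = "proportional",
    corr_threshold: float = 0.6,
    init: PopulationModel | None = None,
    forward_threshold: float = FORWARD_THRESHOLD,
    backward_threshold: float = BACKWARD_THRESHOLD,
) -> FitResult:
    """Stepwise forward-inclusion / backward-elimination covariate search.

    Forward: at each step the candidate with the largest significant OFV
    drop (>= 3.84) is added; candidates on the same parameter whose
    covariate is Spearman-correlated (|rho| > ``corr_threshold``) with the
    chosen one are retired, so only the most significant of a correlated
    pair survives.  Age is tried in both linear and piecewise-linear form
    and the more significant form is kept.  Backward: effects whose removal
    worsens the OFV by less than 6.63 are eliminated.
    """
    comp = _compile(dataset)
    cov_map = {"FFM": comp.ffm, "age": comp.age, "BW": comp.bw, "HT": comp.ht}

    def make_effects(param: str, cov: str) -> list[CovariateEffect]:
        if cov == "age":
            return [
                CovariateEffect(param, "age", "linear_age", 0.0, 1.0),
                CovariateEffect(param, "age", "piecewise_age", 0.0, 1.0),
            ]
        return [CovariateEffect(param, cov, "power", 0.5, 1.0)]

    selected: list[CovariateEffect] = []
    pool = list(candidates)
    base_fit = fit_population(dataset, structure=structure, error=error, effects=selected, init=init)
    current = base_fit
    while pool:
        trials = []
        for param, cov in pool:
            for eff in make_effects(param, cov):
                fit = fit_population(
                    dataset,
                    structure=structure,
                    error=error,
                    effects=selected + [eff],
                    init=current.model,
                )
                trials.append(((param, cov), eff, fit))
        best_cand = max(trials, key=lambda t: current.ofv - t[2].ofv)
        dofv = current.ofv - best_cand[2].ofv
        if dofv < forward_threshold:
            break
        (param, cov), eff, fit = best_cand
        logger.info("forward: added %s on %s (dOFV %.2f)", cov, param, dofv)
        selected.append(eff)
        current = fit
        pool.remove((param, cov))
        # retire candidates correlated with the chosen covariate on the same parameter
        retired = []
        for p2, c2 in pool:
            if p2 != param or c2 == cov:
                continue
            rho = spearmanr(cov_map[cov], cov_map[c2]).statistic
            if abs(rho) > corr_threshold:
                retired.append((p2, c2))
        for item in retired:
            logger.info("retiring correlated candidate %s", item)
            pool.remove(item)
    # backward elimination
    changed = True
    while changed and selected:
        changed = False
        for eff in list(selected):
            reduced = [e for e in selected if e is not eff]
            fit_red = fit_population(
                dataset, structure=structure, error=error, effects=reduced, init=current.model
            )
            if fit_red.ofv - current.ofv < backward_threshold:
                logger.info(
                    "backward: removed %s on %s (dOFV %.2f)",
                    eff.covariate,
                    eff.parameter,
                    fit_red.ofv - current.ofv,
                )
                selected = reduced
                current = fit_red
                changed = True
                break
    return current


# ---------------------------------------------------------------------------
# diagnostics


def _shrinkage_from_fit(fit: FitResult, comp: _Compiled) -> tuple[tuple[float, float], float]:
    om_sd = np.sqrt(np.diag(fit.model.omega))
    with np.errstate(invalid="ignore", divide="ignore"):
        eta_shr = tuple(
            float(1.0 - np.std(fit.ebe[:, k], ddof=1) / om_sd[k]) if om_sd[k] > 0 else 1.0
            for k in range(2)
        )
    tv = _tv_params(fit.model, comp)
    tvcl, tvv1, tvq, tvv2 = tv
    CL = tvcl * np.exp(fit.ebe[:, 0])
    V1 = tvv1 * np.exp(fit.ebe[:, 1])
    f = _predict_rows(comp, CL, V1, tvq, tvv2)
    sd = np.sqrt((fit.model.sigma_prop * f) ** 2 + fit.model.sigma_add**2)
    keep = ~comp.obs_blq
    iwres = (comp.obs_y[keep] - f[keep]) / sd[keep]
    eps_shr = float(1.0 - np.std(iwres, ddof=1)) if keep.sum() > 1 else 1.0
    return eta_shr, eps_shr


def shrinkage(fit: FitResult, flag_threshold: float = 0.35) -> dict:
    """Eta and epsilon shrinkage fractions with the over-parameterization flag.

    Shrinkage of a BSV term above 35% indicates the data cannot support the
    random effect and the model is considered over-parameterized.
    """
    flags = [s > flag_threshold for s in fit.eta_shrinkage]
    return {
        "eta_CL": fit.eta_shrinkage[0],
        "eta_V1": fit.eta_shrinkage[1],
        "eps": fit.eps_shrinkage,
        "overparameterized": any(flags),
    }


# ---------------------------------------------------------------------------
# bootstrap


DEFAULT_AGE_STRATA = (12.0, 18.0)


def bootstrap(
    dataset: Sequence[SubjectRecord],
    n_runs: int = 1000,
    strata: Sequence[float] = DEFAULT_AGE_STRATA,
    seed: int | np.random.Generator = 0,
    **fit_kwargs,
) -> BootstrapResult:
    """Age-stratified nonparametric bootstrap of the population fit.

    Subjects are resampled with replacement within age strata (default
    bins < 12, 12-18, > 18 y), the model is refit on each replicate, and
    percentile 95% confidence intervals are reported per parameter.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ages = np.array([r.covariates.age for r in dataset])
    edges = np.concatenate([[-np.inf], np.sort(np.asarray(strata, dtype=float)), [np.inf]])
    labels = np.digitize(ages, edges[1:-1])
    groups = [np.flatnonzero(labels == g) for g in range(len(edges) - 1)]
    groups = [g for g in groups if len(g) > 0]
    merged = []
    for g in groups:
        if len(g) < 2 and merged:
            warnings.warn("bootstrap stratum with < 2 subjects merged with neighbor")
            merged[-1] = np.concatenate([merged[-1], g])
        else:
            merged.append(g)
    estimates: dict[str, list[float]] = {}
    n_failed = 0
    for _run in range(n_runs):
        idx = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in merged])
        replicate = [dataset[i] for i in idx]
        try:
            fit = fit_population(replicate, **fit_kwargs)
        except Exception:  # non-convergent replicate: skip, as in practice
            n_failed += 1
            continue
        for name, value in fit.params().items():
            estimates.setdefault(name, []).append(value)
    if n_failed:
        logger.warning("%d bootstrap replicate(s) failed and were skipped", n_failed)
    arrays = {k: np.asarray(v) for k, v in estimates.items()}
    ci = {k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5))) for k, v in arrays.items()}
    rse = {
        k: float(np.std(v, ddof=1) / abs(np.mean(v))) if np.mean(v) != 0 else np.nan
        for k, v in arrays.items()
    }
    return BootstrapResult(n_runs=n_runs - n_failed, ci=ci, rse=rse, estimates=arrays)
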