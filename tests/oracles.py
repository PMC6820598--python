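"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed-form/Laplace code paths they check:
compartment kinetics are integrated as ODEs with infusion forcing, marginal
likelihoods by adaptive Gauss-Hermite quadrature, censored-likelihood terms
through arbitrary-precision error functions, and TAT2 by a brute-force
dense-grid scan without crossing interpolation.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from fviiipk.nlme import subject_loglik
from fviiipk.structural_pk import BaselineSpec, DispositionParams, DoseEvent, full_profile


def ode_profile(
    p: DispositionParams,
    doses: list[DoseEvent],
    t_eval: np.ndarray,
    rtol: float = 1e-11,
    atol: float = 1e-14,
) -> np.ndarray:
    """Central concentration (IU/mL) by numerical integration of the mass balance.

    State is amounts (IU) in the central and (optionally) peripheral
    compartments; infusions enter as zero-order forcing terms.
    """

    two = p.n_compartments == 2

    def rate_in(t: float) -> float:
        r = 0.0
        for d in doses:
            if d.duration <= 0:
                continue  # boluses handled via initial/impulse below
            if d.start <= t < d.start + d.duration:
                r += d.amount / d.duration
        return r

    def rhs(t, y):
        a1 = y[0]
        out = np.empty_like(y)
        elim = p.CL / p.V1 * a1
        out[0] = rate_in(t) - elim
        if two:
            a2 = y[1]
            out[0] += -p.Q / p.V1 * a1 + p.Q / p.V2 * a2
            out[1] = p.Q / p.V1 * a1 - p.Q / p.V2 * a2
        return out

    y0 = np.zeros(2 if two else 1)
    bolus_times = sorted({d.start for d in doses if d.duration <= 0})
    # integrate piecewise, injecting boluses as state jumps
    t_eval = np.asarray(t_eval, dtype=float)
    breaks = sorted(
        set(bolus_times)
        | {d.start for d in doses}
        | {d.start + d.duration for d in doses if d.duration > 0}
    )
    t0 = 0.0
    out = np.full(len(t_eval), np.nan)
    done = t_eval <= t0
    out[done] = y0[0] / p.V1 / 1000.0
    segments = [b for b in breaks if b > t0] + [max(float(t_eval.max()), t0) + 1.0]
    y = y0.copy()
    for d in doses:
        if d.duration <= 0 and d.start <= t0:
            y[0] += d.amount
    for t1 in segments:
        pts = t_eval[(t_eval > t0) & (t_eval <= t1)]
        sol = solve_ivp(
            rhs, (t0, t1), y, t_eval=np.unique(np.concatenate([pts, [t1]])),
            rtol=rtol, atol=atol, method="LSODA", max_step=np.inf,
        )
        for t, yy in zip(sol.t, sol.y[0]):
            hit = np.isclose(t_eval, t) & (t_eval > t0)
            out[hit] = yy / p.V1 / 1000.0
        y = sol.y[:, -1].copy()
        for d in doses:
            if d.duration <= 0 and np.isclose(d.start, t1):
                y[0] += d.amount
        t0 = t1
        if t0 >= t_eval.max():
            break
    return out


def agq_marginal_ofv(model, records, n_nodes: int = 32) -> float:
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    The integrand log p(y|eta) + log N(eta; 0, omega) is centered at its
    numerically located mode and scaled by a central-difference Hessian;
    integration uses a tensor-product Gauss-Hermite rule in log space.
    """
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    oinv = np.linalg.inv(model.omega)
    _, logdet_om = np.linalg.slogdet(model.omega)
    total = 0.0
    for rec in records:
        def h(eta):
            return (
                subject_loglik(model, rec, eta)
                - np.log(2 * np.pi)
                - 0.5 * logdet_om
                - 0.5 * eta @ oinv @ eta
            )

        res = minimize(lambda e: -h(e), np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        mode = res.x
        # central-difference Hessian of -h at the mode
        d = 1e-4
        H = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.eye(2)[i] * d
                ej = np.eye(2)[j] * d
                H[i, j] = -(
                    h(mode + ei + ej) - h(mode + ei - ej) - h(mode - ei + ej) + h(mode - ei - ej)
                ) / (4 * d * d)
        H = 0.5 * (H + H.T)
        L = np.linalg.cholesky(np.linalg.inv(H))
        logvals = np.empty((n_nodes, n_nodes))
        for i in range(n_nodes):
            for j in range(n_nodes):
                zz = np.array([z[i], z[j]])
                eta = mode + np.sqrt(2.0) * (L @ zz)
                logvals[i, j] = h(eta) + zz @ zz
        logw = np.log(np.outer(w, w))
        m = np.max(logvals + logw)
        integral = np.exp(m) * np.sum(np.exp(logvals + logw - m))
        loglik = np.log(integral) + np.log(2.0) + np.log(np.abs(np.linalg.det(L)))
        total += -2.0 * loglik
    return total


def exact_log_normcdf(z: float, digits: int = 30) -> float:
    """log Phi(z) through sympy's arbitrary-precision error function."""
    import sympy

    zz = sympy.Float(z, digits)
    phi = (sympy.erf(zz / sympy.sqrt(2)) + 1) / 2
    return float(sympy.log(phi).evalf(digits))


def dense_scan_tat2(
    macro, doses, baseline: BaselineSpec, threshold: float, horizon: float, dt: float = 0.001
) -> float:
    """Brute-force TAT2: count dense-grid points above threshold, no interpolation."""
    t_start = max((d.start for d in doses), default=0.0)
    grid = np.arange(t_start, horizon, dt)
    vals = np.asarray(full_profile(macro, doses, baseline, grid))
    return float(np.sum(vals > threshold) * dt)
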