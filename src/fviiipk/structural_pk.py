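"""Closed-form compartmental kinetics for intravenous factor VIII infusions.

Disposition is expressed as a sum of exponentials (macro constants).  For a
two-compartment model with micro constants ``k10 = CL/V1``, ``k12 = Q/V1``
and ``k21 = Q/V2``, the unit-bolus concentration is

    C(t) = A exp(-alpha t) + B exp(-beta t)

with ``alpha, beta`` the roots of ``s^2 - (k10+k12+k21) s + k10 k21 = 0``.
Observed factor VIII activity additionally carries an endogenous baseline
and, when a pre-dose activity above baseline was measured, a residual from
an earlier infusion that decays at the terminal rate ``beta``.

Units: doses in IU, volumes in L, clearances in L/h, times in h, activities
in IU/mL.  The 1000-fold L-to-mL conversion is applied once, at the
concentration interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DispositionParams",
    "MacroDisposition",
    "DoseEvent",
    "BaselineSpec",
    "micro_to_macro",
    "infusion_concentration",
    "full_profile",
    "terminal_half_life",
    "time_above_threshold",
]

#: default infusion duration (h) when a record does not report one
DEFAULT_INFUSION_DURATION = 0.25


@dataclass(frozen=True)
class DispositionParams:
    """Micro-constant parameterization: CL, V1 and optionally Q, V2.

    One-compartment kinetics iff ``Q`` and ``V2`` are both absent.
    """

    CL: float
    V1: float
    Q: float | None = None
    V2: float | None = None

    def __post_init__(self) -> None:
        if not (self.CL > 0 and self.V1 > 0):
            raise ValueError(f"CL and V1 must be positive, got CL={self.CL}, V1={self.V1}")
        if (self.Q is None) != (self.V2 is None):
            raise ValueError("Q and V2 must be given together (or both omitted)")
        if self.Q is not None and not (self.Q > 0 and self.V2 > 0):
            raise ValueError(f"Q and V2 must be positive, got Q={self.Q}, V2={self.V2}")

    @property
    def n_compartments(self) -> int:
        return 1 if self.Q is None else 2


@dataclass(frozen=True)
class MacroDisposition:
    """Sum-of-exponentials disposition: (amplitude, rate) pairs per unit bolus.

    Amplitudes are in 1/L; rates in 1/h, strictly ordered descending.  For a
    unit bolus the amplitudes sum to ``1/V1``.
    """

    coefficients: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("at least one exponential term required")
        rates = [r for _, r in self.coefficients]
        amps = [a for a, _ in self.coefficients]
        if any(r <= 0 for r in rates):
            raise ValueError(f"rate constants must be positive, got {rates}")
        if any(a <= 0 for a in amps):
            raise ValueError(f"amplitudes must be positive, got {amps}")
        if any(r1 <= r2 for r1, r2 in zip(rates, rates[1:])):
            raise ValueError(f"rate constants must be strictly descending, got {rates}")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.coefficients])

    @property
    def rates(self) -> np.ndarray:
        return np.array([r for _, r in self.coefficients])

    @property
    def terminal_rate(self) -> float:
        return self.coefficients[-1][1]


@dataclass(frozen=True)
class DoseEvent:
    """A single intravenous dose: amount (IU), start (h), duration (h, 0 = bolus)."""

    amount: float
    start: float = 0.0
    duration: float = DEFAULT_INFUSION_DURATION

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"dose amount must be non-negative, got {self.amount}")
        if self.duration < 0:
            raise ValueError(f"infusion duration must be non-negative, got {self.duration}")


@dataclass(frozen=True)
class BaselineSpec:
    """Endogenous factor VIII activity and optional pre-dose measurement.

    ``predose`` is the activity observed before the analyzed infusion; the
    excess over the endogenous level is treated as residual factor from an
    earlier dose and decays at the terminal rate from ``predose_time``.
    """

    endogenous: float = 0.005
    predose: float | None = None
    predose_time: float = 0.0

    def __post_init__(self) -> None:
        if self.endogenous < 0:
            raise ValueError(f"endogenous activity must be non-negative, got {self.endogenous}")
        if self.predose is not None and self.predose < 0:
            raise ValueError(f"predose activity must be non-negative, got {self.predose}")


def micro_to_macro(p: DispositionParams) -> MacroDisposition:
    """Convert micro constants to the macro (sum-of-exponentials) form.

    For two compartments, ``alpha`` and ``beta`` are the roots of
    ``s^2 - (k10+k12+k21) s + k10 k21 = 0`` and the unit-bolus amplitudes are
    ``A = (alpha - k21)/(V1 (alpha - beta))``, ``B = (k21 - beta)/(V1 (alpha - beta))``.
    One-compartment kinetics reduce to the single term ``(1/V1, CL/V1)``.
    """
    if p.n_compartments == 1:
        return MacroDisposition(((1.0 / p.V1, p.CL / p.V1),))
    k10 = p.CL / p.V1
    k12 = p.Q / p.V1
    k21 = p.Q / p.V2
    b = k10 + k12 + k21
    disc = b * b - 4.0 * k10 * k21
    if disc <= 0:
        raise ValueError("degenerate disposition: alpha == beta")
    root = np.sqrt(disc)
    alpha = 0.5 * (b + root)
    beta = 0.5 * (b - root)
    A = (alpha - k21) / (p.V1 * (alpha - beta))
    B = (k21 - beta) / (p.V1 * (alpha - beta))
    return MacroDisposition(((float(A), float(alpha)), (float(B), float(beta))))


def _dose_terms(
    amps: np.ndarray,
    rates: np.ndarray,
    amount: np.ndarray,
    start: np.ndarray,
    duration: np.ndarray,
    t: np.ndarray,
) -> np.ndarray:
    """Concentration increment (IU/L) from doses, vectorized over all axes.

    Shapes broadcast as ``t[..., None, None]`` against ``(n_doses, n_terms)``.
    Complex dtypes pass through (used for complex-step differentiation).
    """
    tt = np.asarray(t)[..., None, None]
    amt = np.asarray(amount)[..., :, None]
    t0 = np.asarray(start)[..., :, None]
    dur = np.asarray(duration)[..., :, None]
    a = amps[..., None, :]
    lam = rates[..., None, :]

    el = np.subtract(tt, t0)
    # bolus limit: treat durations below 1e-9 h as instantaneous input
    bolus = np.abs(dur) < 1e-9
    dur_safe = np.where(bolus, 1.0, dur)
    rate = amt / dur_safe
    during = (el >= 0) & (el < dur) & ~bolus
    after = (el >= dur) & ~bolus
    el_c = np.where(el >= 0, el, 0.0)
    # zero-order input: R*A/lam*(1-exp(-lam*(t-t0))) during, then decay
    inf_during = rate * a / lam * (1.0 - np.exp(-lam * el_c))
    inf_after = rate * a / lam * (1.0 - np.exp(-lam * dur_safe)) * np.exp(-lam * (el_c - dur_safe))
    bolus_term = amt * a * np.exp(-lam * el_c)
    out = np.where(during, inf_during, 0.0) + np.where(after, inf_after, 0.0)
    out = out + np.where(bolus & (el >= 0), bolus_term, 0.0)
    return out.sum(axis=(-1, -2))


def infusion_concentration(
    m: MacroDisposition, doses: Sequence[DoseEvent], t: float | np.ndarray
) -> float | np.ndarray:
    """Activity increment (IU/mL) at time ``t`` from superposed infusions.

    Times before every dose contribute zero.  Accepts scalar or array ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if not doses:
        out = np.zeros_like(t_arr)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out
    amount = np.array([d.amount for d in doses])
    start = np.array([d.start for d in doses])
    duration = np.array([d.duration for d in doses])
    out = _dose_terms(m.amplitudes, m.rates, amount, start, duration, t_arr) / 1000.0
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def full_profile(
    m: MacroDisposition,
    doses: Sequence[DoseEvent],
    b: BaselineSpec,
    t: float | np.ndarray,
    floor: bool = True,
) -> float | np.ndarray:
    """Total factor VIII activity (IU/mL): doses + endogenous + pre-dose residual.

    The residual term ``(predose - endogenous) exp(-beta (t - predose_time))``
    is applied exactly as written (it may be negative when the pre-dose
    observation sits below the endogenous level); with ``floor=True`` the
    total is clamped at zero for reporting, since activities cannot be
    negative.
    """
    t_arr = np.asarray(t, dtype=float)
    out = np.asarray(infusion_concentration(m, doses, t_arr)) + b.endogenous
    if b.predose is not None:
        beta = m.terminal_rate
        out = out + (b.predose - b.endogenous) * np.exp(-beta * (t_arr - b.predose_time))
    if floor:
        out = np.maximum(out, 0.0)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def terminal_half_life(m: MacroDisposition) -> float:
    """Terminal half-life ln(2)/beta, beta being the smallest rate constant."""
    return float(np.log(2.0) / m.terminal_rate)


def time_above_threshold(
    m: MacroDisposition,
    doses: Sequence[DoseEvent],
    b: BaselineSpec,
    threshold: float = 0.02,
    horizon: float = 168.0,
    dt: float = 0.1,
) -> float:
    """Time (h) the profile exceeds ``threshold`` between the last dose and ``horizon``.

    Evaluated on a ``dt`` grid with linear interpolation of the crossing
    points.  With the default threshold of 0.02 IU/mL this is the TAT2
    metric used for prophylaxis design.  If the endogenous level itself
    reaches the threshold the whole window counts.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    t_start = max((d.start for d in doses), default=0.0)
    if horizon <= t_start:
        raise ValueError(f"horizon {horizon} must exceed last dose start {t_start}")
    if b.endogenous >= threshold:
        return horizon - t_start
    grid = np.arange(t_start, horizon + dt, dt)
    grid = grid[grid <= horizon]
    if grid[-1] < horizon:
        grid = np.append(grid, horizon)
    vals = np.asarray(full_profile(m, doses, b, grid))
    return _grid_time_above(grid, vals, threshold)


def _grid_time_above(grid: np.ndarray, vals: np.ndarray, threshold: float):
    """Time above threshold from gridded values (last axis = time).

    Crossing points are localized by linear interpolation within each grid
    interval.  Works on any leading batch shape.
    """
    d = np.diff(grid)
    v0, v1 = vals[..., :-1], vals[..., 1:]
    a0, a1 = v0 > threshold, v1 > threshold
    dv = v1 - v0
    safe = np.where(dv == 0.0, 1.0, dv)
    lam = np.clip((threshold - v0) / safe, 0.0, 1.0)
    frac = np.where(a0 & a1, 1.0, 0.0)
    frac = np.where(a0 & ~a1, lam, frac)
    frac = np.where(~a0 & a1, 1.0 - lam, frac)
    out = np.sum(frac * d, axis=-1)
    return float(out) if out.ndim == 0 else out
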