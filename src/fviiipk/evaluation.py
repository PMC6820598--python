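"""Model evaluation pipelines: pcVPC, tenfold cross-validation, LSA.

Three simulation-based procedures probe different failure modes of a
population PK model used for Bayesian forecasting:

* the prediction-corrected visual predictive check (pcVPC) compares
  percentiles of dose/covariate-normalized observations with the same
  percentiles of model-simulated replicates of the design;
* tenfold cross-validation refits the model on 9/10 of the subjects and
  measures how much the Bayesian forecasts of the held-out subjects move
  relative to forecasts under the full-data model;
* limited sampling analysis (LSA) simulates a rich 10-sample reference
  cohort on a Monday-Wednesday-Friday prophylaxis regimen and quantifies
  the precision and bias of forecasts from 2- and 3-sample subsets.

Relative errors are always 100 (pred - pred_ref)/pred_ref with the rich or
full-data forecast as the reference.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .forecasting import TAT2_THRESHOLD, TAT2_WINDOW, relative_error
from .nlme import (
    FitResult,
    _compile,
    _inner_solve,
    _macro_vec,
    _predict_rows,
    _tv_params,
    fit_population,
)
from .population_model import PopulationModel
from .structural_pk import _dose_terms, _grid_time_above
from .synthetic_cohort import (
    LSA_SAMPLE_OFFSETS,
    DemographicsConfig,
    SubjectRecord,
    lsa_design,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VpcResult",
    "XvalSummary",
    "LsaSummary",
    "pcvpc",
    "tenfold_xval",
    "lsa",
    "designs_with_late_sample",
    "PARAMETERS",
]

PARAMETERS = ("CL", "V1", "half_life", "TAT2")


# ---------------------------------------------------------------------------
# batched individual metrics


def _batch_metrics(
    comp,
    tv,
    eta: np.ndarray,
    threshold: float = TAT2_THRESHOLD,
    window: float = TAT2_WINDOW,
    dt: float = 0.1,
    chunk: int = 64,
) -> dict[str, np.ndarray]:
    """CL, V1, half-life and TAT2 for every subject at the given etas."""
    tvcl, tvv1, tvq, tvv2 = tv
    CL = tvcl * np.exp(eta[:, 0])
    V1 = tvv1 * np.exp(eta[:, 1])
    amps, rates = _macro_vec(CL, V1, tvq, tvv2)
    half_life = np.log(2.0) / rates[:, -1]
    S = len(CL)
    t_last = comp.dose_start.max(axis=1)
    nt = int(np.floor(window / dt)) + 1
    offsets = np.linspace(0.0, window, nt)
    tat2 = np.empty(S)
    for lo in range(0, S, chunk):
        hi = min(lo + chunk, S)
        sl = slice(lo, hi)
        grid = t_last[sl, None] + offsets[None, :]
        conc = (
            _dose_terms(
                amps[sl][:, None, :],
                rates[sl][:, None, :],
                comp.dose_amt[sl][:, None, :],
                comp.dose_start[sl][:, None, :],
                comp.dose_dur[sl][:, None, :],
                grid,
            )
            / 1000.0
        )
        vals = conc + comp.endo[sl, None]
        has_pre = np.isfinite(comp.predose[sl])
        if np.any(has_pre):
            resid = np.where(has_pre, np.nan_to_num(comp.predose[sl] - comp.endo[sl]), 0.0)
            vals = vals + resid[:, None] * np.exp(
                -rates[sl, -1][:, None] * (grid - comp.predose_time[sl, None])
            )
        vals = np.maximum(vals, 0.0)
        tat2[sl] = _grid_time_above(offsets, vals, threshold)
    tat2 = np.where(comp.endo >= threshold, window, tat2)
    return {"CL": CL, "V1": V1, "half_life": half_life, "TAT2": tat2}


def _map_solve(model: PopulationModel, comp) -> np.ndarray:
    tv = _tv_params(model, comp)
    eta, _, _, conv = _inner_solve(comp, tv, model.sigma_prop, model.sigma_add, model.omega)
    if not conv.all():
        n_bad = int((~conv).sum())
        warnings.warn(f"MAP estimation unconverged for {n_bad} subject(s)")
    return eta


# ---------------------------------------------------------------------------
# prediction-corrected visual predictive check


@dataclass
class VpcResult:
    """Observed vs simulated percentile bands of prediction-corrected data."""

    bin_edges: np.ndarray
    bin_mid: np.ndarray
    percentiles: tuple[float, ...]
    observed: np.ndarray  # (3, n_bins)
    sim_lo: np.ndarray  # (3, n_bins) lower 90% CI bound
    sim_med: np.ndarray
    sim_hi: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        for b in range(self.observed.shape[1]):
            col = self.observed[:, b]
            if not np.all(np.diff(col) >= -1e-12):
                raise ValueError("observed percentile bands must be ordered within bins")

    @property
    def within(self) -> np.ndarray:
        return (self.observed >= self.sim_lo) & (self.observed <= self.sim_hi)

    @property
    def frac_within(self) -> float:
        return float(self.within.mean())

    def frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.percentiles):
            for b in range(len(self.bin_mid)):
                rows.append(
                    {
                        "bin_mid": self.bin_mid[b],
                        "percentile": p,
                        "observed": self.observed[i, b],
                        "sim_lo": self.sim_lo[i, b],
                        "sim_med": self.sim_med[i, b],
                        "sim_hi": self.sim_hi[i, b],
                    }
                )
        return pd.DataFrame(rows)


def pcvpc(
    model: PopulationModel,
    dataset: Sequence[SubjectRecord],
    n_sim: int = 500,
    bins: int = 8,
    seed: int | np.random.Generator = 0,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
) -> VpcResult:
    """Prediction-corrected VPC with the Bergstrand correction.

    Each observation and simulated value is scaled by
    ``median(PRED in bin)/PRED_ij`` where PRED is the population prediction
    (eta = 0); observed BLQ values enter at the LLOQ while simulated values
    below the LLOQ are retained numerically.  Simulated percentile bands
    carry 90% confidence intervals across ``n_sim`` design replicates.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    comp = _compile(dataset)
    tv = _tv_params(model, comp)
    tvcl, tvv1, tvq, tvv2 = tv
    pred = _predict_rows(comp, tvcl, tvv1, tvq, tvv2)
    times = comp.obs_time
    edges = np.unique(np.quantile(times, np.linspace(0.0, 1.0, bins + 1)))
    if len(edges) - 1 < bins:
        warnings.warn(f"duplicate time quantiles: using {len(edges) - 1} bins instead of {bins}")
    idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    bin_med = np.array([np.median(pred[idx == b]) for b in range(n_bins)])
    correction = bin_med[idx] / pred

    y_obs = np.where(comp.obs_blq, comp.obs_lloq, comp.obs_y)
    pc_obs = y_obs * correction
    q = np.asarray(percentiles)
    observed = np.stack(
        [np.percentile(pc_obs[idx == b], q) for b in range(n_bins)], axis=1
    )

    S = comp.n_subj
    sim_pct = np.empty((n_sim, len(q), n_bins))
    for r in range(n_sim):
        eta = rng.multivariate_normal(np.zeros(2), model.omega, size=S)
        CL = tvcl * np.exp(eta[:, 0])
        V1 = tvv1 * np.exp(eta[:, 1])
        f = _predict_rows(comp, CL, V1, tvq, tvv2)
        y = f * (1.0 + rng.normal(0.0, model.sigma_prop, f.shape)) + rng.normal(
            0.0, model.sigma_add, f.shape
        )
        pc = y * correction
        for b in range(n_bins):
            sim_pct[r, :, b] = np.percentile(pc[idx == b], q)
    sim_lo = np.percentile(sim_pct, 5.0, axis=0)
    sim_med = np.percentile(sim_pct, 50.0, axis=0)
    sim_hi = np.percentile(sim_pct, 95.0, axis=0)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return VpcResult(
        bin_edges=edges,
        bin_mid=mids,
        percentiles=tuple(percentiles),
        observed=observed,
        sim_lo=sim_lo,
        sim_med=sim_med,
        sim_hi=sim_hi,
        n_replicates=n_sim,
    )


# ---------------------------------------------------------------------------
# tenfold cross-validation


@dataclass
class XvalSummary:
    """Pooled relative errors of held-out forecasts across folds and repeats."""

    errors: pd.DataFrame  # columns: repeat, fold, subject, parameter, re
    n_repeats: int
    n_folds: int

    def summary(self) -> pd.DataFrame:
        """Median and 95th percentile of |RE| per parameter (pooled)."""
        g = self.errors.assign(abs_re=self.errors.re.abs()).groupby("parameter")["abs_re"]
        return pd.DataFrame(
            {"median_abs_re": g.median(), "p95_abs_re": g.quantile(0.95)}
        )


def tenfold_xval(
    dataset: Sequence[SubjectRecord],
    n_repeats: int = 100,
    seed: int | np.random.Generator = 0,
    n_folds: int = 10,
    structure: Literal["1cpt", "2cpt"] = "2cpt",
    error: Literal["additive", "proportional", "combined"] = "proportional",
    effects: Sequence = (),
    medians: dict[str, float] | None = None,
    full_fit: FitResult | None = None,
) -> XvalSummary:
    """Cross-validation of Bayesian forecasts against the full-data model.

    Per repeat the subjects are randomly partitioned into ``n_folds`` folds;
    the model is refit on each learning set and every held-out subject is
    MAP-forecast under the refit model and under the full-data model.  Every
    subject is predicted exactly once per repeat.  Non-convergent fold
    refits are skipped and logged.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dataset = list(dataset)
    S = len(dataset)
    if full_fit is None:
        full_fit = fit_population(
            dataset, structure=structure, error=error, effects=effects, medians=medians
        )
    ref_model = full_fit.model
    comp_all = _compile(dataset)
    tv_ref = _tv_params(ref_model, comp_all)
    eta_ref = _map_solve(ref_model, comp_all)
    ref_metrics = _batch_metrics(comp_all, tv_ref, eta_ref)

    rows = []
    for rep in range(n_repeats):
        perm = rng.permutation(S)
        folds = np.array_split(perm, n_folds)
        for k, fold in enumerate(folds):
            if len(fold) == 0:
                continue
            learn = [dataset[i] for i in perm if i not in set(fold)]
            try:
                refit = fit_population(
                    dataset=learn,
                    structure=structure,
                    error=error,
                    effects=effects,
                    medians=medians,
                    init=ref_model,
                )
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("fold %d of repeat %d failed: %s", k, rep, exc)
                continue
            if not refit.converged:
                logger.warning("fold %d of repeat %d did not converge; skipped", k, rep)
                continue
            held = [dataset[i] for i in fold]
            comp_h = _compile(held)
            tv_h = _tv_params(refit.model, comp_h)
            eta_h = _map_solve(refit.model, comp_h)
            met = _batch_metrics(comp_h, tv_h, eta_h)
            for j, i_subj in enumerate(fold):
                for p in PARAMETERS:
                    re = relative_error(met[p][j], ref_metrics[p][i_subj])
                    rows.append(
                        {
                            "repeat": rep,
                            "fold": k,
                            "subject": dataset[i_subj].id,
                            "parameter": p,
                            "re": re,
                        }
                    )
    return XvalSummary(errors=pd.DataFrame(rows), n_repeats=n_repeats, n_folds=n_folds)


# ---------------------------------------------------------------------------
# limited sampling analysis


def _all_designs(sizes: Sequence[int] = (2, 3)) -> list[tuple[int, ...]]:
    out = []
    for size in sizes:
        out.extend(itertools.combinations(range(len(LSA_SAMPLE_OFFSETS)), size))
    return out


def designs_with_late_sample(
    size: int = 3, after: float = 30.0
) -> list[tuple[int, ...]]:
    """All ``size``-sample designs with at least one draw later than ``after`` h."""
    late = {i for i, off in enumerate(LSA_SAMPLE_OFFSETS) if off > after}
    return [
        d for d in itertools.combinations(range(len(LSA_SAMPLE_OFFSETS)), size)
        if late & set(d)
    ]


@dataclass
class LsaSummary:
    """Per-design precision (median, 90th pct of |RE|) and bias (median RE)."""

    table: pd.DataFrame  # columns: design, n_samples, parameter, median_abs_re, p90_abs_re, bias
    n_subjects: int
    raw: dict[tuple[int, ...], dict[str, np.ndarray]] = field(default_factory=dict)

    def for_designs(self, designs: Sequence[tuple[int, ...]]) -> pd.DataFrame:
        keys = {tuple(d) for d in designs}
        return self.table[self.table.design.isin(keys)]


def lsa(
    model: PopulationModel | None = None,
    n_subjects: int = 1000,
    designs: Sequence[Sequence[int]] | None = None,
    seed: int | np.random.Generator = 0,
    config: DemographicsConfig | None = None,
    keep_raw: bool = True,
) -> LsaSummary:
    """Limited sampling analysis on the simulated prophylaxis cohort.

    Simulates ``n_subjects`` on 50 IU/kg Monday-Wednesday-Friday for four
    weeks, forecasts each subject under the full 10-sample reference design
    and under each sparse design (default: every 2- and 3-sample subset),
    and summarizes the relative errors of CL, V1, half-life and TAT2
    against the reference.  A design that keeps only pre-dose samples still
    runs; it is simply uninformative and shows up as large spread.
    """
    from .population_model import published_model

    mdl = model or published_model()
    records = lsa_design(n=n_subjects, seed=seed, model=mdl, config=config)
    comp = _compile(records)
    tv = _tv_params(mdl, comp)
    eta_ref = _map_solve(mdl, comp)
    ref = _batch_metrics(comp, tv, eta_ref)

    if designs is None:
        design_list = [tuple(range(len(LSA_SAMPLE_OFFSETS)))] + _all_designs((2, 3))
    else:
        design_list = [tuple(int(i) for i in d) for d in designs]
    n_per = len(LSA_SAMPLE_OFFSETS)
    S = comp.n_subj

    rows = []
    raw: dict[tuple[int, ...], dict[str, np.ndarray]] = {}
    for design in design_list:
        if any(i < 0 or i >= n_per for i in design):
            raise ValueError(f"design indices must be in [0, {n_per}), got {design}")
        take = (np.arange(S)[:, None] * n_per + np.asarray(design)[None, :]).ravel()
        comp_d = _design_subset(comp, take, len(design))
        eta_d = _map_solve(mdl, comp_d)
        met = _batch_metrics(comp_d, tv, eta_d)
        res = {p: relative_error(met[p], ref[p]) for p in PARAMETERS}
        if keep_raw:
            raw[design] = res
        for p in PARAMETERS:
            ab = np.abs(res[p])
            rows.append(
                {
                    "design": design,
                    "n_samples": len(design),
                    "parameter": p,
                    "median_abs_re": float(np.median(ab)),
                    "p90_abs_re": float(np.percentile(ab, 90.0)),
                    "bias": float(np.median(res[p])),
                }
            )
    return LsaSummary(table=pd.DataFrame(rows), n_subjects=S, raw=raw)


def _design_subset(comp, take: np.ndarray, k: int):
    """Compiled view keeping only the observation rows in ``take`` (k per subject)."""
    from dataclasses import replace as _dc_replace

    S = comp.n_subj
    return _dc_replace(
        comp,
        obs_subj=comp.obs_subj[take],
        obs_time=comp.obs_time[take],
        obs_y=comp.obs_y[take],
        obs_blq=comp.obs_blq[take],
        obs_lloq=comp.obs_lloq[take],
        row_starts=np.arange(S, dtype=np.intp) * k,
    )
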