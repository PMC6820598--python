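"""Virtual patients with the statistical structure of the development cohort.

The development population (92 males, 1.7-72 y, 9.7-119 kg, one occasion
each, 1-8 post-infusion samples, LLOQ 0.01 IU/mL with ~3% of observations
censored) is emulated by an explicit generative model: age from a truncated
log-normal, height from a male growth curve plus noise, body weight through
an age-dependent BMI with log-normal spread, fat-free mass derived.  Only
the marginal cohort summaries are published, so the joint construction here
(growth curve + BMI) is a modeling choice, parameterized in
:class:`DemographicsConfig`.

Observations are simulated under a population model: log-normal
between-subject variability on CL and V1 (correlated), proportional
residual error, censoring below the LLOQ recorded as BLQ with the value
withheld.  The limited-sampling-analysis cohort (50 IU/kg every
Monday-Wednesday-Friday for 4 weeks, 10 samples around the last Friday
dose) is provided as a dedicated design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .population_model import Covariates, PopulationModel, individual_params
from .structural_pk import BaselineSpec, DoseEvent, full_profile, micro_to_macro

__all__ = [
    "Observation",
    "SubjectRecord",
    "DemographicsConfig",
    "sample_covariates",
    "simulate_subject",
    "development_dataset",
    "lsa_design",
    "LSA_SAMPLE_OFFSETS",
]

#: sampling offsets (h) around the last dose of the limited-sampling design:
#: one pre-dose draw 30 min before the infusion and nine after it
LSA_SAMPLE_OFFSETS = (-0.5, 1.0, 3.0, 6.0, 12.0, 24.0, 30.0, 48.0, 54.0, 72.0)


@dataclass(frozen=True)
class Observation:
    """One assayed sample; censored (BLQ) samples carry no value."""

    time: float
    value: float | None
    blq: bool = False
    lloq: float = 0.01

    def __post_init__(self) -> None:
        if self.lloq <= 0:
            raise ValueError(f"LLOQ must be positive, got {self.lloq}")
        if self.blq and self.value is not None:
            raise ValueError("BLQ observation must not carry a value")
        if not self.blq and self.value is None:
            raise ValueError("non-BLQ observation must carry a value")
        if self.value is not None and self.value < 0:
            raise ValueError(f"activity cannot be negative, got {self.value}")


@dataclass(frozen=True)
class SubjectRecord:
    """Longitudinal record of one subject: covariates, doses, observations."""

    id: str
    covariates: Covariates
    baseline: BaselineSpec = field(default_factory=BaselineSpec)
    doses: tuple[DoseEvent, ...] = ()
    observations: tuple[Observation, ...] = ()
    true_eta: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        times = [o.time for o in self.observations]
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"observations of subject {self.id} must be time-sorted")


@dataclass(frozen=True)
class DemographicsConfig:
    """Generative model for the development-cohort demographics.

    Marginals were calibrated against the published cohort summaries
    (median age 25 y, median BW 63.5 kg, median FFM 50.5 kg).
    """

    age_mu: float = float(np.log(29.0))
    age_sigma: float = 0.85
    age_range: tuple[float, float] = (1.7, 72.0)
    # median male stature (cm) by age (y), linearly interpolated
    growth_knots_age: tuple[float, ...] = (0, 1, 2, 4, 6, 8, 10, 12, 14, 16, 18, 80)
    growth_knots_ht: tuple[float, ...] = (50, 76, 87, 103, 116, 128, 138, 149, 160, 169, 172, 172)
    ht_sd: float = 6.0
    ht_range: tuple[float, float] = (73.8, 188.0)
    # median BMI rises from ~16 in infancy to ~25 in adults
    bmi_base: float = 15.5
    bmi_span: float = 11.0
    bmi_halfage: float = 10.0
    bmi_sigma: float = 0.18
    bw_range: tuple[float, float] = (9.68, 119.0)

    def __post_init__(self) -> None:
        if not (0 < self.age_range[0] < self.age_range[1]):
            raise ValueError(f"invalid age range {self.age_range}")
        if len(self.growth_knots_age) != len(self.growth_knots_ht):
            raise ValueError("growth-curve knot arrays must have equal length")
        if self.age_sigma <= 0 or self.ht_sd < 0 or self.bmi_sigma < 0:
            raise ValueError("dispersion parameters must be positive")


def sample_covariates(
    n: int, seed: int | np.random.Generator, config: DemographicsConfig | None = None
) -> list[Covariates]:
    """Draw ``n`` male subjects from the development-population demographics."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    cfg = config or DemographicsConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = cfg.age_range
    ages = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(cfg.age_mu, cfg.age_sigma, size=max(n, 64))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        ages[filled : filled + take] = draw[:take]
        filled += take
    ht_med = np.interp(ages, cfg.growth_knots_age, cfg.growth_knots_ht)
    ht = np.clip(ht_med + rng.normal(0.0, cfg.ht_sd, n), *cfg.ht_range)
    bmi_med = cfg.bmi_base + cfg.bmi_span * ages / (ages + cfg.bmi_halfage)
    bmi = bmi_med * np.exp(rng.normal(0.0, cfg.bmi_sigma, n))
    bw = np.clip(bmi * (ht / 100.0) ** 2, *cfg.bw_range)
    return [
        Covariates(BW=float(bw[i]), age=float(ages[i]), HT=float(ht[i]), sex="male").with_ffm()
        for i in range(n)
    ]


def simulate_subject(
    model: PopulationModel,
    c: Covariates,
    doses: Sequence[DoseEvent],
    sampling_times: Sequence[float],
    seed: int | np.random.Generator,
    subject_id: str = "sim",
    baseline: BaselineSpec | None = None,
    lloq: float = 0.01,
    eta: Sequence[float] | None = None,
) -> SubjectRecord:
    """Simulate one subject's noisy, censored observations under ``model``.

    eta ~ N(0, omega) unless given explicitly; y = f (1 + eps_prop) + eps_add;
    simulated values below the LLOQ are recorded as censored.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if eta is None:
        eta = rng.multivariate_normal(np.zeros(2), model.omega)
    eta = (float(eta[0]), float(eta[1]))
    est = individual_params(model, c, eta)
    macro = micro_to_macro(est.params)
    b = baseline or BaselineSpec()
    times = np.sort(np.asarray(sampling_times, dtype=float))
    f = np.asarray(full_profile(macro, list(doses), b, times, floor=False))
    y = f * (1.0 + rng.normal(0.0, model.sigma_prop, len(times))) + rng.normal(
        0.0, model.sigma_add, len(times)
    )
    obs = tuple(
        Observation(time=float(t), value=None, blq=True, lloq=lloq)
        if yi < lloq
        else Observation(time=float(t), value=float(yi), blq=False, lloq=lloq)
        for t, yi in zip(times, y)
    )
    return SubjectRecord(
        id=subject_id,
        covariates=c,
        baseline=b,
        doses=tuple(doses),
        observations=obs,
        true_eta=eta,
    )


# samples-per-patient distribution matched to the cohort summary
# (mean 4.2, SD 1.5, median 5, range 1-8)
_N_SAMPLES = np.arange(1, 9)
_N_SAMPLES_P = np.array([0.04, 0.08, 0.16, 0.20, 0.35, 0.12, 0.03, 0.02])

# candidate post-infusion sampling times (h) for routine-care occasions
_DEV_TIMES = np.array([0.5, 1.0, 3.0, 6.0, 9.0, 12.0, 24.0, 30.0, 48.0, 72.0])


def development_dataset(
    n: int = 92,
    seed: int | np.random.Generator = 0,
    model: PopulationModel | None = None,
    config: DemographicsConfig | None = None,
    dose_per_kg: tuple[float, float] = (20.0, 50.0),
    lloq: float = 0.01,
) -> list[SubjectRecord]:
    """A development-like dataset: one infusion, 1-8 samples within 72 h.

    Doses are uniform on 20-50 IU/kg over a 15-min infusion; sampling times
    are drawn without replacement from routine follow-up times up to 72 h.
    """
    from .population_model import published_model

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mdl = model or published_model()
    covs = sample_covariates(n, rng, config)
    records = []
    for i, c in enumerate(covs):
        amount = float(rng.uniform(*dose_per_kg) * c.BW)
        k = int(rng.choice(_N_SAMPLES, p=_N_SAMPLES_P))
        times = np.sort(rng.choice(_DEV_TIMES, size=k, replace=False))
        rec = simulate_subject(
            mdl,
            c,
            [DoseEvent(amount=amount, start=0.0, duration=0.25)],
            times,
            rng,
            subject_id=f"S{i + 1:03d}",
            lloq=lloq,
        )
        records.append(rec)
    return records


def lsa_design(
    n: int = 1000,
    seed: int | np.random.Generator = 0,
    model: PopulationModel | None = None,
    config: DemographicsConfig | None = None,
    dose_per_kg: float = 50.0,
    weeks: int = 4,
    lloq: float = 0.01,
) -> list[SubjectRecord]:
    """The limited-sampling-analysis cohort.

    Each virtual subject receives ``dose_per_kg`` IU/kg every Monday,
    Wednesday and Friday for ``weeks`` weeks (15-min infusions); one sample
    is drawn 30 min before the last Friday dose and nine after it (1, 3, 6,
    12, 24, 30, 48, 54, 72 h).  Observation order matches
    :data:`LSA_SAMPLE_OFFSETS`, so sparse designs can be taken as index
    subsets.
    """
    from .population_model import published_model

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mdl = model or published_model()
    covs = sample_covariates(n, rng, config)
    dose_times = np.array(
        [week * 168.0 + off for week in range(weeks) for off in (0.0, 48.0, 96.0)]
    )
    anchor = dose_times[-1]  # last Friday dose
    times = anchor + np.array(LSA_SAMPLE_OFFSETS)
    records = []
    for i, c in enumerate(covs):
        amount = float(dose_per_kg * c.BW)
        doses = [DoseEvent(amount=amount, start=float(t0), duration=0.25) for t0 in dose_times]
        rec = simulate_subject(
            mdl, c, doses, times, rng, subject_id=f"L{i + 1:04d}", lloq=lloq
        )
        records.append(rec)
    return records
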