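"""Dataset and model-file serialization.

Datasets use a NONMEM-style long CSV: one row per dose or observation, with
columns ID, TIME (h), AMT (IU), DUR (h), DV (IU/mL), BLQ (0/1), LLOQ
(IU/mL), BW (kg), HT (cm), AGE (y), SEX, BASELINE (IU/mL, optional),
PREDOSE / PREDOSE_TIME (optional) and, for synthetic subjects, ETA_CL /
ETA_V1.  Time zero is the first dose of the analyzed occasion; pre-dose
observations carry negative TIME.

Population models are stored as versioned JSON files; the published model
ships with the package (``data/published_model_v1.json``) so forecasting
runs without any fitting.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .population_model import (
    Covariates,
    CovariateEffect,
    PopulationModel,
    fit_height_regression,
    impute_height,
)
from .structural_pk import BaselineSpec, DispositionParams, DoseEvent
from .synthetic_cohort import Observation, SubjectRecord

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_model",
    "write_model",
    "load_published_model",
    "DEFAULT_ENDOGENOUS",
]

DEFAULT_ENDOGENOUS = 0.005

_COLUMNS = [
    "ID", "TIME", "AMT", "DUR", "DV", "BLQ", "LLOQ",
    "BW", "HT", "AGE", "SEX", "BASELINE", "PREDOSE", "PREDOSE_TIME",
    "ETA_CL", "ETA_V1",
]


def write_dataset(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write subject records to the long-format CSV."""
    rows = []
    for r in records:
        c = r.covariates
        common = {
            "ID": r.id,
            "BW": c.BW,
            "HT": c.HT,
            "AGE": c.age,
            "SEX": c.sex,
            "BASELINE": r.baseline.endogenous,
            "PREDOSE": r.baseline.predose,
            "PREDOSE_TIME": r.baseline.predose_time if r.baseline.predose is not None else None,
            "ETA_CL": r.true_eta[0] if r.true_eta else None,
            "ETA_V1": r.true_eta[1] if r.true_eta else None,
        }
        for d in r.doses:
            rows.append({**common, "TIME": d.start, "AMT": d.amount, "DUR": d.duration,
                         "DV": None, "BLQ": 0, "LLOQ": None})
        for o in r.observations:
            rows.append({**common, "TIME": o.time, "AMT": None, "DUR": None,
                         "DV": o.value, "BLQ": int(o.blq), "LLOQ": o.lloq})
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> list[SubjectRecord]:
    """Read and validate a long-format CSV into subject records.

    Missing HT is imputed from the BW/age multilinear regression fitted on
    the complete records; a missing BASELINE defaults to 0.005 IU/mL (half
    the most common LLOQ); subjects flagged in an INHIB column (current
    inhibitors) are excluded.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"ID", "TIME"} - set(df.columns)
    if missing:
        raise ValueError(f"dataset is missing required columns: {sorted(missing)}")
    for col in _COLUMNS + ["INHIB"]:
        if col not in df.columns:
            df[col] = np.nan

    bad_rows = []
    is_dose = df["AMT"].notna() & (df["AMT"] > 0)
    is_obs = ~is_dose
    for i, row in df.iterrows():
        if is_obs[i]:
            has_dv = pd.notna(row["DV"])
            blq = bool(row["BLQ"]) if pd.notna(row["BLQ"]) else False
            if blq and has_dv:
                bad_rows.append((i + 2, "BLQ row must not carry DV"))
            if not blq and not has_dv:
                bad_rows.append((i + 2, "observation row without DV or BLQ flag"))
            if has_dv and row["DV"] < 0:
                bad_rows.append((i + 2, "negative DV"))
            if blq and (pd.isna(row["LLOQ"]) or row["LLOQ"] <= 0):
                bad_rows.append((i + 2, "BLQ row requires a positive LLOQ"))
    if bad_rows:
        detail = "; ".join(f"line {n}: {msg}" for n, msg in bad_rows[:10])
        raise ValueError(f"malformed dataset rows: {detail}")

    # height imputation from complete records
    first = df.groupby("ID", sort=False).first()
    complete = first[first["HT"].notna()]
    regression = None
    if first["HT"].isna().any():
        regression = fit_height_regression(
            list(zip(complete["BW"], complete["AGE"], complete["HT"]))
        )

    records = []
    for sid, g in df.groupby("ID", sort=False):
        head = g.iloc[0]
        if pd.notna(head.get("INHIB")) and int(head["INHIB"]) == 1:
            continue
        ht = head["HT"]
        if pd.isna(ht):
            ht = impute_height(head["BW"], head["AGE"], regression)
        cov = Covariates(
            BW=float(head["BW"]),
            age=float(head["AGE"]),
            HT=float(ht),
            sex=str(head["SEX"]) if pd.notna(head["SEX"]) else "male",
        ).with_ffm()
        endo = float(head["BASELINE"]) if pd.notna(head["BASELINE"]) else DEFAULT_ENDOGENOUS
        predose = float(head["PREDOSE"]) if pd.notna(head["PREDOSE"]) else None
        pt = float(head["PREDOSE_TIME"]) if pd.notna(head["PREDOSE_TIME"]) else 0.0
        baseline = BaselineSpec(endogenous=endo, predose=predose, predose_time=pt)
        doses = []
        obs = []
        for _, row in g.iterrows():
            if pd.notna(row["AMT"]) and row["AMT"] > 0:
                dur = float(row["DUR"]) if pd.notna(row["DUR"]) else 0.25
                doses.append(DoseEvent(amount=float(row["AMT"]), start=float(row["TIME"]), duration=dur))
            else:
                blq = bool(row["BLQ"]) if pd.notna(row["BLQ"]) else False
                lloq = float(row["LLOQ"]) if pd.notna(row["LLOQ"]) else 0.01
                obs.append(
                    Observation(
                        time=float(row["TIME"]),
                        value=None if blq else float(row["DV"]),
                        blq=blq,
                        lloq=lloq,
                    )
                )
        true_eta = None
        if pd.notna(head["ETA_CL"]) and pd.notna(head["ETA_V1"]):
            true_eta = (float(head["ETA_CL"]), float(head["ETA_V1"]))
        obs.sort(key=lambda o: o.time)
        doses.sort(key=lambda d: d.start)
        records.append(
            SubjectRecord(
                id=str(sid),
                covariates=cov,
                baseline=baseline,
                doses=tuple(doses),
                observations=tuple(obs),
                true_eta=true_eta,
            )
        )
    return records


# ---------------------------------------------------------------------------
# model files


def write_model(model: PopulationModel, path: str | Path) -> None:
    """Serialize a population model to JSON (lossless round trip)."""
    doc = {
        "name": model.name,
        "version": model.version,
        "fixed": {
            "CL": model.fixed.CL,
            "V1": model.fixed.V1,
            "Q": model.fixed.Q,
            "V2": model.fixed.V2,
        },
        "effects": [
            {
                "parameter": e.parameter,
                "covariate": e.covariate,
                "form": e.form,
                "theta": e.theta,
                "median": e.median,
            }
            for e in model.effects
        ],
        "omega": [[model.omega[i, j] for j in range(2)] for i in range(2)],
        "sigma_prop": model.sigma_prop,
        "sigma_add": model.sigma_add,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _model_from_doc(doc: dict) -> PopulationModel:
    fixed = doc["fixed"]
    params = DispositionParams(
        CL=fixed["CL"], V1=fixed["V1"], Q=fixed.get("Q"), V2=fixed.get("V2")
    )
    effects = tuple(
        CovariateEffect(
            parameter=e["parameter"],
            covariate=e["covariate"],
            form=e["form"],
            theta=e["theta"],
            median=e["median"],
        )
        for e in doc.get("effects", [])
    )
    return PopulationModel(
        fixed=params,
        effects=effects,
        omega=np.asarray(doc["omega"], dtype=float),
        sigma_prop=doc.get("sigma_prop", 0.0),
        sigma_add=doc.get("sigma_add", 0.0),
        name=doc.get("name", "unnamed"),
        version=str(doc.get("version", "0")),
    )


def read_model(path: str | Path) -> PopulationModel:
    """Read a population model from JSON, validating all invariants."""
    doc = json.loads(Path(path).read_text())
    return _model_from_doc(doc)


def load_published_model() -> PopulationModel:
    """The packaged published model (same content as ``published_model()``)."""
    with resources.files("fviiipk").joinpath("data/published_model_v1.json").open() as fh:
        return _model_from_doc(json.load(fh))
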