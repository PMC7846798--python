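"""Tidy TDM dataset schema, readers/writers and validation.

The shared dataset layout is a flat CSV with one row per concentration
observation; covariates are repeated on every row of a patient and must be
constant within patient.  Categorical covariates use the 1/2 coding of
:class:`~vancopk.covariates.CovariateVector`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .covariates import ALL_COVARIATES, CATEGORICAL_COVARIATES, CovariateVector

__all__ = [
    "TDM_COLUMNS",
    "COVARIATE_COLUMN_MAP",
    "SchemaError",
    "read_tdm_csv",
    "write_tdm_csv",
    "validate_tdm",
    "patients_frame",
    "covariate_vector_from_row",
]

#: covariate name (model-side) -> dataset column name
COVARIATE_COLUMN_MAP = {name: name for name in CATEGORICAL_COVARIATES}
COVARIATE_COLUMN_MAP.update({"Cr": "cr_umol_l", "age": "age_y", "TBW": "tbw_kg"})

TDM_COLUMNS = [
    "patient_id",
    "dose_mg",
    "interval_h",
    "tinf_h",
    "time_in_interval_h",
    "conc_ug_ml",
    "obs_type",
    "at_steady_state",
] + [COVARIATE_COLUMN_MAP[name] for name in ALL_COVARIATES]


class SchemaError(ValueError):
    """Raised when a TDM dataset violates the shared schema."""


def _row_problems(df: pd.DataFrame) -> pd.Series:
    """Per-row problem messages (empty string = clean row)."""
    msg = pd.Series("", index=df.index, dtype=object)

    def flag(mask, text):
        mask = mask.fillna(True) if hasattr(mask, "fillna") else mask
        msg[mask & (msg == "")] = text

    for name in CATEGORICAL_COVARIATES:
        col = pd.to_numeric(df[name], errors="coerce")
        flag(~col.isin([1, 2]), f"{name} must be coded 1 or 2")
    for col, text in [
        ("dose_mg", "dose_mg must be >= 0"),
        ("conc_ug_ml", "conc_ug_ml must be >= 0"),
    ]:
        flag(pd.to_numeric(df[col], errors="coerce") < 0, text)
    flag(pd.to_numeric(df["interval_h"], errors="coerce") <= 0, "interval_h must be > 0")
    tinf = pd.to_numeric(df["tinf_h"], errors="coerce")
    tau = pd.to_numeric(df["interval_h"], errors="coerce")
    flag((tinf <= 0) | (tinf > tau), "tinf_h must lie in (0, interval_h]")
    t = pd.to_numeric(df["time_in_interval_h"], errors="coerce")
    flag((t < 0) | (t > tau), "time_in_interval_h outside [0, interval_h]")
    flag(~df["obs_type"].isin(["trough", "approach_peak", "other"]), "unknown obs_type")
    flag(pd.to_numeric(df["cr_umol_l"], errors="coerce") <= 0, "cr_umol_l must be > 0")
    flag(pd.to_numeric(df["age_y"], errors="coerce") < 18, "age_y must be >= 18")
    flag(pd.to_numeric(df["tbw_kg"], errors="coerce") <= 0, "tbw_kg must be > 0")
    return msg


def validate_tdm(df: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate a TDM frame against the shared schema.

    In strict mode any violation raises :class:`SchemaError` naming the first
    offending rows; in lenient mode offending rows are dropped with a warning.
    Covariates must be constant within patient in either mode.
    """
    missing = [c for c in TDM_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    df = df.copy()
    problems = _row_problems(df)
    bad = problems != ""
    if bad.any():
        detail = "; ".join(
            f"row {i}: {problems[i]}" for i in df.index[bad][:5]
        )
        if strict:
            raise SchemaError(f"{int(bad.sum())} invalid rows ({detail})")
        warnings.warn(f"dropping {int(bad.sum())} invalid rows ({detail})")
        df = df[~bad]
    cov_cols = [COVARIATE_COLUMN_MAP[n] for n in ALL_COVARIATES]
    nuniq = df.groupby("patient_id")[cov_cols].nunique()
    varying = nuniq[(nuniq > 1).any(axis=1)]
    if len(varying):
        raise SchemaError(
            f"covariates vary within patient(s): {list(varying.index[:5])}"
        )
    for name in CATEGORICAL_COVARIATES:
        df[name] = df[name].astype(int)
    df["at_steady_state"] = df["at_steady_state"].astype(bool)
    return df.reset_index(drop=True)


def read_tdm_csv(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a tidy TDM CSV."""
    df = pd.read_csv(path)
    return validate_tdm(df, strict=strict)


def write_tdm_csv(df: pd.DataFrame, path) -> None:
    """Schema-validate and write a TDM frame (round-trip safe)."""
    validate_tdm(df, strict=True)
    df.to_csv(path, index=False)


def covariate_vector_from_row(row) -> CovariateVector:
    """Build a CovariateVector from one dataset row (or patient row)."""
    kwargs = {}
    for name in ALL_COVARIATES:
        val = row[COVARIATE_COLUMN_MAP[name]]
        kwargs[name] = int(val) if name in CATEGORICAL_COVARIATES else float(val)
    return CovariateVector(**kwargs)


def patients_frame(df: pd.DataFrame) -> pd.DataFrame:
    """One row per patient: covariates plus the (first) regimen."""
    cols = ["dose_mg", "interval_h", "tinf_h"] + [
        COVARIATE_COLUMN_MAP[n] for n in ALL_COVARIATES
    ]
    out = df.groupby("patient_id", sort=True)[cols].first().reset_index()
    return out


def design_matrices(df_patients: pd.DataFrame, selection) -> tuple[np.ndarray, np.ndarray]:
    """Stacked design rows [1, covariates...] for CL and V, one row/patient."""
    n = len(df_patients)
    z_cl = np.column_stack(
        [np.ones(n)]
        + [df_patients[COVARIATE_COLUMN_MAP[c]].to_numpy(float) for c in selection.cl_covariates]
    )
    z_v = np.column_stack(
        [np.ones(n)]
        + [df_patients[COVARIATE_COLUMN_MAP[c]].to_numpy(float) for c in selection.v_covariates]
    )
    return z_cl, z_v
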