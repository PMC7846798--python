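"""Internal goodness-of-fit diagnostics and external MPE/MAE validation.

Prediction precision is summarized by the mean prediction error (MPE) and
mean absolute prediction error (MAE) of observed vs model-predicted
concentrations.  Errors are reported in percent of the observed
concentration (the conventional scale for these summaries), with raw-unit
variants alongside; 95% confidence intervals are Student-t intervals on the
mean of per-subject errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import PopulationModel
from .io import covariate_vector_from_row
from .pk import Regimen, TDMRecord, conc_ss_arrays

__all__ = [
    "ValidationReport",
    "prediction_errors",
    "external_validate",
    "gof_diagnostics",
    "GofReport",
]


@dataclass
class ValidationReport:
    mpe_percent: float
    mpe_ci: tuple[float, float]
    mae_percent: float
    mae_ci: tuple[float, float]
    n_subjects: int
    per_subject_errors: np.ndarray  # signed percent errors
    mpe_raw: float = np.nan         # μg/ml
    mae_raw: float = np.nan         # μg/ml

    def to_dict(self) -> dict:
        return {
            "mpe_percent": float(self.mpe_percent),
            "mpe_ci": [float(x) for x in self.mpe_ci],
            "mae_percent": float(self.mae_percent),
            "mae_ci": [float(x) for x in self.mae_ci],
            "n_subjects": int(self.n_subjects),
            "mpe_raw_ug_ml": float(self.mpe_raw),
            "mae_raw_ug_ml": float(self.mae_raw),
        }


def _t_ci(x: np.ndarray) -> tuple[float, float]:
    n = len(x)
    if n < 2:
        return (float("nan"), float("nan"))
    se = x.std(ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.975, n - 1) * se
    m = x.mean()
    return (float(m - half), float(m + half))


def _report(errors_pct: np.ndarray, raw: np.ndarray | None = None) -> ValidationReport:
    abs_err = np.abs(errors_pct)
    return ValidationReport(
        mpe_percent=float(errors_pct.mean()),
        mpe_ci=_t_ci(errors_pct),
        mae_percent=float(abs_err.mean()),
        mae_ci=_t_ci(abs_err),
        n_subjects=len(errors_pct),
        per_subject_errors=errors_pct,
        mpe_raw=float(raw.mean()) if raw is not None else np.nan,
        mae_raw=float(np.abs(raw).mean()) if raw is not None else np.nan,
    )


def prediction_errors(observed, predicted) -> ValidationReport:
    """MPE/MAE (percent of observed) with t-based 95% CIs.

    One element per subject; zero observed concentrations are excluded with
    a warning (they have no defined relative error).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length nonempty vectors")
    keep = obs > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero observed concentration(s)")
        obs, pred = obs[keep], pred[keep]
    if obs.size == 0:
        raise ValueError("no positive observed concentrations")
    raw = obs - pred
    errors = raw / obs * 100.0
    return _report(errors, raw)


def external_validate(
    final_model: PopulationModel,
    external: pd.DataFrame,
    n_feedback: int = 1,
) -> ValidationReport:
    """External validation by one-point Bayesian feedback.

    For each external patient the earliest ``n_feedback`` trough
    observation(s) drive a MAP estimate of (CL, V); the remaining
    observations are predicted from it and only those enter the MPE/MAE
    (per-subject mean percent error).  Patients with a single observation
    are excluded with a warning.
    """
    from .dosing import map_estimate

    errors = []
    raw_errors = []
    skipped = 0
    for pid, grp in external.groupby("patient_id", sort=True):
        if len(grp) < n_feedback + 1:
            skipped += 1
            continue
        # canonical feedback choice: troughs first, then by sampling time and
        # concentration, so the result is independent of row order
        grp = grp.sort_values(
            ["obs_type", "time_in_interval_h", "conc_ug_ml"],
            key=lambda s: s.map({"trough": 0, "approach_peak": 1, "other": 2})
            if s.name == "obs_type"
            else s,
            kind="mergesort",
        )
        troughs = grp[grp["obs_type"] == "trough"]
        fb = (troughs if len(troughs) >= n_feedback else grp).head(n_feedback)
        rest = grp.drop(fb.index)
        row0 = fb.iloc[0]
        regimen = Regimen(row0["dose_mg"], row0["interval_h"], row0["tinf_h"])
        recs = [
            TDMRecord(str(pid), r["time_in_interval_h"], r["obs_type"], r["conc_ug_ml"])
            for _, r in fb.iterrows()
        ]
        fit = map_estimate(final_model, covariate_vector_from_row(row0), recs, regimen, str(pid))
        pred = conc_ss_arrays(
            fit.map_params.cl,
            fit.map_params.v,
            rest["dose_mg"].to_numpy(float),
            rest["interval_h"].to_numpy(float),
            rest["tinf_h"].to_numpy(float),
            rest["time_in_interval_h"].to_numpy(float),
        )
        obs = rest["conc_ug_ml"].to_numpy(float)
        pos = obs > 0
        if not pos.any():
            skipped += 1
            continue
        raw = obs[pos] - pred[pos]
        errors.append(float(np.mean(raw / obs[pos] * 100.0)))
        raw_errors.append(float(np.mean(raw)))
    if skipped:
        warnings.warn(f"excluded {skipped} patient(s) without enough usable observations")
    if not errors:
        raise ValueError("no external patients with >= 2 usable observations")
    return _report(np.asarray(errors), np.asarray(raw_errors))


@dataclass
class GofReport:
    table: pd.DataFrame            # obs, pred, residual, weighted_residual, outlier
    shapiro_statistic: float
    shapiro_p: float
    n_outliers: int
    residual_mean: float = field(default=np.nan)
    weighted_residual_mean: float = field(default=np.nan)
    weighted_residual_sd: float = field(default=np.nan)


def gof_diagnostics(fit, df: pd.DataFrame) -> GofReport:
    """Residuals, weighted residuals and a normality statistic.

    ``fit`` is a :class:`~vancopk.estimation.FitResult` (or fitted
    :class:`~vancopk.estimation.EMPopulationFitter`).  The residual column is
    observed minus the individual (empirical-Bayes) prediction; the weighted
    residual is population-level in the usual pharmacometric sense —
    (observed − population prediction) divided by the total model SD of that
    observation, √(G Ω Gᵀ + σ²) with G the parameter gradient — so that data
    simulated from a correct model give weighted residuals with mean ≈ 0 and
    SD ≈ 1.  |weighted residual| > 4 flags an outlier.
    """
    from .covariates import predict_typical
    from .estimation import EMPopulationFitter, FitResult
    from .io import covariate_vector_from_row

    if isinstance(fit, EMPopulationFitter):
        fit = FitResult.from_estimator(fit)
    if not fit.converged:
        raise ValueError("goodness-of-fit requires a converged fit")
    est = fit.individual_conditional_estimates.set_index("patient_id")
    b = est.loc[df["patient_id"], ["cl", "v"]].to_numpy(float)
    dose = df["dose_mg"].to_numpy(float)
    tau = df["interval_h"].to_numpy(float)
    tinf = df["tinf_h"].to_numpy(float)
    t = df["time_in_interval_h"].to_numpy(float)
    pred = conc_ss_arrays(b[:, 0], b[:, 1], dose, tau, tinf, t)
    obs = df["conc_ug_ml"].to_numpy(float)
    resid = obs - pred

    # population prediction and linearized total variance per observation
    typ = np.array(
        [
            [p.cl, p.v]
            for p in (
                predict_typical(fit.model, covariate_vector_from_row(r))
                for _, r in df.iterrows()
            )
        ]
    )
    pop_pred = conc_ss_arrays(typ[:, 0], typ[:, 1], dose, tau, tinf, t)
    grads = []
    for j in range(2):
        h = 1e-4 * np.maximum(np.abs(typ[:, j]), 0.1)
        up, dn = typ.copy(), typ.copy()
        up[:, j] += h
        dn[:, j] -= h
        grads.append(
            (conc_ss_arrays(up[:, 0], up[:, 1], dose, tau, tinf, t)
             - conc_ss_arrays(dn[:, 0], dn[:, 1], dose, tau, tinf, t)) / (2 * h)
        )
    g_cl, g_v = grads
    om = fit.model.omega
    var_iiv = g_cl**2 * om[0, 0] + 2 * g_cl * g_v * om[0, 1] + g_v**2 * om[1, 1]
    total_sd = np.sqrt(var_iiv + fit.model.residual_sd(pop_pred) ** 2)
    wres = (obs - pop_pred) / total_sd
    outlier = np.abs(wres) > 4.0
    if len(wres) >= 3:
        sh_stat, sh_p = stats.shapiro(wres)
    else:
        sh_stat, sh_p = np.nan, np.nan
    table = pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "observed": obs,
            "predicted": pred,
            "population_predicted": pop_pred,
            "residual": resid,
            "weighted_residual": wres,
            "outlier": outlier,
        }
    )
    return GofReport(
        table=table,
        shapiro_statistic=float(sh_stat),
        shapiro_p=float(sh_p),
        n_outliers=int(outlier.sum()),
        residual_mean=float(resid.mean()),
        weighted_residual_mean=float(wres.mean()),
        weighted_residual_sd=float(wres.std(ddof=1)) if len(wres) > 1 else np.nan,
    )


def plot_gof(report: GofReport, path_prefix: str) -> list[str]:
    """Write observed-vs-predicted scatter and weighted-residual plots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    t = report.table
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(t["predicted"], t["observed"], s=12, alpha=0.6)
    lim = max(t["predicted"].max(), t["observed"].max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("Individual predicted (μg/ml)")
    ax.set_ylabel("Observed (μg/ml)")
    fig.tight_layout()
    p = f"{path_prefix}_obs_vs_pred.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].scatter(t["predicted"], t["weighted_residual"], s=12, alpha=0.6)
    axes[0].axhline(0.0, color="k", ls="--", lw=1)
    axes[0].set_xlabel("Individual predicted (μg/ml)")
    axes[0].set_ylabel("Weighted residual")
    axes[1].hist(t["weighted_residual"], bins=30)
    axes[1].set_xlabel("Weighted residual")
    fig.tight_layout()
    p = f"{path_prefix}_weighted_residuals.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
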