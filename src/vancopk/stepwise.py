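"""F-test forward stepwise covariate screening for CL and V.

The canonical mode regresses individual empirical-Bayes (conditional)
parameter estimates on candidate covariates by ordinary least squares and
enters covariates by extra-sum-of-squares F tests: at each step every
remaining candidate is tested given the current set, the candidate with the
largest F-change enters if its p-value is below ``alpha`` (strictly), and
the procedure stops when no candidate qualifies.  This mirrors classical
stepwise-linear-regression output (overall F, F-change, P).  A full-refit
sensitivity mode re-fits the nonlinear mixed-effects model per candidate and
uses likelihood-ratio tests instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .covariates import ALL_COVARIATES, CovariateSelection
from .io import COVARIATE_COLUMN_MAP

__all__ = [
    "StepwiseCovariateSelector",
    "StepwiseTrace",
    "screen_single",
    "stepwise",
    "covariate_frame",
]

F_CAP = 1e12  # stands in for an infinite F when the added column fits exactly


class UndefinedFError(ValueError):
    """Raised when the F statistic is undefined (e.g. constant covariate)."""


@dataclass
class StepwiseTrace:
    """Ordered record of entry tests and the resulting selection."""

    steps: pd.DataFrame  # columns: candidate, F_total, F_change, p_value, action
    final_selection: tuple[str, ...]

    def to_csv(self, path) -> None:
        self.steps.to_csv(path, index=False)


def covariate_frame(patients: pd.DataFrame) -> pd.DataFrame:
    """Rename dataset covariate columns to model-side covariate names."""
    inverse = {v: k for k, v in COVARIATE_COLUMN_MAP.items()}
    cols = [c for c in patients.columns if c in inverse]
    return patients[cols].rename(columns=inverse)


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and residual df of an OLS fit."""
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return float(resid @ resid), len(y) - rank


def _f_change(x_base: np.ndarray, candidate_col: np.ndarray, y: np.ndarray):
    """Extra-sum-of-squares F for adding one column to a base design."""
    if np.ptp(candidate_col) == 0:
        raise UndefinedFError("candidate covariate is constant")
    rss0, _ = _rss(x_base, y)
    x1 = np.column_stack([x_base, candidate_col])
    rss1, df1 = _rss(x1, y)
    if df1 < 1:
        raise UndefinedFError("not enough observations for the F test")
    tss = float(np.sum((y - y.mean()) ** 2))
    scale = max(tss, 1e-300)
    if rss1 / scale < 1e-12:
        f_change = F_CAP
    else:
        f_change = max(rss0 - rss1, 0.0) / (rss1 / df1)
    p_value = float(stats.f.sf(f_change, 1, df1))
    # overall regression F of the augmented model (the "F Test" column)
    k = x1.shape[1] - 1
    if rss1 / scale < 1e-12:
        f_total = F_CAP
    else:
        f_total = ((tss - rss1) / k) / (rss1 / df1) if k > 0 else np.nan
    return f_change, p_value, f_total


def screen_single(
    target: str,
    candidate: str,
    individual_estimates: pd.DataFrame,
    covariates: pd.DataFrame,
    current: tuple[str, ...] = (),
) -> tuple[float, float]:
    """F-change and p-value for adding ``candidate`` given ``current``.

    ``individual_estimates`` must carry columns ``cl``/``v`` indexed like
    ``covariates`` (model-side covariate names).
    """
    y = individual_estimates[target.lower()].to_numpy(float)
    n = len(y)
    x_base = np.column_stack(
        [np.ones(n)] + [covariates[c].to_numpy(float) for c in current]
    )
    f, p, _ = _f_change(x_base, covariates[candidate].to_numpy(float), y)
    return f, p


class StepwiseCovariateSelector(BaseEstimator):
    """Forward stepwise covariate selection on empirical-Bayes estimates.

    Parameters
    ----------
    candidates : sequence of str
        Model-side covariate names to screen (default: all eleven).
    alpha : float
        Entry threshold; a candidate enters only if its F-change p < alpha.
    backward : bool
        After each entry, re-test previously entered covariates and drop any
        whose removal F is no longer significant (off by default; the
        canonical procedure is forward-only).

    After ``fit(X, y)`` (X = covariate frame with model-side names, y =
    per-patient parameter estimates): ``selection_`` (ordered tuple) and
    ``trace_`` (:class:`StepwiseTrace`).
    """

    def __init__(self, candidates=ALL_COVARIATES, alpha: float = 0.05, backward: bool = False):
        self.candidates = candidates
        self.alpha = alpha
        self.backward = backward

    def fit(self, X: pd.DataFrame, y):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not len(self.candidates):
            raise ValueError("candidates must be nonempty")
        y = np.asarray(y, dtype=float)
        n = len(y)
        entered: list[str] = []
        rows = []
        remaining = sorted(self.candidates)  # lexicographic tie-break order
        max_steps = 10 * len(remaining)  # guards against enter/remove cycling
        while remaining and len(rows) < max_steps:
            best = None
            for cand in remaining:
                x_base = np.column_stack(
                    [np.ones(n)] + [X[c].to_numpy(float) for c in entered]
                )
                f, p, f_total = _f_change(x_base, X[cand].to_numpy(float), y)
                if best is None or f > best[1]:  # ties keep the lexicographic first
                    best = (cand, f, p, f_total)
            cand, f, p, f_total = best
            action = "enter" if p < self.alpha else "reject"
            rows.append(
                {"candidate": cand, "F_total": f_total, "F_change": f,
                 "p_value": p, "action": action}
            )
            if action == "reject":
                break
            entered.append(cand)
            remaining.remove(cand)
            if self.backward and len(entered) > 1:
                # re-test earlier entries given the rest; drop the weakest
                dropped = True
                while dropped and len(entered) > 1:
                    dropped = False
                    for old in list(entered[:-1]):
                        others = [c for c in entered if c != old]
                        x_base = np.column_stack(
                            [np.ones(n)] + [X[c].to_numpy(float) for c in others]
                        )
                        f, p, _ = _f_change(x_base, X[old].to_numpy(float), y)
                        if p >= self.alpha:
                            entered.remove(old)
                            remaining.append(old)
                            remaining.sort()
                            rows.append(
                                {"candidate": old, "F_total": np.nan,
                                 "F_change": f, "p_value": p, "action": "remove"}
                            )
                            dropped = True
                            break
        self.trace_ = StepwiseTrace(
            steps=pd.DataFrame(rows, columns=["candidate", "F_total", "F_change", "p_value", "action"]),
            final_selection=tuple(entered),
        )
        self.selection_ = tuple(entered)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[list(self.selection_)]


def stepwise(
    target: str,
    candidates,
    individual_estimates: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
) -> StepwiseTrace:
    """Forward stepwise screening for one parameter ("CL" or "V")."""
    sel = StepwiseCovariateSelector(candidates=tuple(candidates), alpha=alpha)
    sel.fit(covariates, individual_estimates[target.lower()].to_numpy(float))
    return sel.trace_


def stepwise_refit(
    target: str,
    candidates,
    df: pd.DataFrame,
    alpha: float = 0.05,
    **fit_controls,
) -> StepwiseTrace:
    """Full-refit sensitivity mode: likelihood-ratio forward selection.

    At each step the nonlinear mixed-effects model is re-fitted with each
    remaining candidate added to the ``target`` equation and the candidate
    with the largest likelihood-ratio statistic enters if its χ²(1) p-value
    is below ``alpha``.  Much slower than the canonical EB mode.
    """
    from .estimation import fit_population

    entered: list[str] = []
    rows = []
    remaining = sorted(candidates)

    def fit_ll(sel_cl, sel_v):
        res = fit_population(
            df, CovariateSelection(tuple(sel_cl), tuple(sel_v)), **fit_controls
        )
        return res.log_likelihood

    base_ll = fit_ll(entered if target == "CL" else (), entered if target == "V" else ())
    while remaining:
        best = None
        for cand in remaining:
            trial = entered + [cand]
            ll = fit_ll(trial if target == "CL" else (), trial if target == "V" else ())
            lrt = max(2.0 * (ll - base_ll), 0.0)
            if best is None or lrt > best[1]:
                best = (cand, lrt, ll)
        cand, lrt, ll = best
        p = float(stats.chi2.sf(lrt, 1))
        action = "enter" if p < alpha else "reject"
        rows.append(
            {"candidate": cand, "F_total": np.nan, "F_change": lrt,
             "p_value": p, "action": action}
        )
        if action == "reject":
            break
        entered.append(cand)
        remaining.remove(cand)
        base_ll = ll
    return StepwiseTrace(
        steps=pd.DataFrame(rows, columns=["candidate", "F_total", "F_change", "p_value", "action"]),
        final_selection=tuple(entered),
    )
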