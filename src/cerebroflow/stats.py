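"""Covariate-adjusted association models for the cohort analysis.

Each model is ordinary least squares of one hemodynamic outcome (e.g.
white matter CVR) on one SVD predictor plus an adjustment set — none
(univariate), {age, sex, sbp}, {age, sex, pulse_pressure}, or the same
plus log10 WMH volume as a confound check.  Inference is plain OLS with
t-based 95% confidence intervals; collinearity is screened with variance
inflation factors at the conventional limit of 2; residual diagnostics
(QQ pairs, residual-vs-fitted, Breusch-Pagan) are emitted as data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan

from .exceptions import (
    CompletenessWarning,
    MissingDataError,
    NoVarianceError,
    SingularDesignError,
)

#: VIF above this flags collinearity
VIF_LIMIT = 2.0

EXPECTED_BP_READINGS = 7


@dataclass(frozen=True)
class BPSummary:
    sbp: float
    dbp: float
    pulse_pressure: float
    n_readings: int


@dataclass
class AssociationResult:
    """One fitted outcome ~ predictor (+ adjustment) model."""

    outcome: str
    predictor: str
    adjustment: tuple
    beta: float
    ci95_low: float
    ci95_high: float
    p_value: float
    n: int
    vif: dict = field(default_factory=dict)
    n_dropped: int = 0
    _fit: object = field(default=None, repr=False, compare=False)

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "adjustment": "+".join(self.adjustment) or "none",
            "beta": self.beta,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "p_value": self.p_value,
            "n": self.n,
            "max_vif": max(self.vif.values()) if self.vif else np.nan,
            "n_dropped": self.n_dropped,
        }


@dataclass(frozen=True)
class DiagnosticsSummary:
    """Residual diagnostics as plottable data, not figures."""

    fitted: np.ndarray
    residuals: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    bp_lm_stat: float
    bp_p_value: float

    @property
    def heteroscedastic(self) -> bool:
        return self.bp_p_value < 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fitted": self.fitted,
            "residual": self.residuals,
            "qq_theoretical": self.qq_theoretical,
            "qq_sample": self.qq_sample,
        })


def summarize_bp(readings) -> BPSummary:
    """Mean systolic/diastolic BP over the visit's readings.

    ``readings`` is a sequence of (systolic, diastolic) pairs (7 expected;
    fewer triggers a completeness warning).  Pulse pressure is the
    difference of the means — identical, by linearity, to the mean of the
    per-reading pulse pressures.
    """
    arr = np.asarray(list(readings), dtype=float)
    if arr.size == 0:
        raise MissingDataError("no BP readings")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("readings must be (systolic, diastolic) pairs")
    if arr.shape[0] != EXPECTED_BP_READINGS:
        warnings.warn(
            f"expected {EXPECTED_BP_READINGS} BP readings, got {arr.shape[0]}",
            CompletenessWarning,
            stacklevel=2,
        )
    sbp, dbp = arr.mean(axis=0)
    return BPSummary(float(sbp), float(dbp), float(sbp - dbp), arr.shape[0])


def compute_vif(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Variance inflation factors for a set of design columns.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing column j on the remaining
    columns (with intercept).  Perfect collinearity yields ``inf`` and a
    flag, never an exception.
    """
    columns = list(columns)
    if len(columns) < 2:
        raise ValueError("need at least 2 design columns for VIF")
    X = table[columns].to_numpy(dtype=float)
    rows = []
    for j, name in enumerate(columns):
        others = np.column_stack(
            [np.ones(len(X))] + [X[:, k] for k in range(len(columns)) if k != j]
        )
        y = X[:, j]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = np.sum((y - y.mean()) ** 2)
        if tss == 0:
            vif = np.inf  # constant column: undefined, flag it
        else:
            r2 = 1.0 - resid @ resid / tss
            vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"column": name, "vif": max(vif, 1.0),
                     "flagged": vif > VIF_LIMIT})
    return pd.DataFrame(rows)


def fit_association(
    table: pd.DataFrame,
    outcome: str,
    predictor: str,
    adjustment=(),
) -> AssociationResult:
    """OLS of ``outcome`` on ``predictor`` plus an adjustment set.

    Complete-case analysis: rows with any missing modelled value are
    dropped (the count is recorded).  The result carries the beta, t-based
    95% CI and p-value for the predictor term, per-term VIFs, and the
    underlying fit for :func:`diagnostics`.
    """
    adjustment = tuple(adjustment)
    cols = [outcome, predictor, *adjustment]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns absent from table: {missing}")
    data = table[cols].apply(pd.to_numeric)
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    n = len(complete)
    n_pred = 1 + len(adjustment)
    if n < n_pred + 3:
        raise MissingDataError(
            f"only {n} complete rows for {n_pred} predictor(s)"
        )
    if complete[predictor].nunique() <= 1:
        raise NoVarianceError(f"predictor {predictor!r} is constant")

    X = sm.add_constant(complete[[predictor, *adjustment]], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError(
            f"design [{', '.join(X.columns)}] is rank deficient"
        )
    fit = sm.OLS(complete[outcome], X).fit()
    ci_low, ci_high = fit.conf_int().loc[predictor]

    if adjustment:
        vif = {
            row["column"]: row["vif"]
            for _, row in compute_vif(complete, [predictor, *adjustment]).iterrows()
        }
    else:
        vif = {predictor: 1.0}
    return AssociationResult(
        outcome=outcome,
        predictor=predictor,
        adjustment=adjustment,
        beta=float(fit.params[predictor]),
        ci95_low=float(ci_low),
        ci95_high=float(ci_high),
        p_value=float(fit.pvalues[predictor]),
        n=n,
        vif=vif,
        n_dropped=n_dropped,
        _fit=fit,
    )


def diagnostics(result: AssociationResult) -> DiagnosticsSummary:
    """Residual diagnostics for a fitted association model.

    Emits residual-vs-fitted pairs, normal QQ quantile pairs, and the
    Breusch-Pagan Lagrange-multiplier heteroscedasticity test.
    """
    fit = result._fit
    if fit is None:
        raise ValueError("result does not retain its fitted model")
    resid = np.asarray(fit.resid, dtype=float)
    fitted = np.asarray(fit.fittedvalues, dtype=float)
    (osm, osr), _ = sps.probplot(resid, dist="norm")
    if np.allclose(resid, 0.0):
        lm, lm_p = 0.0, 1.0  # perfect fit: nothing to test
    else:
        lm, lm_p, _, _ = het_breuschpagan(resid, fit.model.exog)
    return DiagnosticsSummary(
        fitted=fitted,
        residuals=resid,
        qq_theoretical=osm,
        qq_sample=osr,
        bp_lm_stat=float(lm),
        bp_p_value=float(lm_p),
    )


def run_model_grid(table: pd.DataFrame, models) -> pd.DataFrame:
    """Fit a declarative list of models and tabulate the results.

    ``models`` is an iterable of mappings with keys ``outcome``,
    ``predictor`` and optional ``adjust`` (list of covariates) — one row of
    the output per model.
    """
    rows = []
    for spec in models:
        res = fit_association(
            table, spec["outcome"], spec["predictor"],
            tuple(spec.get("adjust", ())),
        )
        rows.append(res.to_row())
    return pd.DataFrame(rows)
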