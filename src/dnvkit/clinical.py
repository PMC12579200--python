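"""Regression harness for clinical association models and post hoc power.

Four models are supported on the per-proband phenotype table (all with
listwise deletion of incomplete cases and BH-FDR across each model's
predictors):

* dnSNV count ~ father age at conception + sex + PC1..5  (OLS)
* dnSNV count ~ mother age at conception + sex + PC1..5  (OLS)
* age at diagnosis ~ dnSNV count + sex + PC1..5          (OLS)
* severe symptoms ~ dnSNV count + first-degree relatives + brain trauma +
  comorbidity + sex + age at diagnosis + PC1..5          (logistic)

Symptom severity dichotomizes the CY-BOCS total at >= 24.  Diagnostics:
Shapiro-Wilk residual normality and VIFs (flagged at 5) for OLS; McFadden
R^2 (flagged when > 0.4), VIFs (flagged at 10) and an events-per-variable
flag for the logistic model.  The post hoc power routine inverts the
noncentral-F power function of the linear-model F test (noncentrality
lambda = f^2 (u + v + 1)) to the minimal detectable Cohen's f^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrices
from scipy import optimize, stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .burden import bh_fdr


def severity_class(cybocs_total):
    """Dichotomize a CY-BOCS total: >= 24 severe, < 24 mild-to-moderate,
    missing stays missing (and drops out of the logistic model)."""
    if cybocs_total is None or (
        isinstance(cybocs_total, float) and math.isnan(cybocs_total)
    ):
        return "missing"
    if not 0 <= cybocs_total <= 40:
        raise ValueError(f"CY-BOCS total {cybocs_total} outside [0, 40]")
    return "severe" if cybocs_total >= 24 else "mild_moderate"


@dataclass
class RegressionReport:
    model: str
    formula: str
    coefficients: pd.DataFrame  # estimate, ci_low, ci_high, se, p, p_adj
    n_used: int
    excluded: list
    diagnostics: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def _complete_cases(data, formula, id_column):
    columns = set()
    for chunk in formula.replace("~", "+").split("+"):
        token = chunk.strip()
        for part in token.replace("(", " ").replace(")", " ").split():
            if part in data.columns:
                columns.add(part)
    mask = data[sorted(columns)].notna().all(axis=1)
    used = data.loc[mask]
    excluded = list(data.loc[~mask, id_column]) if id_column in data.columns else []
    return used, excluded


def _check_rank(exog, names):
    rank = np.linalg.matrix_rank(exog)
    if rank >= exog.shape[1]:
        return
    collinear = []
    for j in range(exog.shape[1]):
        others = np.delete(exog, j, axis=1)
        resid = exog[:, j] - others @ np.linalg.lstsq(others, exog[:, j], rcond=None)[0]
        if np.allclose(resid, 0, atol=1e-10):
            collinear.append(names[j])
    raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def _vifs(exog, names):
    out = {}
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        out[name] = float(variance_inflation_factor(exog, j))
    return out


def _coef_table(params, conf, bse, pvalues):
    predictors = [n for n in params.index if n != "Intercept"]
    df = pd.DataFrame(
        {
            "estimate": params[predictors],
            "ci_low": conf.loc[predictors, 0],
            "ci_high": conf.loc[predictors, 1],
            "se": bse[predictors],
            "p": pvalues[predictors],
        }
    )
    df["p_adj"] = bh_fdr(df["p"].to_numpy())
    return df


def fit_linear(formula, data, id_column="proband_id"):
    """Ordinary least squares with listwise deletion, BH-FDR across the
    model's predictors, and residual diagnostics."""
    used, excluded = _complete_cases(data, formula, id_column)
    y, X = dmatrices(formula, used, return_type="dataframe")
    _check_rank(X.to_numpy(), list(X.columns))
    fit = sm.OLS(y, X).fit()
    coef = _coef_table(fit.params, fit.conf_int(), fit.bse, fit.pvalues)
    resid = fit.resid
    shapiro_p = float(stats.shapiro(resid)[1]) if len(resid) >= 3 else float("nan")
    vifs = _vifs(X.to_numpy(), list(X.columns))
    flags = [f"vif>=5:{k}" for k, v in vifs.items() if v >= 5]
    report = RegressionReport(
        model="linear",
        formula=formula,
        coefficients=coef,
        n_used=int(fit.nobs),
        excluded=excluded,
        diagnostics={
            "residual_normality_p": shapiro_p,
            "vif": vifs,
            "residuals": resid.to_numpy(),
            "fitted": fit.fittedvalues.to_numpy(),
            "r_squared": float(fit.rsquared),
        },
        flags=flags,
    )
    return report


class SeparationError(RuntimeError):
    pass


def _find_separating(y, X):
    out = []
    for col in X.columns:
        if col == "Intercept":
            continue
        x1 = X.loc[y == 1, col]
        x0 = X.loc[y == 0, col]
        if len(x1) and len(x0) and (x1.min() > x0.max() or x0.min() > x1.max()):
            out.append(col)
    return out


def fit_logistic(formula, data, id_column="proband_id"):
    """Maximum-likelihood logistic regression with Wald CIs, BH-FDR across
    predictors, McFadden R^2, VIF and events-per-variable flags."""
    used, excluded = _complete_cases(data, formula, id_column)
    y, X = dmatrices(formula, used, return_type="dataframe")
    yv = y.iloc[:, 0]
    _check_rank(X.to_numpy(), list(X.columns))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.Logit(yv, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise SeparationError("did not converge")
    except (Exception) as exc:  # PerfectSeparationError or convergence failure
        separating = _find_separating(yv, X)
        raise SeparationError(
            f"logistic fit failed ({exc}); separating predictor(s): {separating or 'none identified'}"
        ) from None
    coef = _coef_table(fit.params, fit.conf_int(), fit.bse, fit.pvalues)
    mcfadden = 1.0 - fit.llf / fit.llnull if fit.llnull != 0 else float("nan")
    vifs = _vifs(X.to_numpy(), list(X.columns))
    n_pred = len(coef)
    events = int(min((yv == 1).sum(), (yv == 0).sum()))
    epv = events / n_pred if n_pred else float("inf")
    flags = [f"vif>=10:{k}" for k, v in vifs.items() if v >= 10]
    if epv < 10:
        flags.append(f"low_events_per_variable:{epv:.1f}")
    if mcfadden > 0.4:
        flags.append("mcfadden_r2>0.4")
    return RegressionReport(
        model="logistic",
        formula=formula,
        coefficients=coef,
        n_used=int(fit.nobs),
        excluded=excluded,
        diagnostics={
            "mcfadden_r2": float(mcfadden),
            "vif": vifs,
            "events_per_variable": epv,
        },
        flags=flags,
    )


def f_test_power(f2, u, v, alpha=0.05):
    """Power of the linear-model F test at effect size f^2 with numerator
    df u, denominator df v, and noncentrality f^2 (u + v + 1)."""
    if v <= 0:
        raise ValueError("denominator df must be positive")
    crit = stats.f.ppf(1.0 - alpha, u, v)
    lam = f2 * (u + v + 1)
    if lam == 0:  # central case: scipy's ncf is degenerate at nc = 0
        return float(stats.f.sf(crit, u, v))
    return float(stats.ncf.sf(crit, u, v, lam))


def minimal_detectable_f2(u, n=None, v=None, alpha=0.05, power=0.8, tol=1e-6):
    """Smallest Cohen's f^2 detectable with the requested power.

    Provide either the sample size *n* (v = n - u - 1) or *v* directly.
    Solved by monotone bisection of the noncentral-F power function to
    |Delta power| < *tol*.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if v is None:
        if n is None:
            raise ValueError("provide n or v")
        v = n - u - 1
    if v <= 0:
        raise ValueError(f"denominator df {v} <= 0; sample too small for {u} predictors")

    def gap(f2):
        return f_test_power(f2, u, v, alpha) - power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("power target unreachable")
    f2 = optimize.brentq(gap, 0.0, hi, xtol=1e-12)
    assert abs(gap(f2)) < tol
    return float(f2)


# canonical model formulas ---------------------------------------------------

MODEL_FORMULAS = {
    "paternal_age": "dnsnv_count ~ father_age_at_conception + sex + pc1 + pc2 + pc3 + pc4 + pc5",
    "maternal_age": "dnsnv_count ~ mother_age_at_conception + sex + pc1 + pc2 + pc3 + pc4 + pc5",
    "age_at_diagnosis": "age_at_diagnosis ~ dnsnv_count + sex + pc1 + pc2 + pc3 + pc4 + pc5",
    "severity": (
        "severe ~ dnsnv_count + first_degree_relative_dx + brain_trauma + "
        "comorbidity + sex + age_at_diagnosis + pc1 + pc2 + pc3 + pc4 + pc5"
    ),
}


def run_all_models(phenotypes):
    """Run the four canonical models on a phenotype table that already
    carries ``dnsnv_count`` and the ancestry PCs.  Returns name -> report
    (a model is skipped with a warning if it cannot be fit)."""
    data = phenotypes.copy()
    data["severe"] = [
        {"severe": 1.0, "mild_moderate": 0.0, "missing": float("nan")}[
            severity_class(v if not pd.isna(v) else None)
        ]
        for v in data["cybocs_total"]
    ]
    reports = {}
    for name, formula in MODEL_FORMULAS.items():
        try:
            if name == "severity":
                reports[name] = fit_logistic(formula, data)
            else:
                reports[name] = fit_linear(formula, data)
        except (ValueError, SeparationError) as exc:
            warnings.warn(f"model {name} not fit: {exc}")
    return reports
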