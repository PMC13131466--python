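"""Pooled regression of per-cell aneuploidy burden on deletion status.

The model is ordinary least squares of the altered fraction (loss + gain)
on indicator covariates

    altered ~ 1 + del13 + del17 + wgd_like

pooled across all cells, with heteroskedasticity-consistent HC3 standard
errors for the coefficient tests: per-cell burdens are far from
homoskedastic (WGD-like cells in particular have very different variance),
so the sandwich covariance (X'X)^-1 X' diag(e_i^2/(1-h_ii)^2) X (X'X)^-1
replaces the classical one.  t statistics use n - p degrees of freedom.
The fit itself stands on statsmodels OLS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import AnalysisError
from .sc_cnv import CellBurden

__all__ = ["RegressionFit", "ols_fit", "hc3_inference", "fit_burden_model"]

DEFAULT_TERMS = ("intercept", "del13", "del17", "wgd_like")


@dataclass
class RegressionFit:
    terms: list[str]
    coefficients: np.ndarray
    se_classical: np.ndarray
    residuals: np.ndarray
    leverages: np.ndarray
    n: int
    se_hc3: np.ndarray | None = None
    t_hc3: np.ndarray | None = None
    p_hc3: np.ndarray | None = None
    dropped_terms: list[str] | None = None  # indicators with no variation
    _model: object | None = None  # statsmodels OLS, kept for inference


def _name_collinear(design: np.ndarray, terms: Sequence[str]) -> list[str]:
    """Heuristically name the columns involved in a rank deficiency."""
    bad = []
    for j in range(design.shape[1]):
        others = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(design):
            bad.append(terms[j])
    return bad or list(terms)


def ols_fit(
    y: np.ndarray, design: np.ndarray, terms: Sequence[str] | None = None
) -> RegressionFit:
    """Least-squares fit returning residuals and hat-diagonal leverages."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    terms = list(terms) if terms is not None else [f"x{j}" for j in range(p)]
    if len(terms) != p:
        raise AnalysisError("terms length must match design columns")
    if n <= p:
        raise AnalysisError(f"need n > p observations (n={n}, p={p})")
    if np.linalg.matrix_rank(X) < p:
        raise AnalysisError(
            f"design is rank deficient; collinear terms: {_name_collinear(X, terms)}"
        )
    model = sm.OLS(y, X)
    res = model.fit()
    leverages = res.get_influence().hat_matrix_diag
    return RegressionFit(
        terms=terms,
        coefficients=np.asarray(res.params),
        se_classical=np.asarray(res.bse),
        residuals=np.asarray(res.resid),
        leverages=np.asarray(leverages),
        n=n,
        _model=model,
    )


def hc3_inference(fit: RegressionFit) -> RegressionFit:
    """Attach HC3-robust SEs and t tests (df = n - p) to an OLS fit."""
    if np.any(fit.leverages >= 1.0 - 1e-12):
        raise AnalysisError("a perfectly leveraged observation (h = 1) breaks HC3")
    res = fit._model.fit(cov_type="HC3", use_t=True)
    fit.se_hc3 = np.asarray(res.bse)
    # guard the zero-residual edge: se 0 makes t/p degenerate per term
    with np.errstate(divide="ignore", invalid="ignore"):
        fit.t_hc3 = np.where(
            fit.se_hc3 > 0,
            fit.coefficients / np.where(fit.se_hc3 > 0, fit.se_hc3, 1.0),
            np.where(fit.coefficients != 0, np.sign(fit.coefficients) * np.inf, 0.0),
        )
    fit.p_hc3 = np.where(
        fit.se_hc3 > 0,
        np.nan_to_num(np.asarray(res.pvalues), nan=1.0),
        np.where(fit.coefficients != 0, 0.0, 1.0),
    )
    return fit


def fit_burden_model(burdens: Sequence[CellBurden]) -> RegressionFit:
    """Fit altered_fraction ~ intercept + del13 + del17 + wgd_like with HC3.

    Indicator covariates with no variation in the data (e.g. no WGD-like
    cell at all) are dropped from the design and listed in
    ``dropped_terms``; keeping them would make the design singular.
    """
    if not burdens:
        raise AnalysisError("no cells to regress")
    y = np.array([b.altered_fraction for b in burdens])
    columns = {
        "intercept": np.ones(len(burdens)),
        "del13": np.array([1.0 if b.del13 else 0.0 for b in burdens]),
        "del17": np.array([1.0 if b.del17 else 0.0 for b in burdens]),
        "wgd_like": np.array([1.0 if b.wgd_like else 0.0 for b in burdens]),
    }
    dropped = [
        t for t in DEFAULT_TERMS[1:] if np.all(columns[t] == columns[t][0])
    ]
    terms = [t for t in DEFAULT_TERMS if t not in dropped]
    X = np.column_stack([columns[t] for t in terms])
    fit = ols_fit(y, X, terms=terms)
    fit.dropped_terms = dropped
    return hc3_inference(fit)
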