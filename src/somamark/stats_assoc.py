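"""Marker–phenotype association statistics.

Provides the rank-based inverse normal (quantile-normal) transform used
to normalise both markers, covariate residualisation, and the logistic
and linear association fits that report effect sizes per marker SD with
Wald 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                             PerfectSeparationWarning)

__all__ = ["inverse_normal", "residualize", "logistic_assoc", "linear_assoc",
           "AssocResult"]


def inverse_normal(values, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse normal transform.

    Maps value of rank r (average rank for ties) to
    ``Phi^-1((r - offset) / (n - 2*offset + 1))``.  The default
    ``offset=0.5`` gives the plain ``(r - 0.5)/n`` grid; ``offset=3/8``
    gives Blom's variant.  Monotone in the input.

    Raises
    ------
    ValueError
        If fewer than two values are supplied, any value is not
        finite, or all values are identical (ranks undefined).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D array of values")
    if x.size < 2:
        raise ValueError("inverse_normal requires at least two values")
    if not np.all(np.isfinite(x)):
        raise ValueError("inverse_normal requires finite values")
    if np.all(x == x[0]):
        raise ValueError("all values identical: ranks are undefined")
    ranks = stats.rankdata(x, method="average")
    n = x.size
    return stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))


def _encode_covariates(covariates: Optional[pd.DataFrame],
                       categorical: Tuple[str, ...] = ()) -> Optional[pd.DataFrame]:
    """Dummy-encode categorical columns; drop constant columns with a
    warning (they are collinear with the intercept)."""
    if covariates is None or covariates.shape[1] == 0:
        return None
    out = {}
    for col in covariates.columns:
        series = covariates[col]
        if col in categorical or series.dtype == object \
                or isinstance(series.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(series.astype("category"),
                                     prefix=str(col), drop_first=True,
                                     dtype=float)
            for dcol in dummies.columns:
                out[dcol] = dummies[dcol].to_numpy()
        else:
            out[str(col)] = series.to_numpy(dtype=float)
    frame = pd.DataFrame(out, index=covariates.index)
    constant = [c for c in frame.columns if frame[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant covariate(s): {constant}",
                      stacklevel=3)
        frame = frame.drop(columns=constant)
    return frame if frame.shape[1] else None


def residualize(values, covariates: Optional[pd.DataFrame],
                categorical: Tuple[str, ...] = ()) -> np.ndarray:
    """OLS residuals of ``values`` on the (encoded) covariates.

    A single joint multiple regression; categorical columns are
    indicator-coded against the lexicographically first level.  With no
    usable covariates the values are returned centred.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 3:
        raise ValueError("residualize requires at least three samples")
    X = _encode_covariates(covariates, categorical)
    if X is None:
        return y - y.mean()
    if len(X) != y.size:
        raise ValueError("covariates not aligned with values")
    design = sm.add_constant(X.to_numpy(dtype=float))
    return np.asarray(sm.OLS(y, design).fit().resid)


@dataclass
class AssocResult:
    """One fitted marker–outcome association.

    ``beta`` is the log-odds (logistic) or slope (linear) per unit of
    the tested term; ``or_`` and ``ci95`` are the exp-transformed
    effect and Wald interval; ``p`` is the two-sided Wald p-value.
    Non-convergent fits (e.g. perfect separation) are flagged via
    ``converged`` and carry NaN estimates.
    """

    beta: float
    se: float
    or_: float
    ci95: Tuple[float, float]
    p: float
    n: int
    term: str = "marker"
    converged: bool = True


_Z95 = stats.norm.ppf(0.975)


def _build_design(main, main_name: str,
                  covariates: Optional[pd.DataFrame],
                  categorical: Tuple[str, ...]) -> pd.DataFrame:
    x = np.asarray(main, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"{main_name} is constant; association undefined")
    X = pd.DataFrame({main_name: x})
    enc = _encode_covariates(covariates, categorical)
    if enc is not None:
        if len(enc) != x.size:
            raise ValueError("covariates not aligned with samples")
        for col in enc.columns:
            X[col] = enc[col].to_numpy()
    full = np.column_stack([np.ones(x.size), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("collinear design: a covariate duplicates the "
                         "tested term or another column")
    return X


def _wald_result(params, bse, pvalues, term: str, n: int,
                 converged: bool) -> AssocResult:
    beta = float(params[term])
    se = float(bse[term])
    return AssocResult(
        beta=beta, se=se, or_=float(np.exp(beta)),
        ci95=(float(np.exp(beta - _Z95 * se)),
              float(np.exp(beta + _Z95 * se))),
        p=float(pvalues[term]), n=n, term=term, converged=converged)


def logistic_assoc(marker, status, covariates: Optional[pd.DataFrame] = None,
                   categorical: Tuple[str, ...] = ()) -> AssocResult:
    """Maximum-likelihood logistic regression of case status on a
    marker (plus covariates), reporting the marker's odds ratio and
    Wald 95% CI.

    ``status`` must be binary with both classes present.  Perfect
    separation is flagged (``converged=False``) rather than raised.
    """
    y = np.asarray(status, dtype=float)
    classes = np.unique(y)
    if classes.size != 2 or not set(classes) <= {0.0, 1.0}:
        raise ValueError("status must be binary 0/1 with both classes present")
    X = _build_design(marker, "marker", covariates, categorical)
    design = sm.add_constant(X, has_constant="add")
    n = int(y.size)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design.astype(float)).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning,
                np.linalg.LinAlgError):
            nan = float("nan")
            return AssocResult(beta=nan, se=nan, or_=nan, ci95=(nan, nan),
                               p=nan, n=n, converged=False)
    converged = bool(fit.mle_retvals.get("converged", True))
    return _wald_result(fit.params, fit.bse, fit.pvalues, "marker", n,
                        converged)


def linear_assoc(marker, exposure, covariates: Optional[pd.DataFrame] = None,
                 categorical: Tuple[str, ...] = ()) -> AssocResult:
    """OLS regression of a marker on an exposure (SLE count, ordinal
    adversity code, ...) plus covariates; slope form of
    :class:`AssocResult` (``beta`` is the slope, ``or_`` its exp).
    """
    y = np.asarray(marker, dtype=float)
    X = _build_design(exposure, "exposure", covariates, categorical)
    design = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, design.astype(float)).fit()
    return _wald_result(fit.params, fit.bse, fit.pvalues, "exposure",
                        int(y.size), True)
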