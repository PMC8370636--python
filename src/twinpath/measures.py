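"""Construction of analysis variables from informant reports.

Covers the four academic-adjustment measures and the two adulthood
variables: grade composites averaged over subjects and informants, 6-item
motivation sums averaged over informants, either-informant discipline item
coding followed by a one-factor ML confirmatory factor analysis, binning of
free-response cigarettes/day onto a 0-6 scale, and age-residualized
educational attainment.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "compose_gpa", "compose_motivation", "compose_motivation_teacher",
    "code_discipline_items", "OneFactorCFA", "fit_discipline_cfa",
    "code_cigarettes", "residualize_attainment", "build_composites",
]

N_GPA_SUBJECTS = 4
N_MOTIV_ITEMS = 6
N_DISC_ITEMS = 6


def _validate_items(items, n_items, lo, hi, what):
    arr = np.asarray(items, dtype=float)
    if arr.shape != (n_items,):
        raise ValueError(f"{what} must have {n_items} items, got shape {arr.shape}")
    finite = arr[np.isfinite(arr)]
    if np.any(finite < lo) or np.any(finite > hi):
        raise ValueError(f"{what} values outside [{lo}, {hi}]")
    return arr


def compose_gpa(twin_items=None, mother_items=None):
    """Grade composite: per-informant mean over the four class subjects
    (0-4 grade points), then mean over available informants."""
    means = []
    for items, who in ((twin_items, "twin"), (mother_items, "mother")):
        if items is None:
            continue
        arr = _validate_items(items, N_GPA_SUBJECTS, 0, 4, f"{who} grades")
        if np.isfinite(arr).any():
            means.append(np.nanmean(arr))
    if not means:
        raise ValueError("at least one informant report is required")
    return float(np.mean(means))


def compose_motivation(self_items=None, mother_items=None):
    """Motivation composite: per-informant sum of the six items, then mean
    over available informants."""
    sums = []
    for items, who in ((self_items, "self"), (mother_items, "mother")):
        if items is None:
            continue
        arr = _validate_items(items, N_MOTIV_ITEMS, -np.inf, np.inf,
                              f"{who} motivation items")
        sums.append(arr.sum())
    if not sums:
        raise ValueError("at least one informant report is required")
    return float(np.mean(sums))


def compose_motivation_teacher(reports):
    """Teacher motivation composite: item sum per teacher, mean across the
    1-3 available teacher reports."""
    reports = [r for r in reports if r is not None]
    if not 1 <= len(reports) <= 3:
        raise ValueError("expected 1-3 teacher reports")
    sums = [_validate_items(r, N_MOTIV_ITEMS, -np.inf, np.inf,
                            "teacher motivation items").sum()
            for r in reports]
    return float(np.mean(sums))


def code_discipline_items(twin_items=None, mother_items=None):
    """Either-informant discipline coding: a problem graded 0/1/2 is taken
    at the highest level reported by either informant (elementwise max);
    with a single informant that report passes through."""
    reports = []
    for items, who in ((twin_items, "twin"), (mother_items, "mother")):
        if items is None:
            continue
        arr = _validate_items(items, N_DISC_ITEMS, 0, 2, f"{who} discipline items")
        if not np.all(np.isin(arr[np.isfinite(arr)], (0.0, 1.0, 2.0))):
            raise ValueError("discipline items must be coded 0, 1 or 2")
        reports.append(arr)
    if not reports:
        raise ValueError("at least one informant report is required")
    if len(reports) == 1:
        return reports[0]
    with np.errstate(invalid="ignore"):
        return np.fmax(reports[0], reports[1])


class OneFactorCFA(BaseEstimator, TransformerMixin):
    """One-factor linear confirmatory factor analysis by maximum likelihood.

    Model: x = mu + lambda * f + e, f ~ N(0, 1), e ~ N(0, diag(u)).
    Estimated by full-information ML over missing-data patterns, so rows
    with some missing items still contribute.  ``transform`` returns
    regression-method factor scores lambda' Sigma^{-1} (x - mu) computed on
    each row's observed items (mean ~0 in-sample).

    Attributes
    ----------
    loadings_ : raw loadings
    uniquenesses_ : residual item variances
    std_loadings_ : loadings on the standardized-item scale
    heywood_, converged_, n_iter_, loglik_
    """

    def __init__(self, min_rows=50, max_iter=500, tol=1e-8):
        self.min_rows = min_rows
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("item matrix must be 2-D")
        usable = np.isfinite(X).any(axis=1)
        X = X[usable]
        n, p = X.shape
        if n < self.min_rows:
            raise ValueError(f"need at least {self.min_rows} rows, got {n}")

        col_mean = np.nanmean(X, axis=0)
        col_var = np.nanvar(X, axis=0, ddof=1)
        if np.any(col_var <= 0):
            raise ValueError("constant item encountered")
        lam0 = np.sqrt(col_var / 2.0)
        theta0 = np.log(col_var / 2.0)
        x0 = np.concatenate([col_mean, lam0, theta0])
        patterns = _pattern_stats(X)

        def negll(par):
            mu = par[:p]
            lam = par[p:2 * p]
            u = np.exp(par[2 * p:])
            total = 0.0
            for mask, n_g, sy, syy in patterns:
                lo, uo = lam[mask], u[mask]
                k = lo.size
                sigma = np.outer(lo, lo) + np.diag(uo)
                try:
                    chol = np.linalg.cholesky(sigma)
                except np.linalg.LinAlgError:
                    return 1e12
                logdet = 2.0 * np.log(np.diag(chol)).sum()
                kinv = np.linalg.inv(sigma)
                mo = mu[mask]
                quad = (np.trace(kinv @ syy) - 2.0 * mo @ kinv @ sy
                        + n_g * mo @ kinv @ mo)
                total += n_g * (k * math.log(2 * math.pi) + logdet) + quad
            return 0.5 * total

        res = optimize.minimize(negll, x0, method="L-BFGS-B",
                                options={"maxiter": self.max_iter,
                                         "ftol": self.tol})
        mu = res.x[:p]
        lam = res.x[p:2 * p]
        u = np.exp(res.x[2 * p:])
        if lam.sum() < 0:  # sign indeterminacy: orient positively
            lam = -lam
        self.mean_ = mu
        self.loadings_ = lam
        self.uniquenesses_ = u
        self.std_loadings_ = lam / np.sqrt(lam**2 + u)
        #: degenerate when the factor explains <5% of item variance on
        #: average (e.g. uncorrelated items)
        self.degenerate_ = bool(np.mean(self.std_loadings_**2) < 0.05)
        self.heywood_ = bool(np.any(u < 1e-4 * col_var))
        self.converged_ = bool(res.success)
        self.n_iter_ = int(res.nit)
        self.loglik_ = -float(res.fun)
        self.n_used_ = n
        if not res.success:
            self.message_ = str(res.message)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        lam, u, mu = self.loadings_, self.uniquenesses_, self.mean_
        scores = np.full(X.shape[0], np.nan)
        for mask, rows in _group_rows(X):
            if not mask.any():
                continue
            lo = lam[mask]
            sigma = np.outer(lo, lo) + np.diag(u[mask])
            w = np.linalg.solve(sigma, lo)
            scores[rows] = (X[np.ix_(rows, np.where(mask)[0])] - mu[mask]) @ w
        return scores


def _pattern_stats(X):
    """Per missing-data pattern: (mask, n, sum y, sum yy')."""
    finite = np.isfinite(X)
    keys = [tuple(row) for row in finite]
    out = []
    for key in sorted(set(keys)):
        mask = np.array(key)
        if not mask.any():
            continue
        rows = np.array([i for i, k in enumerate(keys) if k == key])
        sub = X[np.ix_(rows, np.where(mask)[0])]
        out.append((mask, len(rows), sub.sum(axis=0), sub.T @ sub))
    return out


def _group_rows(X):
    finite = np.isfinite(X)
    keys = [tuple(row) for row in finite]
    for key in sorted(set(keys)):
        rows = np.array([i for i, k in enumerate(keys) if k == key])
        yield np.array(key), rows


def fit_discipline_cfa(items, min_rows=50):
    """Fit the one-factor discipline model and return
    (standardized loadings, factor scores, fitted estimator)."""
    model = OneFactorCFA(min_rows=min_rows).fit(items)
    scores = model.transform(np.asarray(items, dtype=float))
    return model.std_loadings_, scores, model


DEFAULT_CIGS_UPPER_BOUNDS = (0.0, 0.99, 5.0, 10.0, 15.0, 19.0)


def code_cigarettes(raw, upper_bounds=DEFAULT_CIGS_UPPER_BOUNDS):
    """Bin free-response cigarettes/day onto the 0-6 scale.

    ``upper_bounds`` are inclusive category maxima for categories 0-5;
    anything above the last bound is category 6 (20+/day).  Defaults: 0 =
    none, 1 = less than daily (<1), 2 = 1-5, 3 = 6-10, 4 = 11-15,
    5 = 16-19, 6 = 20 or more.
    """
    arr = np.asarray(raw, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("cigarettes/day cannot be negative")
    bounds = np.asarray(upper_bounds, dtype=float)
    if bounds.size != 6 or np.any(np.diff(bounds) <= 0):
        raise ValueError("need 6 strictly increasing upper bounds")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    coded = np.searchsorted(bounds, arr, side="left").astype(float)
    coded[~np.isfinite(arr)] = np.nan
    return float(coded[0]) if scalar else coded


def residualize_attainment(categories, ages):
    """Residualize attainment categories on age at report.

    Returns unstandardized residuals from the least-squares line fit on
    records where both the category and age are present; other entries are
    NaN.
    """
    cat = np.asarray(categories, dtype=float)
    age = np.asarray(ages, dtype=float)
    ok = np.isfinite(cat) & np.isfinite(age)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete attainment records")
    if np.ptp(age[ok]) == 0:
        raise ValueError("all ages identical; age slope not identified")
    slope, intercept = np.polyfit(age[ok], cat[ok], 1)
    resid = np.full(cat.shape, np.nan)
    resid[ok] = cat[ok] - (intercept + slope * age[ok])
    return resid


def build_composites(data) -> pd.DataFrame:
    """Informant-mean composites for every trait x occasion of a
    :class:`~twinpath.simulate.PanelDataset`, plus the age-residualized
    attainment outcome, one row per person.

    Cigarettes values are run through :func:`code_cigarettes` so columns
    ``cigs_per_day_*`` are on the 0-6 scale.
    """
    from .simulate import to_wide

    wide = to_wide(data)
    for col in [c for c in wide.columns if c.startswith("cigs_per_day_")]:
        wide[col] = code_cigarettes(wide[col].to_numpy())
    ea = wide["ea_category"].where(wide["ea_observed"].astype(bool))
    wide["ea_residual"] = residualize_attainment(ea, wide["ea_age"])
    return wide
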