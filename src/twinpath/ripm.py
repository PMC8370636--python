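"""Random-intercept panel models (RI-PM) with autoregressive occasion
residuals, estimated by full-information maximum likelihood (FIML).

Model for a person's T repeated measures y = (y_1..y_T) given covariates x:

    y_t = mu_t + eta + r_t,         eta = Gamma' x + zeta,  zeta ~ N(0, psi)
    r_1 = e_1,  r_t = rho_{t-1} r_{t-1} + e_t,   e_t ~ N(0, theta_t)

All factor loadings are fixed to 1; occasion intercepts mu_t are free; the
random intercept has mean 0 (unconditional case) and free variance psi.
The implied covariance is

    Cov(y_s, y_t) = psi + Cov(r_s, r_t),
    Var(r_t) = rho_{t-1}^2 Var(r_{t-1}) + theta_t,
    Cov(r_s, r_t) = prod_{u=s..t-1} rho_u * Var(r_s)   (s < t).

The likelihood is the casewise multivariate-normal likelihood summed over
missing-data patterns; each person contributes their observed occasions.
Variance parameters are optimized on the log scale, which keeps the implied
covariance positive definite throughout the search.  Each likelihood
evaluation uses per-pattern sufficient statistics, so its cost does not
grow with sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.tools import numdiff

__all__ = [
    "ripm_covariance", "implied_moments", "RandomInterceptPanelModel",
    "fit_ripm", "simulate_ripm", "fit_crosssection", "lr_test", "RIPMParams",
]


@dataclass
class RIPMParams:
    """Raw RI-PM parameters (occasion intercepts, RI regression, variances)."""

    mu: np.ndarray
    psi: float
    thetas: np.ndarray
    rhos: np.ndarray
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def validate(self):
        if self.psi <= 0 or np.any(np.asarray(self.thetas) <= 0):
            raise ValueError("variance parameters must be positive")
        T = len(self.mu)
        if len(self.thetas) != T or len(self.rhos) != T - 1:
            raise ValueError("inconsistent parameter dimensions")
        return self


def ripm_covariance(psi, thetas, rhos):
    """Implied T x T occasion covariance matrix."""
    thetas = np.asarray(thetas, dtype=float)
    rhos = np.asarray(rhos, dtype=float)
    T = thetas.size
    v = np.empty(T)
    v[0] = thetas[0]
    for t in range(1, T):
        v[t] = rhos[t - 1] ** 2 * v[t - 1] + thetas[t]
    cov = np.full((T, T), float(psi))
    for s in range(T):
        cov[s, s] += v[s]
        acc = v[s]
        for t in range(s + 1, T):
            acc *= rhos[t - 1]
            cov[s, t] += acc
            cov[t, s] += acc
    return cov


def implied_moments(params: RIPMParams, predictor_moments=None):
    """Model-implied occasion mean vector and covariance matrix.

    ``predictor_moments`` is (mean_x, cov_x) for the conditional model; the
    random-intercept variance then becomes Gamma' cov_x Gamma + psi and the
    means shift by Gamma' mean_x.
    """
    params.validate()
    mu = np.asarray(params.mu, dtype=float).copy()
    psi = float(params.psi)
    if params.gamma.size:
        if predictor_moments is None:
            raise ValueError("conditional model requires predictor moments")
        mean_x, cov_x = predictor_moments
        shift = float(params.gamma @ np.asarray(mean_x, dtype=float))
        mu += shift
        psi += float(params.gamma @ np.asarray(cov_x, dtype=float)
                     @ params.gamma)
    return mu, ripm_covariance(psi, params.thetas, params.rhos)


def _prepare_patterns(Y, X):
    """Group rows by missing-data pattern; store sufficient statistics so a
    likelihood evaluation costs O(T^2 + Tp + p^2) per pattern."""
    finite = np.isfinite(Y)
    keep = finite.any(axis=1)
    Y, X, finite = Y[keep], X[keep], finite[keep]
    keys = [tuple(r) for r in finite]
    patterns = []
    for key in sorted(set(keys)):
        mask = np.array(key)
        rows = np.array([i for i, k in enumerate(keys) if k == key])
        Yo = Y[np.ix_(rows, np.where(mask)[0])]
        Xg = X[rows]
        patterns.append({
            "mask": mask,
            "n": len(rows),
            "Sy": Yo.sum(axis=0),
            "Syy": Yo.T @ Yo,
            "SyX": Yo.T @ Xg,
            "SX": Xg.sum(axis=0),
            "SXX": Xg.T @ Xg,
        })
    return patterns, int(keep.sum())


def _fiml_negll(mu, gamma, sigma, patterns):
    """-2 log L / 2 from pattern sufficient statistics.

    For pattern g with observed set o and person-specific mean
    m_i = mu_o + 1 s_i (s_i = gamma' x_i), the summed quadratic form
    expands into the precomputed moments.
    """
    total = 0.0
    for g in patterns:
        mask = g["mask"]
        so = sigma[np.ix_(mask, mask)]
        k = int(mask.sum())
        try:
            chol = np.linalg.cholesky(so)
            kinv = np.linalg.solve(so, np.eye(k))
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        if not np.all(np.isfinite(kinv)):
            return 1e12
        mo = mu[mask]
        one = np.ones(k)
        k1 = kinv @ one
        quad = float(np.sum(kinv * g["Syy"]))
        quad -= 2.0 * float(mo @ kinv @ g["Sy"])
        quad += g["n"] * float(mo @ kinv @ mo)
        if gamma.size:
            syxg = g["SyX"] @ gamma
            sxg = float(g["SX"] @ gamma)
            sxxg = float(gamma @ g["SXX"] @ gamma)
            quad -= 2.0 * float(k1 @ syxg)
            quad += 2.0 * float(mo @ k1) * sxg
            quad += float(one @ k1) * sxxg
        total += g["n"] * (k * math.log(2 * math.pi) + logdet) + quad
    return 0.5 * total


class RandomInterceptPanelModel(BaseEstimator):
    """Sklearn-style estimator for the RI-PM.

    Parameters
    ----------
    autoregressive : include the AR paths between occasion residuals.
    max_iter, gtol : optimizer controls (quasi-Newton from method-of-moments
        starts; converged when the gradient norm is below ``gtol``).

    Fitted attributes
    -----------------
    mu_, psi_, theta_, rho_, gamma_ : raw parameters
    standardized_gamma_ : Gamma scaled by predictor SD / implied eta SD
    loglik_, n_used_, converged_, grad_norm_, vcov_, param_names_
    """

    def __init__(self, autoregressive=True, max_iter=500, gtol=1e-6,
                 compute_vcov=True):
        self.autoregressive = autoregressive
        self.max_iter = max_iter
        self.gtol = gtol
        self.compute_vcov = compute_vcov

    # -- parameter packing ---------------------------------------------------

    def _unpack(self, par, T, p):
        mu = par[:T]
        gamma = par[T:T + p]
        psi = math.exp(par[T + p])
        thetas = np.exp(par[T + p + 1:T + p + 1 + T])
        if self.autoregressive:
            rhos = par[T + p + 1 + T:]
        else:
            rhos = np.zeros(T - 1)
        return mu, gamma, psi, thetas, rhos

    def fit(self, Y, X=None):
        Y = self._as_matrix(Y, "occasions_")
        if X is None:
            X = np.empty((len(Y), 0))
            self.predictor_names_ = []
        else:
            X = self._as_matrix(X, "predictor_names_")
            if np.isnan(X).any():
                raise ValueError("predictors must be complete for fitted cases")
        if Y.shape[1] < 2:
            raise ValueError("need at least 2 occasions")
        T, p = Y.shape[1], X.shape[1]

        patterns, n_used = _prepare_patterns(Y, X)
        if n_used == 0:
            raise ValueError("no case has any observed occasion")

        # method-of-moments starts
        pairwise = pd.DataFrame(Y).cov().to_numpy()
        off = pairwise[~np.eye(T, dtype=bool)]
        psi0 = max(float(np.nanmean(off)), 1e-3)
        theta0 = np.maximum(np.diag(pairwise) - psi0, 1e-3)
        mu0 = np.nanmean(Y, axis=0)
        x0 = [mu0, np.zeros(p), [math.log(psi0)], np.log(theta0)]
        if self.autoregressive:
            x0.append(np.zeros(T - 1))
        x0 = np.concatenate(x0)

        def objective(par):
            # per-case mean of -log L keeps gradients O(1) regardless of n
            mu, gamma, psi, thetas, rhos = self._unpack(par, T, p)
            sigma = ripm_covariance(psi, thetas, rhos)
            return _fiml_negll(mu, gamma, sigma, patterns) / n_used

        res = optimize.minimize(objective, x0, method="BFGS",
                                options={"maxiter": self.max_iter,
                                         "gtol": self.gtol})
        grad_norm = float(np.max(np.abs(res.jac)))
        mu, gamma, psi, thetas, rhos = self._unpack(res.x, T, p)

        self.mu_ = mu
        self.gamma_ = gamma
        self.psi_ = psi
        self.theta_ = thetas
        self.rho_ = rhos
        self.loglik_ = -float(res.fun) * n_used
        self.n_used_ = n_used
        self.converged_ = bool(res.success or grad_norm < 1e-3)
        self.grad_norm_ = grad_norm
        self.n_params_ = res.x.size
        self.param_names_ = (
            [f"mu_{o}" for o in self.occasions_]
            + [f"gamma_{nm}" for nm in self.predictor_names_]
            + ["log_psi"] + [f"log_theta_{o}" for o in self.occasions_]
            + ([f"rho_{self.occasions_[t]}_{self.occasions_[t+1]}"
                for t in range(T - 1)] if self.autoregressive else [])
        )
        self._raw_estimates_ = res.x
        self._patterns_ = patterns
        self._T_, self._p_ = T, p

        if p:
            cov_x = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
            sd_eta = math.sqrt(float(gamma @ cov_x @ gamma) + psi)
            self.predictor_sds_ = np.sqrt(np.diag(cov_x))
            self.standardized_gamma_ = gamma * self.predictor_sds_ / sd_eta
            self.eta_sd_ = sd_eta
            self._x_moments_ = (X.mean(axis=0), cov_x)
        else:
            self.standardized_gamma_ = np.zeros(0)
            self.eta_sd_ = math.sqrt(psi)
            self._x_moments_ = None

        if self.compute_vcov:
            hess = numdiff.approx_hess(res.x, objective) * n_used
            try:
                self.vcov_ = np.linalg.inv(hess)
            except np.linalg.LinAlgError:
                self.vcov_ = np.full((res.x.size, res.x.size), np.nan)
        else:
            self.vcov_ = None
        return self

    def _as_matrix(self, M, names_attr):
        if isinstance(M, pd.DataFrame):
            setattr(self, names_attr, [str(c) for c in M.columns])
            return M.to_numpy(dtype=float)
        M = np.asarray(M, dtype=float)
        setattr(self, names_attr, [str(i) for i in range(M.shape[1])])
        return M

    # -- model-implied quantities -------------------------------------------

    def params_(self):
        return RIPMParams(mu=self.mu_, psi=self.psi_, thetas=self.theta_,
                          rhos=self.rho_, gamma=self.gamma_)

    def implied_moments(self):
        return implied_moments(self.params_(), self._x_moments_)

    def implied_covariance(self):
        return ripm_covariance(self.psi_, self.theta_, self.rho_)

    def residual_covariance(self):
        return self.implied_covariance() - self.psi_

    # -- MAP factor scores ---------------------------------------------------

    def transform(self, Y, X=None):
        """Maximum a posteriori random-intercept scores.

        score_i = Gamma'x_i + psi 1' Sigma_obs^{-1} (y_obs - mu_obs -
        1 Gamma'x_i); persons with no observed occasion get NaN.
        """
        Yarr = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) \
            else np.asarray(Y, dtype=float)
        n, T = Yarr.shape
        if X is None:
            shift = np.zeros(n)
        else:
            Xarr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) \
                else np.asarray(X, dtype=float)
            shift = Xarr @ self.gamma_
        sigma = ripm_covariance(self.psi_, self.theta_, self.rho_)
        scores = np.full(n, np.nan)
        finite = np.isfinite(Yarr)
        keys = [tuple(r) for r in finite]
        for key in sorted(set(keys)):
            mask = np.array(key)
            if not mask.any():
                continue
            rows = np.array([i for i, k in enumerate(keys) if k == key])
            so = sigma[np.ix_(mask, mask)]
            w = self.psi_ * np.linalg.solve(so, np.ones(mask.sum()))
            resid = (Yarr[np.ix_(rows, np.where(mask)[0])]
                     - self.mu_[mask] - shift[rows, None])
            scores[rows] = shift[rows] + resid @ w
        return scores

    def score_reliability(self, pattern):
        """Var(MAP score)/psi for an observed-occasion mask; in [0, 1]."""
        mask = np.asarray(pattern, dtype=bool)
        if not mask.any():
            raise ValueError("empty observation pattern")
        sigma = ripm_covariance(self.psi_, self.theta_, self.rho_)
        so = sigma[np.ix_(mask, mask)]
        one = np.ones(int(mask.sum()))
        return float(self.psi_ * one @ np.linalg.solve(so, one))


def fit_ripm(Y, X=None, autoregressive=True, **kwargs):
    """Functional wrapper over :class:`RandomInterceptPanelModel`."""
    return RandomInterceptPanelModel(
        autoregressive=autoregressive, **kwargs).fit(Y, X)


def simulate_ripm(params: RIPMParams, n, rng, X=None):
    """Draw wide-format data from an RI-PM; used for parameter-recovery and
    oracle checks."""
    params.validate()
    T = len(params.mu)
    eta = rng.normal(0.0, math.sqrt(params.psi), n)
    if params.gamma.size:
        eta = eta + np.asarray(X, dtype=float) @ params.gamma
    Y = np.empty((n, T))
    r = np.zeros(n)
    for t in range(T):
        e = rng.normal(0.0, math.sqrt(params.thetas[t]), n)
        r = e if t == 0 else params.rhos[t - 1] * r + e
        Y[:, t] = params.mu[t] + eta + r
    return Y


def fit_crosssection(y, X):
    """Least-squares fit of one occasion on covariates; returns a Series of
    standardized coefficients (beta * sd_x / sd_y)."""
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    Xc, yc = X.loc[ok], y[ok]
    n, p = Xc.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} complete cases, got {n}")
    M = np.column_stack([np.ones(n), Xc.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        _, R = np.linalg.qr(M)
        bad = [str(Xc.columns[j - 1]) for j in range(1, M.shape[1])
               if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    coefs, *_ = np.linalg.lstsq(M, yc, rcond=None)
    sds = Xc.to_numpy(dtype=float).std(axis=0, ddof=1)
    sy = yc.std(ddof=1)
    return pd.Series(coefs[1:] * sds / sy, index=[str(c) for c in Xc.columns])


def lr_test(full, reduced):
    """Likelihood-ratio test of nested fits sharing the same cases.

    Returns (delta_chi2, df, p) with delta_chi2 = 2 (ll_full - ll_reduced).
    """
    if full.n_used_ != reduced.n_used_:
        raise ValueError("fits use different case sets")
    df = full.n_params_ - reduced.n_params_
    if df < 0:
        raise ValueError("reduced model has more parameters than full model")
    delta = 2.0 * (full.loglik_ - reduced.loglik_)
    if delta < -1e-6:
        raise ValueError("full model fits worse; models are not nested")
    delta = max(delta, 0.0)
    p = 1.0 if df == 0 and delta <= 0 else float(stats.chi2.sf(delta, max(df, 1)))
    if df == 0:
        p = 1.0 if delta <= 1e-10 else 0.0
    return delta, df, p
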