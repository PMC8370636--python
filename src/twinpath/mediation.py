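"""Path-analysis mediation model with family-clustered bootstrap inference.

The model regresses each of the mediators (random-intercept factor scores)
on the exogenous predictors (two PGSs plus controls), and the outcome
(age-residualized educational attainment) on the exogenous predictors and
all mediators, all by least squares.  For this fully recursive,
just-identified system the equation-wise least-squares fit coincides with
ML path analysis, and the exact decomposition

    total effect = direct effect + sum_k a_k * b_k

holds at machine precision on complete data (the total equals the
coefficient of the model omitting the mediators).

Inference follows the clustered nonparametric percentile bootstrap:
families are resampled with replacement to the original family count, all
statistics are recomputed per draw, and 95% CIs are the empirical 2.5/97.5
percentiles.  A parameter is flagged significant only if its CI excludes 0
AND its (normal-approximation, bootstrap-SE) two-sided p-value is < .005.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "PathModelSpec", "PathModel", "fit_path_model", "decompose_effects",
    "cluster_bootstrap", "flag_significance", "BootstrapResult",
    "significance_table",
]

P_THRESHOLD = 0.005


@dataclass
class PathModelSpec:
    exogenous: tuple
    mediators: tuple
    outcome: str
    pgs_names: tuple = ("pgs_smoking", "pgs_edu")

    def validate(self):
        if set(self.mediators) & {self.outcome}:
            raise ValueError("mediators and outcome must be disjoint")
        if set(self.exogenous) & set(self.mediators):
            raise ValueError("exogenous and mediator sets must be disjoint")
        return self


def default_spec():
    from .config import TRAITS
    return PathModelSpec(
        exogenous=("pgs_smoking", "pgs_edu", "sex",
                   "pc1", "pc2", "pc3", "pc4", "pc5"),
        mediators=tuple(f"ri_{t}" for t in TRAITS),
        outcome="ea_residual",
    )


class PathModel(BaseEstimator):
    """Recursive least-squares path model (sklearn-style estimator).

    Parameters are the variable roles; ``fit`` takes a tidy per-person
    DataFrame containing all of them.  Cases with any missing model
    variable are dropped (the decomposition identity requires a common
    case base across equations).

    Fitted attributes (all standardized unless suffixed ``_raw_``)
    -----------------
    a_paths_ : DataFrame (exogenous x mediators)
    b_paths_ : Series (mediator -> outcome)
    direct_ : Series (exogenous -> outcome)
    indirect_ : DataFrame of per-mediator products a_ik * b_k
    total_indirect_, total_ : Series per exogenous
    r2_outcome_ : float; r2_outcome_reduced_ : without mediators
    mediator_resid_cov_ : residual covariances among mediators
    """

    def __init__(self, exogenous=None, mediators=None, outcome=None):
        self.exogenous = exogenous
        self.mediators = mediators
        self.outcome = outcome

    def _spec(self):
        return PathModelSpec(tuple(self.exogenous), tuple(self.mediators),
                             self.outcome).validate()

    def fit(self, df, y=None):
        spec = self._spec()
        cols = list(spec.exogenous) + list(spec.mediators) + [spec.outcome]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"missing model variables: {missing}")
        data = df[cols + (["family_id"] if "family_id" in df.columns else [])]
        data = data.dropna(subset=cols)
        n = len(data)
        n_par = (len(spec.mediators) + 1) * (len(spec.exogenous) + 1) \
            + len(spec.mediators)
        if n < 5 * (len(spec.exogenous) + len(spec.mediators) + 1):
            raise ValueError(f"too few complete cases (n={n}) for {n_par} "
                             "parameters")

        X = data[list(spec.exogenous)].to_numpy(dtype=float)
        M = data[list(spec.mediators)].to_numpy(dtype=float)
        yv = data[spec.outcome].to_numpy(dtype=float)
        self._check_collinearity(X, spec.exogenous)

        sd_x = X.std(axis=0, ddof=1)
        sd_m = M.std(axis=0, ddof=1)
        sd_y = yv.std(ddof=1)

        ones = np.ones((n, 1))
        Xd = np.hstack([ones, X])
        # a-paths: every mediator on the exogenous block
        a_raw, _, _, _ = np.linalg.lstsq(Xd, M, rcond=None)
        a_raw = a_raw[1:]  # (p, K)
        med_resid = M - Xd @ np.linalg.lstsq(Xd, M, rcond=None)[0]
        # outcome equation with mediators
        XMd = np.hstack([ones, X, M])
        bfull, _, _, _ = np.linalg.lstsq(XMd, yv, rcond=None)
        cprime_raw = bfull[1:1 + X.shape[1]]
        b_raw = bfull[1 + X.shape[1]:]
        resid_full = yv - XMd @ bfull
        # reduced outcome equation (total effects)
        tot_raw = np.linalg.lstsq(Xd, yv, rcond=None)[0][1:]
        resid_red = yv - Xd @ np.linalg.lstsq(Xd, yv, rcond=None)[0]

        exo = list(spec.exogenous)
        meds = list(spec.mediators)
        self.a_paths_raw_ = pd.DataFrame(a_raw, index=exo, columns=meds)
        self.b_paths_raw_ = pd.Series(b_raw, index=meds)
        self.direct_raw_ = pd.Series(cprime_raw, index=exo)
        self.total_raw_ = pd.Series(tot_raw, index=exo)

        self.a_paths_ = self.a_paths_raw_.mul(sd_x, axis=0).div(sd_m, axis=1)
        self.b_paths_ = self.b_paths_raw_ * sd_m / sd_y
        self.direct_ = self.direct_raw_ * sd_x / sd_y
        self.total_ = self.total_raw_ * sd_x / sd_y
        self.indirect_ = self.a_paths_ * self.b_paths_
        self.total_indirect_ = self.indirect_.sum(axis=1)
        self.indirect_raw_ = self.a_paths_raw_ * self.b_paths_raw_
        self.total_indirect_raw_ = self.indirect_raw_.sum(axis=1)

        var_y = yv.var(ddof=0)
        self.r2_outcome_ = 1.0 - resid_full.var(ddof=0) / var_y
        self.r2_outcome_reduced_ = 1.0 - resid_red.var(ddof=0) / var_y
        self.mediator_resid_cov_ = pd.DataFrame(
            np.atleast_2d(np.cov(med_resid, rowvar=False, ddof=1)),
            index=meds, columns=meds)
        self.n_used_ = n
        self.loglik_ = self._gaussian_loglik(resid_full, n)
        self._data_ = data
        return self

    @staticmethod
    def _gaussian_loglik(resid, n):
        s2 = resid.var(ddof=0)
        return float(-0.5 * n * (np.log(2 * np.pi * s2) + 1.0))

    @staticmethod
    def _check_collinearity(X, names, tol=1e-8):
        M = np.column_stack([np.ones(len(X)), X])
        _, R = np.linalg.qr(M)
        d = np.abs(np.diag(R))
        bad = [names[j - 1] for j in range(1, M.shape[1]) if d[j] < tol * d[0]]
        if bad:
            raise ValueError(f"collinear predictors beyond tolerance: {bad}")

    def statistics(self) -> pd.Series:
        """Flat named vector of standardized statistics, bootstrap-friendly."""
        out = {}
        for e in self.a_paths_.index:
            for m in self.a_paths_.columns:
                out[f"a:{e}->{m}"] = self.a_paths_.loc[e, m]
                out[f"ind:{e}->{m}"] = self.indirect_.loc[e, m]
        for m in self.b_paths_.index:
            out[f"b:{m}"] = self.b_paths_[m]
        for e in self.direct_.index:
            out[f"direct:{e}"] = self.direct_[e]
            out[f"total_ind:{e}"] = self.total_indirect_[e]
            out[f"total:{e}"] = self.total_[e]
        out["r2_outcome"] = self.r2_outcome_
        return pd.Series(out)


def fit_path_model(df, spec: PathModelSpec = None) -> PathModel:
    spec = (spec or default_spec()).validate()
    return PathModel(exogenous=list(spec.exogenous),
                     mediators=list(spec.mediators),
                     outcome=spec.outcome).fit(df)


def decompose_effects(fit: PathModel, min_total=0.01) -> pd.DataFrame:
    """Per-exogenous effect decomposition (standardized scale).

    proportion mediated = total indirect / total, suppressed when
    |total| <= ``min_total`` (ratio instability).
    """
    rows = []
    for e in fit.direct_.index:
        total = fit.total_[e]
        rows.append({
            "exogenous": e,
            "direct": fit.direct_[e],
            **{f"indirect_{m}": fit.indirect_.loc[e, m]
               for m in fit.indirect_.columns},
            "total_indirect": fit.total_indirect_[e],
            "total": total,
            "proportion_mediated": (fit.total_indirect_[e] / total
                                    if abs(total) > min_total else np.nan),
        })
    return pd.DataFrame(rows).set_index("exogenous")


@dataclass
class BootstrapResult:
    names: list
    draws: np.ndarray           # (n_successful, k)
    estimates: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    n_draws: int
    n_failed: int
    seed: int
    cluster_key: str = "family_id"

    def se(self):
        return pd.Series(self.draws.std(axis=0, ddof=1), index=self.names)

    def p_values(self):
        """Two-sided normal-approximation p from estimate / bootstrap SE."""
        se = self.se()
        z = self.estimates / se.replace(0.0, np.nan)
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.names)

    def summary(self):
        df = pd.DataFrame({
            "estimate": self.estimates,
            "se": self.se(),
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p_values(),
        })
        df["significant"] = [
            flag_significance(r.estimate, (r.ci_low, r.ci_high), r.p)
            for r in df.itertuples()
        ]
        return df


def cluster_bootstrap(df, statistic, n_draws=1000, seed=0,
                      cluster="family_id", max_fail_frac=0.05):
    """Family-clustered nonparametric percentile bootstrap.

    ``statistic`` maps a resampled DataFrame to a named Series.  Whole
    clusters are resampled with replacement to the original cluster count;
    failed refits are dropped and counted (aborts if more than
    ``max_fail_frac`` fail).  Deterministic given ``seed``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if cluster not in df.columns:
        raise ValueError(f"cluster key {cluster!r} not in data")
    rng = np.random.default_rng(seed)
    est = statistic(df)
    names = list(est.index)

    fam_codes, fam_index = pd.factorize(df[cluster], sort=True)
    rows_by_fam = [np.where(fam_codes == i)[0] for i in range(len(fam_index))]
    nf = len(rows_by_fam)

    draws, n_failed = [], 0
    for _ in range(n_draws):
        sampled = rng.integers(0, nf, nf)
        idx = np.concatenate([rows_by_fam[f] for f in sampled])
        try:
            stat = statistic(df.iloc[idx])
            draws.append(stat.reindex(names).to_numpy(dtype=float))
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > max_fail_frac * n_draws:
        raise RuntimeError(
            f"{n_failed}/{n_draws} bootstrap refits failed; aborting")
    draws = np.asarray(draws)
    lo = pd.Series(np.percentile(draws, 2.5, axis=0), index=names)
    hi = pd.Series(np.percentile(draws, 97.5, axis=0), index=names)
    return BootstrapResult(names=names, draws=draws, estimates=est,
                           ci_low=lo, ci_high=hi, n_draws=n_draws,
                           n_failed=n_failed, seed=seed, cluster_key=cluster)


def flag_significance(estimate, ci, p):
    """Significance rule: 95% CI excludes 0 AND p < .005."""
    lo, hi = ci
    if lo > hi:
        raise ValueError("confidence interval bounds out of order")
    excludes_zero = lo > 0 or hi < 0
    return bool(excludes_zero and np.isfinite(p) and p < P_THRESHOLD)


def significance_table(boot: BootstrapResult) -> pd.DataFrame:
    """Tidy (path, estimate, ci_low, ci_high, p, significant) table."""
    return boot.summary().rename_axis("path").reset_index()
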