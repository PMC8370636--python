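"""Cohort configuration and moment calibration.

The synthetic cohort emulates a longitudinal same-sex twin-family study:
monozygotic (MZ) and dizygotic (DZ) twin pairs assessed on academic
adjustment at ages 11/14/17, cigarettes per day at 14/17/21/24, and a
6-category educational-attainment outcome in adulthood, with two correlated
polygenic scores (PGS) per person.

Each trait follows a stable-trait + autoregressive-state decomposition

    y_t = mu_t + sqrt(psi) * eta + r_t,     r_t = rho_{t-1} r_{t-1} + e_t,

where ``eta`` is the person's standardized random intercept (the stable
trait) and ``r_t`` are occasion residuals.  Given per-occasion SDs and the
three pairwise occasion correlations, (psi, theta_t, rho_t) are exactly
identified and solved in closed form by :func:`solve_trait_panel`.

Random intercepts across the five traits are driven by the two PGSs plus an
additive-genetic / shared-environment / unique (ACE-style) residual that
creates MZ > DZ twin similarity.  Default numeric values are the published
descriptive and path-model estimates for this design (per-age means/SDs and
lag correlations; RI correlation matrix; standardized PGS effects).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import optimize, stats

TRAITS = ("gpa", "motiv_sp", "motiv_teacher", "discipline", "cigs_per_day")
ACADEMIC_TRAITS = TRAITS[:4]
N_PCS = 5

#: published per-occasion descriptives: occasions, means, SDs, and the
#: occasion-correlation matrix entries (r12, r23, r13) for the academic
#: traits; cigarettes carries a single mean lag-1 autocorrelation.
TRAIT_DESCRIPTIVES = {
    "gpa": {
        "occasions": ("11", "14", "17"),
        "means": (3.10, 3.06, 3.02),
        "sds": (0.66, 0.79, 0.77),
        "lag_corrs": (0.64, 0.73),
        "lag2_corr": 0.56,
    },
    "motiv_sp": {
        "occasions": ("11", "14", "17"),
        "means": (20.89, 19.83, 19.76),
        "sds": (2.50, 2.94, 3.08),
        "lag_corrs": (0.47, 0.62),
        "lag2_corr": 0.41,
    },
    "motiv_teacher": {
        "occasions": ("11", "14", "17"),
        "means": (19.87, 19.64, 19.67),
        "sds": (3.13, 3.40, 3.42),
        "lag_corrs": (0.58, 0.58),
        "lag2_corr": 0.53,
    },
    "discipline": {
        "occasions": ("11", "14", "17"),
        "means": (0.0, 0.0, 0.0),
        "sds": (0.61, 0.80, 0.75),
        "lag_corrs": (0.25, 0.48),
        "lag2_corr": 0.25,
    },
    "cigs_per_day": {
        "occasions": ("14", "17", "21", "24"),
        "means": (0.53, 1.36, 2.00, 1.79),
        "sds": (1.29, 1.86, 2.06, 2.05),
        "mean_lag1_corr": 0.67,
    },
}

#: RI-score correlations among the five traits (order = TRAITS).
DEFAULT_RI_CORR = np.array(
    [
        [1.00, 0.58, 0.67, -0.38, -0.30],
        [0.58, 1.00, 0.59, -0.47, -0.36],
        [0.67, 0.59, 1.00, -0.51, -0.38],
        [-0.38, -0.47, -0.51, 1.00, 0.37],
        [-0.30, -0.36, -0.38, 0.37, 1.00],
    ]
)

#: standardized effects of (smoking PGS, education PGS) on each trait RI,
#: from the 2-PGS path model; these reproduce the marginal PGS-RI
#: correlations given the -.23 PGS cross-correlation.
DEFAULT_RI_EFFECTS = {
    "gpa": (-0.09, 0.22),
    "motiv_sp": (-0.13, 0.09),
    "motiv_teacher": (-0.13, 0.19),
    "discipline": (0.15, -0.05),
    "cigs_per_day": (0.18, -0.10),
}

#: standardized path coefficients onto (age-adjusted) educational
#: attainment: two PGS direct effects plus the five RI effects.
DEFAULT_EA_COEFS = {
    "pgs_smoking": -0.07,
    "pgs_edu": 0.11,
    "gpa": 0.28,
    "motiv_sp": 0.03,
    "motiv_teacher": 0.21,
    "discipline": -0.08,
    "cigs_per_day": -0.05,
}

#: attainment category percentages.  The published set
#: (9.5, 9.8, 30.5, 31.9, 8.8, 4.2) sums to 94.7, not 100; the default
#: places the unaccounted 5.3 points in the heterogeneous middle category
#: (vocational / some college / associate's), preserving the other five
#: printed shares exactly.  Normalized on use.
EA_CATEGORY_PERCENTS = (9.5, 9.8, 35.8, 31.9, 8.8, 4.2)

#: representative raw cigarettes/day for each 0-6 category; chosen so the
#: default coding bins map each value back to its own category.
CIGS_CATEGORY_RAW = (0.0, 0.5, 3.0, 8.0, 13.0, 17.5, 25.0)


class CalibrationError(ValueError):
    """A configured moment structure is infeasible or non-PSD."""


def solve_trait_panel(sds, r12, r23, r13):
    """Solve (psi, theta, rho) from 3-occasion SDs and correlations.

    With total variances V_t and occasion covariances c_st the stable-trait
    variance satisfies (c13 - psi)(V2 - psi) = (c12 - psi)(c23 - psi), which
    is linear in psi.  Residual variances and AR coefficients follow by
    back-substitution.
    """
    sd1, sd2, sd3 = sds
    V = np.array([sd1**2, sd2**2, sd3**2])
    c12 = r12 * sd1 * sd2
    c23 = r23 * sd2 * sd3
    c13 = r13 * sd1 * sd3
    denom = c13 + V[1] - c12 - c23
    if abs(denom) < 1e-12:
        raise CalibrationError("degenerate occasion-correlation structure")
    psi = (c13 * V[1] - c12 * c23) / denom
    v = V - psi
    if psi <= 0 or np.any(v <= 0):
        raise CalibrationError(
            f"stable/residual variance split infeasible (psi={psi:.4f}, v={v})"
        )
    rho1 = (c12 - psi) / v[0]
    rho2 = (c23 - psi) / v[1]
    theta = np.array([v[0], v[1] - rho1**2 * v[0], v[2] - rho2**2 * v[1]])
    if np.any(theta <= 0):
        raise CalibrationError(f"negative innovation variance theta={theta}")
    return float(psi), theta, np.array([rho1, rho2])


def maxent_pmf(mean, sd, k_max=6):
    """Maximum-entropy pmf on {0..k_max} with the given mean and SD.

    Has the exponential-family form p_k proportional to exp(a*k + b*k^2);
    (a, b) are solved so the first two moments match.
    """
    ks = np.arange(k_max + 1, dtype=float)
    target = np.array([mean, sd**2 + mean**2])

    def moments(par):
        logits = par[0] * ks + par[1] * ks**2
        logits -= logits.max()
        p = np.exp(logits)
        p /= p.sum()
        return np.array([p @ ks, p @ ks**2]) - target

    sol = optimize.root(moments, x0=np.array([-1.0, 0.0]), method="hybr")
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise CalibrationError(
            f"no maximum-entropy pmf on 0..{k_max} with mean={mean}, sd={sd}"
        )
    logits = sol.x[0] * ks + sol.x[1] * ks**2
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def categorization_attenuation(pmf, values=None):
    """Correlation between a thresholded-normal category variable and its
    latent standard-normal driver.

    Categories are assigned by cutting N(0,1) at the quantiles of ``pmf``;
    Cov(cat, z) = sum_k v_k (phi(t_{k-1}) - phi(t_k)) in closed form.
    """
    pmf = np.asarray(pmf, dtype=float)
    if values is None:
        values = np.arange(pmf.size, dtype=float)
    values = np.asarray(values, dtype=float)
    cum = np.cumsum(pmf)[:-1]
    t = stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))
    phi = stats.norm.pdf(t)
    phi_lo = np.concatenate([[0.0], phi])
    phi_hi = np.concatenate([phi, [0.0]])
    cov = float(values @ (phi_lo - phi_hi))
    mean = float(pmf @ values)
    var = float(pmf @ (values - mean) ** 2)
    return cov / math.sqrt(var)


def _step_hermite_coefs(pmf, values=None, n_terms=60):
    """Hermite coefficients a_k of the thresholded-category step function.

    For cat = f(z) with jumps h_j at thresholds t_j,
    a_k = E[f(z) He_k(z)] = sum_j h_j He_{k-1}(t_j) phi(t_j)  (k >= 1),
    so that Cov(f(z1), f(z2)) = sum_k rho^k a_k^2 / k! for bivariate-normal
    (z1, z2) with correlation rho.
    """
    pmf = np.asarray(pmf, dtype=float)
    if values is None:
        values = np.arange(pmf.size, dtype=float)
    values = np.asarray(values, dtype=float)
    cum = np.cumsum(pmf)[:-1]
    t = stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))
    h = np.diff(values)
    phi = stats.norm.pdf(t)
    # He_{k-1}(t) by recurrence
    coefs = np.empty(n_terms)
    he_prev = np.zeros_like(t)   # He_{-1} convention unused
    he = np.ones_like(t)         # He_0
    for k in range(1, n_terms + 1):
        coefs[k - 1] = float((h * he * phi).sum())
        he_next = t * he - (k - 1) * he_prev
        he_prev, he = he, he_next
    return coefs


def coded_pair_corr(rho, pmf_a, pmf_b, values=None):
    """Exact Pearson correlation between two thresholded-normal category
    variables whose latents have correlation ``rho``."""
    a = _step_hermite_coefs(pmf_a, values)
    b = _step_hermite_coefs(pmf_b, values)
    ks = np.arange(1, a.size + 1)
    weights = np.cumprod(np.full(a.size, rho)) / \
        np.cumprod(ks.astype(float))
    cov = float((weights * a * b).sum())

    def sd(p):
        p = np.asarray(p, dtype=float)
        v = np.arange(p.size) if values is None else np.asarray(values)
        m = p @ v
        return math.sqrt(p @ (v - m) ** 2)

    return cov / (sd(pmf_a) * sd(pmf_b))


def solve_latent_corr(target, pmf_a, pmf_b, values=None):
    """Latent-normal correlation producing a target coded correlation.

    Returns the solution capped at .97 when the target is unattainable
    (the coded correlation is increasing in the latent one).
    """
    hi = 0.97
    if coded_pair_corr(hi, pmf_a, pmf_b, values) <= target:
        return hi
    return float(optimize.brentq(
        lambda r: coded_pair_corr(r, pmf_a, pmf_b, values) - target,
        -0.97, hi, xtol=1e-10))


def _check_psd(mat, name):
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise CalibrationError(f"{name} is not symmetric")
    eigmin = float(np.linalg.eigvalsh(mat).min())
    if eigmin < -1e-10:
        raise CalibrationError(
            f"{name} is not positive semi-definite (min eigenvalue {eigmin:.3e})"
        )


@dataclass
class TraitPanelParams:
    """Stable-trait + AR-state parameters for one trait's occasion panel."""

    occasions: tuple
    means: np.ndarray
    psi: float
    thetas: np.ndarray
    rhos: np.ndarray

    def resid_vars(self):
        """Variances v_t of the occasion-residual factors."""
        v = np.empty(len(self.thetas))
        v[0] = self.thetas[0]
        for t in range(1, len(v)):
            v[t] = self.rhos[t - 1] ** 2 * v[t - 1] + self.thetas[t]
        return v

    def total_sds(self):
        return np.sqrt(self.psi + self.resid_vars())


@dataclass
class MissingnessConfig:
    #: pair-level probability of appearing at each follow-up visit
    retention: dict = field(
        default_factory=lambda: {"14": 0.914, "17": 0.863, "21": 0.717, "24": 0.866}
    )
    #: person-level probability a teacher report exists at each school age
    teacher_availability: dict = field(
        default_factory=lambda: {"11": 0.699, "14": 0.720, "17": 0.598}
    )
    ea_missing: float = 0.079

    def validate(self):
        for name, d in (("retention", self.retention),
                        ("teacher_availability", self.teacher_availability)):
            for occ, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise CalibrationError(f"{name}[{occ}]={p} outside [0,1]")
        if not 0.0 <= self.ea_missing <= 1.0:
            raise CalibrationError(f"ea_missing={self.ea_missing} outside [0,1]")


@dataclass
class EAModel:
    """Latent-liability model for the 6-category attainment outcome.

    The liability is a weighted sum of a standardized age-at-report score,
    the PGSs and trait random intercepts, plus independent noise, cut at
    thresholds matching ``category_props``.  Coefficients are interpreted on
    the observed categorical scale: both the age path and the structural
    paths are inflated by the categorization attenuation factor so that the
    thresholded variable, not the latent one, carries the target effects.
    """

    coefs: dict = field(default_factory=lambda: dict(DEFAULT_EA_COEFS))
    age_corr: float = 0.27
    category_percents: tuple = EA_CATEGORY_PERCENTS
    age_mean: float = 29.4
    age_sd: float = 3.9
    age_range: tuple = (19.7, 39.9)

    def category_props(self):
        p = np.asarray(self.category_percents, dtype=float)
        if np.any(p < 0) or p.sum() <= 0:
            raise CalibrationError("EA category percentages must be non-negative")
        return p / p.sum()

    def thresholds(self):
        cum = np.cumsum(self.category_props())[:-1]
        t = stats.norm.ppf(cum)
        if not np.all(np.diff(t) > 0):
            raise CalibrationError("EA thresholds are not strictly increasing")
        return t

    def attenuation(self):
        return categorization_attenuation(self.category_props(),
                                          values=np.arange(1, 7))


def _default_panel_params():
    panel = {}
    for trait in ACADEMIC_TRAITS:
        d = TRAIT_DESCRIPTIVES[trait]
        psi, thetas, rhos = solve_trait_panel(
            d["sds"], d["lag_corrs"][0], d["lag_corrs"][1], d["lag2_corr"]
        )
        panel[trait] = TraitPanelParams(
            occasions=tuple(d["occasions"]),
            means=np.asarray(d["means"], dtype=float),
            psi=psi,
            thetas=thetas,
            rhos=rhos,
        )
    return panel


def _default_cigs_latent(pmfs, stable_share=0.35, target_lag1=0.67):
    """Latent-scale panel parameters for the cigarettes process.

    The latent process has unit variance at each occasion; the stable-trait
    share is ``stable_share``.  Latent adjacent correlations are solved
    exactly (Hermite series) so the *coded* 0-6 variable shows the target
    lag-1 autocorrelation wherever attainable.
    """
    n_occ = len(pmfs)
    psi = stable_share
    v = np.full(n_occ, 1.0 - psi)
    rhos = np.empty(n_occ - 1)
    thetas = np.empty(n_occ)
    thetas[0] = v[0]
    for t in range(n_occ - 1):
        latent_corr = solve_latent_corr(target_lag1, pmfs[t], pmfs[t + 1])
        rhos[t] = (latent_corr - psi) / v[t]
        thetas[t + 1] = v[t + 1] - rhos[t] ** 2 * v[t]
        if thetas[t + 1] <= 0:
            raise CalibrationError("cigarette latent AR structure infeasible")
    return TraitPanelParams(
        occasions=tuple(TRAIT_DESCRIPTIVES["cigs_per_day"]["occasions"]),
        means=np.zeros(n_occ),
        psi=psi,
        thetas=thetas,
        rhos=rhos,
    )


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic twin-cohort generator."""

    n_families: int = 1881
    prop_mz: float = 1205 / 1881
    prop_younger_cohort: float = 2510 / 3762
    prop_female: float = 0.52

    pgs_cross_corr: float = -0.23
    dz_pgs_within_pair_corr: float = 0.50

    ri_effects: dict = field(default_factory=lambda: dict(DEFAULT_RI_EFFECTS))
    ri_corr: np.ndarray = field(default_factory=lambda: DEFAULT_RI_CORR.copy())
    familial_a: float = 0.40
    familial_c: float = 0.30

    panel: dict = field(default_factory=_default_panel_params)

    #: within-trait twin/self vs mother report correlations
    informant_corr: dict = field(
        default_factory=lambda: {"gpa": 0.79, "motiv_sp": 0.51, "discipline": 0.62}
    )
    #: occasion-level correlation between self/parent and teacher motivation
    motiv_cross_informant_corr: float = 0.55
    teacher_count_probs: tuple = (0.25, 0.45, 0.30)

    cigs_pmfs: np.ndarray = None
    cigs_raw_values: tuple = CIGS_CATEGORY_RAW
    cigs_stable_share: float = 0.35
    cigs_lag1_corr: float = 0.67

    ea: EAModel = field(default_factory=EAModel)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    seed: int = 0

    def __post_init__(self):
        if self.cigs_pmfs is None:
            d = TRAIT_DESCRIPTIVES["cigs_per_day"]
            self.cigs_pmfs = np.stack(
                [maxent_pmf(m, s) for m, s in zip(d["means"], d["sds"])]
            )
        if "cigs_per_day" not in self.panel:
            self.panel["cigs_per_day"] = _default_cigs_latent(
                self.cigs_pmfs, self.cigs_stable_share, self.cigs_lag1_corr
            )

    # -- derived structures -------------------------------------------------

    def pgs_cov(self):
        return np.array([[1.0, self.pgs_cross_corr], [self.pgs_cross_corr, 1.0]])

    def ri_effect_matrix(self):
        """5x2 matrix of standardized PGS effects on the trait RIs."""
        return np.array([self.ri_effects[t] for t in TRAITS], dtype=float)

    def ri_resid_cov(self):
        """Covariance of the non-PGS part of the standardized RIs."""
        B = self.ri_effect_matrix()
        cov = np.asarray(self.ri_corr, dtype=float) - B @ self.pgs_cov() @ B.T
        _check_psd(cov, "random-intercept residual covariance")
        if np.any(np.diag(cov) <= 0):
            raise CalibrationError(
                "PGS effects explain >=100% of a trait random intercept"
            )
        return cov

    def ea_structural_cov(self):
        """Covariance of (pgs_smoking, pgs_edu, eta_1..eta_5)."""
        B = self.ri_effect_matrix()
        Sp = self.pgs_cov()
        top = np.hstack([Sp, (Sp @ B.T)])
        bottom = np.hstack([B @ Sp, np.asarray(self.ri_corr, dtype=float)])
        return np.vstack([top, bottom])

    def ea_liability_weights(self):
        """(age weight, structural weight vector, residual SD) for the EA
        liability, all on the latent N(0,1) scale."""
        lam = self.ea.attenuation()
        names = ["pgs_smoking", "pgs_edu"] + list(TRAITS)
        c = np.array([self.ea.coefs[n] for n in names])
        sigma = self.ea_structural_cov()
        alpha = self.ea.age_corr / lam
        gamma = math.sqrt(1.0 - self.ea.age_corr**2) / lam
        resid_var = 1.0 - alpha**2 - gamma**2 * float(c @ sigma @ c)
        if resid_var <= 0:
            raise CalibrationError(
                "EA liability coefficients explain >=100% of variance"
            )
        return alpha, gamma * c, math.sqrt(resid_var)

    def informant_noise_var(self, trait, occ_index):
        """Variance of the +/- informant disturbance for a two-informant
        trait, from Var(composite) and the target informant correlation."""
        r = self.informant_corr[trait]
        pp = self.panel[trait]
        V = pp.psi + pp.resid_vars()[occ_index]
        return V * (1.0 - r) / (1.0 + r)

    def motiv_innovation_corr(self):
        """Innovation correlation between the two motivation traits solving
        for the target occasion-level cross-informant correlation.

        The implied occasion correlation is linear in the innovation
        correlation delta, so delta has a closed form.
        """
        a = self.panel["motiv_sp"]
        b = self.panel["motiv_teacher"]
        r_eta = float(self.ri_corr[TRAITS.index("motiv_sp"),
                                   TRAITS.index("motiv_teacher")])
        eta_cov = r_eta * math.sqrt(a.psi * b.psi)
        sd_a, sd_b = a.total_sds(), b.total_sds()
        # occasion corr = base_t + slope_t * delta
        base, slope = [], []
        cross_prev = 0.0  # coefficient of delta in Cov(r_a,t, r_b,t)
        for t in range(len(a.occasions)):
            if t > 0:
                cross_prev = a.rhos[t - 1] * b.rhos[t - 1] * cross_prev
            cross_prev += math.sqrt(a.thetas[t] * b.thetas[t])
            denom = sd_a[t] * sd_b[t]
            base.append(eta_cov / denom)
            slope.append(cross_prev / denom)
        target = self.motiv_cross_informant_corr
        delta = (target - np.mean(base)) / np.mean(slope)
        if not -1.0 < delta < 1.0:
            raise CalibrationError(
                f"motivation innovation correlation {delta:.3f} outside (-1,1)"
            )
        return float(delta)

    # -- validation and serialization ---------------------------------------

    def validate(self):
        for name, frac in (
            ("prop_mz", self.prop_mz),
            ("prop_younger_cohort", self.prop_younger_cohort),
            ("prop_female", self.prop_female),
        ):
            if not 0.0 <= frac <= 1.0:
                raise CalibrationError(f"{name}={frac} outside [0,1]")
        if self.n_families < 0:
            raise CalibrationError("n_families must be non-negative")
        if not -1.0 < self.pgs_cross_corr < 1.0:
            raise CalibrationError("pgs_cross_corr outside (-1,1)")
        if not 0.0 <= self.dz_pgs_within_pair_corr <= 1.0:
            raise CalibrationError("dz_pgs_within_pair_corr outside [0,1]")
        if self.familial_a < 0 or self.familial_c < 0 or \
                self.familial_a + self.familial_c > 1.0:
            raise CalibrationError("familial variance fractions infeasible")
        _check_psd(self.ri_corr, "random-intercept correlation matrix")
        _check_psd(self.pgs_cov(), "PGS correlation matrix")
        self.ri_resid_cov()
        self.ea_liability_weights()
        self.ea.thresholds()
        self.missingness.validate()
        for trait, pp in self.panel.items():
            if pp.psi <= 0 or np.any(pp.thetas <= 0):
                raise CalibrationError(f"non-positive variance in panel[{trait}]")
        pm = np.asarray(self.cigs_pmfs)
        if np.any(pm < 0) or not np.allclose(pm.sum(axis=1), 1.0):
            raise CalibrationError("cigarette category pmfs must be distributions")
        if not np.all(np.diff(self.cigs_raw_values) > 0):
            raise CalibrationError("cigs_raw_values must be strictly increasing")
        return self

    def to_dict(self):
        def convert(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: convert(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [convert(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x
        return convert(asdict(self))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "panel" in d:
            d["panel"] = {
                t: TraitPanelParams(
                    occasions=tuple(p["occasions"]),
                    means=np.asarray(p["means"], dtype=float),
                    psi=float(p["psi"]),
                    thetas=np.asarray(p["thetas"], dtype=float),
                    rhos=np.asarray(p["rhos"], dtype=float),
                )
                for t, p in d["panel"].items()
            }
        if "ri_corr" in d:
            d["ri_corr"] = np.asarray(d["ri_corr"], dtype=float)
        if "cigs_pmfs" in d and d["cigs_pmfs"] is not None:
            d["cigs_pmfs"] = np.asarray(d["cigs_pmfs"], dtype=float)
        if "ri_effects" in d:
            d["ri_effects"] = {k: tuple(v) for k, v in d["ri_effects"].items()}
        if "ea" in d and isinstance(d["ea"], dict):
            ea = dict(d["ea"])
            for key in ("category_percents", "age_range"):
                if key in ea:
                    ea[key] = tuple(ea[key])
            d["ea"] = EAModel(**ea)
        if "missingness" in d and isinstance(d["missingness"], dict):
            d["missingness"] = MissingnessConfig(**d["missingness"])
        for key in ("teacher_count_probs", "cigs_raw_values"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed=0, **overrides):
    """The packaged default configuration, optionally overridden."""
    cfg = CohortConfig(seed=seed, **overrides)
    return cfg.validate()
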