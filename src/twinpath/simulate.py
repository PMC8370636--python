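"""Synthetic twin-cohort generator.

Produces long-format person x trait x occasion x informant measurements with
the statistical structure the downstream random-intercept panel and
mediation models assume: MZ/DZ family clustering, two correlated polygenic
scores, stable-trait + AR(1)-state occasion dynamics, informant splitting,
a thresholded 6-category attainment outcome, and cohort/attrition
missingness.

Simulation-truth columns (``ri_true_*``, the per-person random intercepts on
the standardized scale) are carried in the person table for validation and
are not part of the exported long schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    ACADEMIC_TRAITS,
    N_PCS,
    TRAITS,
    CohortConfig,
)

PERSON_COLUMNS = [
    "family_id", "person_id", "zygosity", "sex", "cohort",
    "age_at_last_assessment",
    *[f"pc{i}" for i in range(1, N_PCS + 1)],
    "pgs_smoking", "pgs_edu",
    "ea_category", "ea_age", "ea_observed",
]
MEASUREMENT_COLUMNS = ["person_id", "trait", "occasion", "informant",
                       "value", "observed"]
LONG_COLUMNS = [c for c in PERSON_COLUMNS if c not in
                ("ea_category", "ea_age", "ea_observed")] + \
    ["ea_category", "ea_age", "ea_observed"] + MEASUREMENT_COLUMNS[1:]


@dataclass
class PanelDataset:
    """Normalized container: one person-level table plus long measurements."""

    persons: pd.DataFrame
    measurements: pd.DataFrame

    @property
    def n_persons(self):
        return len(self.persons)

    def trait_wide(self, trait, informant_mean=True, observed_only=True):
        """Person x occasion matrix of informant-averaged values."""
        m = self.measurements
        sel = m[m["trait"] == trait]
        if observed_only:
            sel = sel[sel["observed"]]
        agg = (sel.groupby(["person_id", "occasion"], observed=True)["value"]
                  .mean().unstack("occasion"))
        occs = [o for o in _trait_occasions(self, trait) if o in agg.columns]
        return agg.reindex(index=self.persons["person_id"], columns=occs)

    def copy(self):
        return PanelDataset(self.persons.copy(), self.measurements.copy())


def _trait_occasions(data, trait):
    occ = data.measurements.loc[data.measurements["trait"] == trait,
                                "occasion"]
    seen = list(dict.fromkeys(occ))
    return sorted(seen, key=lambda s: float(s))


def _empty_dataset():
    persons = pd.DataFrame(columns=PERSON_COLUMNS)
    measurements = pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    return PanelDataset(persons, measurements)


def _mvn(rng, cov, n):
    chol = np.linalg.cholesky(cov)
    return rng.standard_normal((n, cov.shape[0])) @ chol.T


def simulate_cohort(config: CohortConfig) -> PanelDataset:
    """Generate a fully observed cohort under ``config``.

    Deterministic given ``config.seed``.  Missingness is applied separately
    by :func:`apply_missingness`.
    """
    config.validate()
    nf = int(config.n_families)
    if nf == 0:
        return _empty_dataset()
    rng = np.random.default_rng([int(config.seed), 0])
    n = 2 * nf

    family_id = np.repeat(np.arange(1, nf + 1), 2)
    person_id = family_id * 10 + np.tile([1, 2], nf)

    n_mz = int(round(config.prop_mz * nf))
    fam_is_mz = np.zeros(nf, dtype=bool)
    fam_is_mz[rng.permutation(nf)[:n_mz]] = True
    zygosity = np.where(np.repeat(fam_is_mz, 2), "MZ", "DZ")

    fam_young = rng.random(nf) < config.prop_younger_cohort
    cohort = np.where(np.repeat(fam_young, 2), "younger", "older")
    fam_female = rng.random(nf) < config.prop_female
    sex = np.repeat(fam_female, 2).astype(float)  # 1 = female

    # polygenic scores: family component + individual component
    Sp = config.pgs_cov()
    F = np.repeat(_mvn(rng, Sp, nf), 2, axis=0)
    U = _mvn(rng, Sp, n)
    a_share = np.where(np.repeat(fam_is_mz, 2), 1.0,
                       config.dz_pgs_within_pair_corr)[:, None]
    pgs = np.sqrt(a_share) * F + np.sqrt(1.0 - a_share) * U

    pcs = rng.standard_normal((n, N_PCS))

    # standardized random intercepts: PGS part + ACE-style residual
    B = config.ri_effect_matrix()
    resid_cov = config.ri_resid_cov()
    d = np.diag(resid_cov)
    r_eps = resid_cov / np.sqrt(np.outer(d, d))
    A, C = config.familial_a, config.familial_c
    E = 1.0 - A - C
    g_fam = np.repeat(_mvn(rng, r_eps, nf), 2, axis=0)
    g_ind = _mvn(rng, r_eps, n)
    g = np.where(np.repeat(fam_is_mz, 2)[:, None], g_fam,
                 math.sqrt(0.5) * g_fam + math.sqrt(0.5) * g_ind)
    c_fam = np.repeat(_mvn(rng, r_eps, nf), 2, axis=0)
    u_ind = _mvn(rng, r_eps, n)
    eps = np.sqrt(d) * (math.sqrt(A) * g + math.sqrt(C) * c_fam
                        + math.sqrt(E) * u_ind)
    eta = pgs @ B.T + eps  # (n, 5), standardized RIs

    # occasion residual processes; motivation innovations are correlated
    delta_mt = config.motiv_innovation_corr()
    resid = {}
    shared_z = {}
    msp, mte = config.panel["motiv_sp"], config.panel["motiv_teacher"]
    for t in range(len(msp.occasions)):
        z = _mvn(rng, np.array([[1.0, delta_mt], [delta_mt, 1.0]]), n)
        shared_z[t] = z
    for k, trait in enumerate(TRAITS):
        pp = config.panel[trait]
        T = len(pp.occasions)
        r = np.zeros((n, T))
        for t in range(T):
            if trait == "motiv_sp":
                e = shared_z[t][:, 0] * math.sqrt(pp.thetas[t])
            elif trait == "motiv_teacher":
                e = shared_z[t][:, 1] * math.sqrt(pp.thetas[t])
            else:
                e = rng.standard_normal(n) * math.sqrt(pp.thetas[t])
            r[:, t] = e if t == 0 else pp.rhos[t - 1] * r[:, t - 1] + e
        resid[trait] = r

    blocks = []

    def add_block(trait, occasion, informant, values):
        blocks.append(pd.DataFrame({
            "person_id": person_id,
            "trait": trait,
            "occasion": occasion,
            "informant": informant,
            "value": values,
            "observed": True,
        }))

    # academic traits: latent composite split into informant reports
    two_informant = {"gpa": ("twin", "mother"),
                     "motiv_sp": ("self", "mother"),
                     "discipline": ("twin", "mother")}
    for k, trait in enumerate(ACADEMIC_TRAITS):
        pp = config.panel[trait]
        for t, occ in enumerate(pp.occasions):
            latent = pp.means[t] + math.sqrt(pp.psi) * eta[:, k] + \
                resid[trait][:, t]
            if trait in two_informant:
                q = config.informant_noise_var(trait, t)
                dlt = rng.standard_normal(n) * math.sqrt(q)
                i1, i2 = two_informant[trait]
                add_block(trait, occ, i1, latent + dlt)
                add_block(trait, occ, i2, latent - dlt)
            else:  # teacher ratings: 1-3 teachers, mean equal to latent
                probs = np.asarray(config.teacher_count_probs)
                k_teachers = rng.choice(
                    np.arange(1, len(probs) + 1), size=n, p=probs / probs.sum())
                V = pp.psi + pp.resid_vars()[t]
                noise = rng.standard_normal((n, 3)) * math.sqrt(0.3 * V)
                mask = np.arange(1, 4)[None, :] <= k_teachers[:, None]
                noise -= (noise * mask).sum(1, keepdims=True) / \
                    k_teachers[:, None]
                for j in range(3):
                    vals = latent + noise[:, j]
                    vals = np.where(mask[:, j], vals, np.nan)
                    blk = pd.DataFrame({
                        "person_id": person_id[mask[:, j]],
                        "trait": trait,
                        "occasion": occ,
                        "informant": f"teacher_{j + 1}",
                        "value": vals[mask[:, j]],
                        "observed": True,
                    })
                    blocks.append(blk)

    # cigarettes: latent N(0,1) per occasion -> maxent category -> raw value
    pp = config.panel["cigs_per_day"]
    raw_values = np.asarray(config.cigs_raw_values)
    k_cig = TRAITS.index("cigs_per_day")
    for t, occ in enumerate(pp.occasions):
        z = math.sqrt(pp.psi) * eta[:, k_cig] + resid["cigs_per_day"][:, t]
        cuts = stats.norm.ppf(np.cumsum(config.cigs_pmfs[t])[:-1])
        cat = np.searchsorted(cuts, z)
        add_block("cigs_per_day", occ, "self", raw_values[cat])

    # educational attainment
    alpha, w, resid_sd = config.ea_liability_weights()
    ea_age = np.clip(rng.normal(config.ea.age_mean, config.ea.age_sd, n),
                     *config.ea.age_range)
    z_age = (ea_age - config.ea.age_mean) / config.ea.age_sd
    struct = np.hstack([pgs, eta])
    liab = alpha * z_age + struct @ w + resid_sd * rng.standard_normal(n)
    ea_cat = 1 + np.searchsorted(config.ea.thresholds(), liab)

    persons = pd.DataFrame({
        "family_id": family_id,
        "person_id": person_id,
        "zygosity": zygosity,
        "sex": sex,
        "cohort": cohort,
        "age_at_last_assessment": np.round(ea_age, 2),
        **{f"pc{i + 1}": pcs[:, i] for i in range(N_PCS)},
        "pgs_smoking": pgs[:, 0],
        "pgs_edu": pgs[:, 1],
        "ea_category": ea_cat,
        "ea_age": np.round(ea_age, 2),
        "ea_observed": True,
        **{f"ri_true_{t}": eta[:, i] for i, t in enumerate(TRAITS)},
    })
    measurements = pd.concat(blocks, ignore_index=True)
    for col in ("trait", "occasion", "informant"):
        measurements[col] = measurements[col].astype("category")
    return PanelDataset(persons, measurements)


def apply_missingness(data: PanelDataset, config: CohortConfig) -> PanelDataset:
    """Set observed flags by cohort design and pair-level attrition.

    Older-cohort persons are unobserved at ages 11 and 14 by design.
    Follow-up visits are missed at the pair (family) level with the
    configured retention probabilities; teacher reports are additionally
    missing at the person-occasion level; attainment is missing at the
    person level.  Rows flagged unobserved carry no value.
    """
    config.missingness.validate()
    data = data.copy()
    if data.n_persons == 0:
        return data
    rng = np.random.default_rng([int(config.seed), 17])
    persons = data.persons
    m = data.measurements
    miss = config.missingness

    fam_ids = persons["family_id"].unique()
    fam_young = persons.drop_duplicates("family_id").set_index("family_id")[
        "cohort"].eq("younger")
    pid_to_fam = persons.set_index("person_id")["family_id"]
    fam_of_row = m["person_id"].map(pid_to_fam)
    row_young = fam_of_row.map(fam_young).to_numpy()

    observed = m["observed"].to_numpy().copy()

    # design: older cohort joins at 17 -- nothing observed at 11 or 14
    design_missing = (~row_young) & m["occasion"].isin(["11", "14"]).to_numpy()
    observed &= ~design_missing

    # pair-level visit attrition
    for occ, rate in miss.retention.items():
        present = pd.Series(rng.random(len(fam_ids)) < rate, index=fam_ids)
        if occ in ("14", "17"):  # intake visits for the older cohort
            present |= ~fam_young.reindex(fam_ids)
            if occ == "14":
                continue_mask = row_young
            else:
                continue_mask = np.ones(len(m), dtype=bool)
        else:
            continue_mask = np.ones(len(m), dtype=bool)
        at_occ = m["occasion"].eq(occ).to_numpy() & continue_mask
        fam_present = fam_of_row.map(present).to_numpy()
        observed &= ~(at_occ & ~fam_present)

    # teacher availability, one draw per person-occasion
    is_teacher = m["informant"].astype(str).str.startswith("teacher").to_numpy()
    for occ, rate in miss.teacher_availability.items():
        avail = pd.Series(rng.random(data.n_persons) < rate,
                          index=persons["person_id"])
        row_avail = m["person_id"].map(avail).to_numpy()
        sel = is_teacher & m["occasion"].eq(occ).to_numpy()
        observed &= ~(sel & ~row_avail)

    m["observed"] = observed
    m.loc[~m["observed"], "value"] = np.nan
    ea_obs = rng.random(data.n_persons) >= miss.ea_missing
    persons["ea_observed"] = ea_obs
    persons.loc[~ea_obs, "ea_category"] = np.nan
    return data


# -- persistence ------------------------------------------------------------

def export_panel(data: PanelDataset, path, layout="long", sep=",",
                 missing_sentinel="NA"):
    """Write the dataset; ``long`` round-trips through :func:`read_panel`,
    ``wide`` has one row per person with trait_occasion composite columns."""
    if data.n_persons == 0:
        raise ValueError("refusing to export an empty dataset")
    if layout == "long":
        pers = data.persons[[c for c in data.persons.columns
                             if not c.startswith("ri_true_")]]
        df = data.measurements.merge(pers, on="person_id", how="left")
        df = df[LONG_COLUMNS]
    elif layout == "wide":
        df = to_wide(data)
    else:
        raise ValueError(f"unknown layout {layout!r} (expected long|wide)")
    df.to_csv(path, sep=sep, index=False, na_rep=missing_sentinel)
    return path


def to_wide(data: PanelDataset) -> pd.DataFrame:
    """One row per person: covariates + informant-mean composite columns
    named trait_occasion (e.g. gpa_11)."""
    pers = data.persons[[c for c in data.persons.columns
                         if not c.startswith("ri_true_")]].copy()
    obs = data.measurements[data.measurements["observed"]]
    comp = (obs.groupby(["person_id", "trait", "occasion"], observed=True)
               ["value"].mean().reset_index())
    comp["col"] = comp["trait"].astype(str) + "_" + comp["occasion"].astype(str)
    wide = comp.pivot(index="person_id", columns="col", values="value")
    ordered = [f"{t}_{o}" for t in TRAITS
               for o in map(str, _trait_occasions(data, t))
               if f"{t}_{o}" in wide.columns]
    return pers.merge(wide[ordered], left_on="person_id", right_index=True,
                      how="left")


def read_panel(path, sep=",", missing_sentinel="NA") -> PanelDataset:
    """Reconstruct a :class:`PanelDataset` from a long-layout export."""
    df = pd.read_csv(path, sep=sep, na_values=[missing_sentinel],
                     keep_default_na=False,
                     dtype={"occasion": str})
    person_cols = [c for c in PERSON_COLUMNS if c in df.columns]
    persons = df[person_cols].drop_duplicates("person_id").reset_index(drop=True)
    measurements = df[MEASUREMENT_COLUMNS].copy()
    measurements["observed"] = measurements["observed"].astype(bool)
    for col in ("trait", "occasion", "informant"):
        measurements[col] = measurements[col].astype("category")
    return PanelDataset(persons, measurements)
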