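"""End-to-end analysis pipeline on a synthetic cohort.

Stages: simulate -> apply missingness -> build composites -> unconditional
RI-PMs per trait -> MAP factor scores -> conditional (1-PGS / 2-PGS) RI-PMs
-> per-age cross-sectional regressions -> mediation path model with
family-clustered bootstrap -> summary tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import TRAITS, ACADEMIC_TRAITS, CohortConfig, default_config
from .measures import build_composites
from .mediation import (cluster_bootstrap, decompose_effects, default_spec,
                        fit_path_model, significance_table)
from .reporting import (descriptives_table, lag1_correlations,
                        mean_lag1_autocorrelation, percent_attenuation,
                        render_tables)
from .ripm import RandomInterceptPanelModel, fit_crosssection
from .scoring import map_scores
from .simulate import apply_missingness, simulate_cohort

log = logging.getLogger(__name__)

CONTROLS = ["sex", "pc1", "pc2", "pc3", "pc4", "pc5"]
PGS_COLS = ["pgs_smoking", "pgs_edu"]


def trait_occasion_columns(composites, trait):
    prefix = f"{trait}_"
    cols = [c for c in composites.columns if c.startswith(prefix)
            and c[len(prefix):].isdigit()]
    return sorted(cols, key=lambda c: int(c[len(prefix):]))


def fit_unconditional_models(composites):
    """Unconditional RI-PM per trait; returns {trait: fitted model}."""
    fits = {}
    for trait in TRAITS:
        cols = trait_occasion_columns(composites, trait)
        Y = composites[cols]
        fits[trait] = RandomInterceptPanelModel().fit(Y)
        log.info("unconditional RI-PM %s: loglik=%.1f psi=%.3f rho=%s",
                 trait, fits[trait].loglik_, fits[trait].psi_,
                 np.round(fits[trait].rho_, 3))
    return fits


def compute_factor_scores(composites, fits):
    """MAP scores from the unconditional fits, joined onto the composites
    table as ri_<trait> columns."""
    out = composites.copy()
    for trait, fit in fits.items():
        cols = trait_occasion_columns(composites, trait)
        sc = map_scores(fit, composites[cols],
                        person_ids=composites["person_id"])
        out[f"ri_{trait}"] = sc["score"].to_numpy()
    return out


def fit_conditional_models(composites, compute_vcov=False):
    """1-PGS and 2-PGS conditional RI-PMs per trait.

    Returns a tidy frame of standardized PGS coefficients per
    (trait, model, pgs)."""
    rows = []
    fits = {}
    for trait in TRAITS:
        cols = trait_occasion_columns(composites, trait)
        Y = composites[cols]
        for model_name, pgs_set in (("1pgs_smoking", ["pgs_smoking"]),
                                    ("1pgs_edu", ["pgs_edu"]),
                                    ("2pgs", PGS_COLS)):
            X = composites[pgs_set + CONTROLS]
            fit = RandomInterceptPanelModel(compute_vcov=compute_vcov).fit(Y, X)
            fits[(trait, model_name)] = fit
            for j, pgs in enumerate(pgs_set):
                rows.append({
                    "trait": trait, "model": model_name, "pgs": pgs,
                    "estimate": fit.standardized_gamma_[j],
                    "converged": fit.converged_,
                })
    return pd.DataFrame(rows), fits


def crosssection_coefficients(composites):
    """Standardized per-age PGS coefficients from multiple regressions."""
    rows = []
    for trait in ACADEMIC_TRAITS:
        for col in trait_occasion_columns(composites, trait):
            occ = col.rsplit("_", 1)[1]
            for pgs in PGS_COLS:
                coefs = fit_crosssection(
                    composites[col], composites[[pgs] + CONTROLS])
                rows.append({"trait": trait, "occasion": occ, "pgs": pgs,
                             "estimate": coefs[pgs]})
    return pd.DataFrame(rows)


def attenuation_summary(conditional: pd.DataFrame) -> pd.DataFrame:
    """Percent attenuation of each PGS effect from the 1-PGS to the 2-PGS
    model, per trait."""
    rows = []
    for trait in conditional["trait"].unique():
        sub = conditional[conditional["trait"] == trait]
        for pgs, m1 in (("pgs_smoking", "1pgs_smoking"),
                        ("pgs_edu", "1pgs_edu")):
            b1 = float(sub.loc[(sub.model == m1) & (sub.pgs == pgs),
                               "estimate"].iloc[0])
            b2 = float(sub.loc[(sub.model == "2pgs") & (sub.pgs == pgs),
                               "estimate"].iloc[0])
            rows.append({"trait": trait, "pgs": pgs, "beta_1pgs": b1,
                         "beta_2pgs": b2,
                         "percent_reduction": percent_attenuation(b1, b2)})
    return pd.DataFrame(rows)


def mediation_correlations(scored: pd.DataFrame) -> pd.DataFrame:
    """Correlations among PGSs, RI scores and the attainment residual."""
    cols = PGS_COLS + [f"ri_{t}" for t in TRAITS] + ["ea_residual"]
    return scored[cols].corr()


def run_pipeline(config: CohortConfig = None, bootstrap_draws=1000,
                 bootstrap_seed=None, out_dir=None):
    """Run every stage; returns a dict of artifacts."""
    config = config or default_config()
    if bootstrap_seed is None:
        bootstrap_seed = int(config.seed) + 1

    data = apply_missingness(simulate_cohort(config), config)
    composites = build_composites(data)
    uncond = fit_unconditional_models(composites)
    scored = compute_factor_scores(composites, uncond)
    conditional, cond_fits = fit_conditional_models(composites)
    crosssec = crosssection_coefficients(composites)
    atten = attenuation_summary(conditional)
    corr = mediation_correlations(scored)

    spec = default_spec()
    path_fit = fit_path_model(scored, spec)
    boot = cluster_bootstrap(
        scored, lambda d: fit_path_model(d, spec).statistics(),
        n_draws=bootstrap_draws, seed=bootstrap_seed)
    effects = decompose_effects(path_fit)
    sig = significance_table(boot)

    results = {
        "data": data,
        "composites": composites,
        "scored": scored,
        "unconditional_fits": uncond,
        "conditional": conditional,
        "conditional_fits": cond_fits,
        "crosssection": crosssec,
        "attenuation": atten,
        "correlations": corr,
        "path_fit": path_fit,
        "bootstrap": boot,
        "effects": effects,
        "significance": sig,
    }
    if out_dir is not None:
        write_outputs(results, out_dir)
    return results


def write_outputs(results, out_dir):
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comp = results["composites"]
    occ_map = {t: [c.rsplit("_", 1)[1] for c in
                   trait_occasion_columns(comp, t)] for t in TRAITS}
    desc = descriptives_table(comp, occ_map)
    results["conditional"].to_csv(out / "conditional_coefficients.csv",
                                  index=False)
    results["crosssection"].to_csv(out / "crosssection_coefficients.csv",
                                   index=False)
    results["attenuation"].to_csv(out / "attenuation.csv", index=False)
    results["significance"].to_csv(out / "mediation_bootstrap.csv",
                                   index=False)
    scored_cols = ["person_id"] + [f"ri_{t}" for t in TRAITS]
    results["scored"][scored_cols].to_csv(out / "factor_scores.csv",
                                          index=False)
    render_tables(out, descriptives=desc,
                  coefficients=results["conditional"],
                  correlations=results["correlations"].round(4),
                  mediation=results["effects"].reset_index())
    log.info("wrote outputs to %s", out)
    return out
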