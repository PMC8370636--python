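"""Per-person random-intercept (MAP) factor scores from a fitted RI-PM.

Under the fitted normal model the posterior of a person's random intercept
given their observed occasions is normal, so the posterior mode equals the
posterior mean and has the closed form

    score = Gamma'x + psi * 1' Sigma_obs^{-1} (y_obs - mu_obs - 1 Gamma'x),

with Sigma_obs the implied covariance restricted to observed occasions.
Scores shrink toward the (conditional) mean; the shrinkage weight for a
single occasion with no AR structure is psi / (psi + theta).

Downstream mediation regressions use scores from *unconditional* fits, so
predictor effects estimated on the scores are not double-counted through
the scoring step.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

__all__ = ["map_scores", "score_reliability", "score_table"]


def map_scores(fit, Y, X=None, person_ids=None) -> pd.DataFrame:
    """MAP random-intercept scores for each row of the wide panel ``Y``.

    Persons with zero observed occasions get NaN.  Returns a DataFrame with
    columns (person_id, score, n_occasions_used).
    """
    if not getattr(fit, "converged_", False):
        raise ValueError("factor scoring requires a converged fit")
    Yarr = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) \
        else np.asarray(Y, dtype=float)
    scores = fit.transform(Y, X)
    n_obs = np.isfinite(Yarr).sum(axis=1)
    if person_ids is None:
        person_ids = (Y.index if isinstance(Y, pd.DataFrame)
                      else np.arange(len(Yarr)))
    return pd.DataFrame({
        "person_id": np.asarray(person_ids),
        "score": scores,
        "n_occasions_used": n_obs,
    })


def score_reliability(fit, pattern):
    """Reliability Var(score)/psi of the MAP score for an observed-occasion
    mask; lies in [0, 1] and is non-decreasing in the pattern."""
    return fit.score_reliability(pattern)


def reliability_by_pattern(fit, n_occasions):
    """Reliability for every non-empty observation pattern."""
    out = {}
    for bits in itertools.product([0, 1], repeat=n_occasions):
        if any(bits):
            out[bits] = fit.score_reliability(np.array(bits, dtype=bool))
    return out


def score_table(scores_by_trait: dict) -> pd.DataFrame:
    """Long (person_id, trait, score, n_occasions_used) table from per-trait
    score frames."""
    frames = []
    for trait, df in scores_by_trait.items():
        d = df.copy()
        d.insert(1, "trait", trait)
        frames.append(d)
    return pd.concat(frames, ignore_index=True)
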