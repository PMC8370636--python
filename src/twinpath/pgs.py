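"""Polygenic-score construction from a dosage matrix and a weight table.

Implements additive per-allele scoring with standard score-file semantics:
score_i = sum_j w_j d_ij over the variants shared between the dosage matrix
and the weight table, with mean imputation or skipping for missing dosages.
Strand handling is deliberately minimal: with only the counted allele
available per dosage column, a complement-allele match cannot be
distinguished from an allele flip on a palindromic variant, so complement
matches are dropped (with a logged count) rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def read_weight_table(path) -> pd.DataFrame:
    """Read a 3-column whitespace/tab-delimited (variant, allele, weight)
    score file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["variant_id", "effect_allele", "weight"])
    return _validate_weights(df)


def _validate_weights(df):
    if df["variant_id"].duplicated().any():
        dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant ids in weight table: {dups[:5]}")
    if not np.all(np.isfinite(df["weight"].to_numpy(dtype=float))):
        raise ValueError("non-finite weights in weight table")
    bad = ~df["effect_allele"].str.upper().isin(list("ACGT"))
    if bad.any():
        raise ValueError(
            f"invalid effect alleles: {df.loc[bad, 'effect_allele'].tolist()[:5]}")
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].str.upper()
    return df


def read_dosage_matrix(path, sep=None) -> pd.DataFrame:
    """Read a rectangular dosage table (PLINK .raw style accepted).

    Metadata columns (FID/PAT/MAT/SEX/PHENOTYPE) are dropped; IID becomes
    the index when present.  Column names of the form ``variant_allele``
    carry the counted allele.
    """
    df = pd.read_csv(path, sep=sep or r"\s+")
    if "IID" in df.columns:
        df = df.set_index("IID")
    df = df.drop(columns=[c for c in _PLINK_META if c in df.columns],
                 errors="ignore")
    return df.astype(float)


def _split_counted_allele(col):
    if "_" in col and col.rsplit("_", 1)[1].upper() in COMPLEMENT:
        vid, allele = col.rsplit("_", 1)
        return vid, allele.upper()
    return col, None


@dataclass
class ScoringReport:
    n_scored: int
    n_dropped_palindromic: int
    dropped_variants: list
    mismatched_variants: list


class PGSScorer(BaseEstimator, TransformerMixin):
    """Additive polygenic scoring as an sklearn transformer.

    Parameters
    ----------
    weights : DataFrame with columns variant_id, effect_allele, weight
    missing_policy : 'mean_impute' replaces a missing dosage with that
        variant's sample mean; 'skip' treats it as zero contribution.
    """

    def __init__(self, weights=None, missing_policy="mean_impute"):
        self.weights = weights
        self.missing_policy = missing_policy

    def fit(self, X, y=None):
        if self.missing_policy not in ("mean_impute", "skip"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        weights = _validate_weights(pd.DataFrame(self.weights))
        wmap = weights.set_index("variant_id")

        cols, used_w, dropped, mismatched = [], [], [], []
        for col in X.columns:
            vid, counted = _split_counted_allele(str(col))
            if vid not in wmap.index:
                continue
            effect = wmap.loc[vid, "effect_allele"]
            w = float(wmap.loc[vid, "weight"])
            if counted is None or counted == effect:
                cols.append(col)
                used_w.append(w)
            elif counted == COMPLEMENT[effect]:
                dropped.append(vid)  # strand flip vs allele flip: ambiguous
            else:
                mismatched.append(vid)
        if mismatched:
            raise ValueError(
                "allele mismatch without a complement resolution for "
                f"variants: {mismatched}")
        if not cols:
            raise ValueError("no variants shared between dosages and weights")
        if dropped:
            log.info("dropped %d palindromic/ambiguous variants: %s",
                     len(dropped), dropped[:10])
        self.used_columns_ = cols
        self.used_weights_ = np.asarray(used_w)
        self.report_ = ScoringReport(len(cols), len(dropped), dropped,
                                     mismatched)
        return self

    def transform(self, X):
        D = np.asarray(X[self.used_columns_], dtype=float)
        if np.nanmin(D, initial=0.0) < 0 or np.nanmax(D, initial=0.0) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if self.missing_policy == "mean_impute":
            col_means = np.nanmean(D, axis=0)
            idx = np.where(np.isnan(D))
            D[idx] = np.take(col_means, idx[1])
        else:
            D = np.nan_to_num(D, nan=0.0)
        return D @ self.used_weights_


def score_pgs(dosages, weights, missing_policy="mean_impute"):
    """Per-person additive scores; see :class:`PGSScorer`."""
    scorer = PGSScorer(weights=weights, missing_policy=missing_policy)
    return scorer.fit(dosages).transform(dosages)


def standardize_scores(scores):
    """Z-scores with the n-1 denominator; constant input is rejected."""
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 scores to standardize")
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("scores are constant; z-scores undefined")
    return (arr - arr.mean()) / sd
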