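"""Derived arithmetic and table rendering.

Small pure functions reproducing the summary arithmetic used when reading
longitudinal panel results: mean lag-1 autocorrelations, percent
attenuation between 1-predictor and 2-predictor models, block summaries of
correlation matrices, and tidy/markdown renderings of descriptive and
coefficient tables with half-up 2-decimal rounding.
"""

from __future__ import annotations

import decimal

import numpy as np
import pandas as pd

__all__ = [
    "mean_lag1_autocorrelation", "percent_attenuation",
    "correlation_summary", "round_half_up", "format_estimate",
    "descriptives_table", "coefficient_table", "markdown_table",
    "render_tables",
]


def mean_lag1_autocorrelation(corrs):
    """Arithmetic mean of adjacent-occasion (lag-1) correlations only.

    Lag-2+ correlations are excluded by definition: for a 3-occasion panel
    the input is (r_12, r_23).
    """
    arr = np.atleast_1d(np.asarray(corrs, dtype=float))
    if arr.size < 1:
        raise ValueError("need at least one adjacent-lag correlation")
    return float(arr.mean())


def lag1_correlations(wide):
    """Adjacent-occasion correlations of a person x occasion matrix
    (pairwise-complete)."""
    df = pd.DataFrame(wide)
    return np.array([df.iloc[:, t].corr(df.iloc[:, t + 1])
                     for t in range(df.shape[1] - 1)])


def percent_attenuation(beta_1pgs, beta_2pgs):
    """Percent reduction in effect magnitude after adjusting for the second
    predictor: (|b1| - |b2|) / |b1| * 100.  Negative values indicate
    suppression."""
    if beta_1pgs == 0:
        raise ValueError("attenuation undefined for a zero base coefficient")
    return (abs(beta_1pgs) - abs(beta_2pgs)) / abs(beta_1pgs) * 100.0


def correlation_summary(corr, rows, cols, mode="mean_abs"):
    """Summary of the absolute entries of a correlation-matrix block,
    excluding diagonal self-pairs."""
    corr = pd.DataFrame(corr)
    rows, cols = list(rows), list(cols)
    for name in rows + cols:
        if name not in corr.index or name not in corr.columns:
            raise ValueError(f"variable {name!r} not in correlation matrix")
    seen = set()
    unique_vals = []
    for r in rows:
        for c in cols:
            if r == c or (c, r) in seen:
                continue
            seen.add((r, c))
            unique_vals.append(abs(float(corr.loc[r, c])))
    if not unique_vals:
        raise ValueError("empty correlation block")
    arr = np.asarray(unique_vals)
    if mode == "mean_abs":
        return float(arr.mean())
    if mode == "max_abs":
        return float(arr.max())
    if mode == "min_abs":
        return float(arr.min())
    raise ValueError(f"unknown mode {mode!r}")


def round_half_up(x, ndigits=2):
    """Decimal round-half-up (so .545 -> .55, -.545 -> -.55, i.e. halves go
    away from zero), matching printed tables.  Values are first snapped to
    10 decimal digits so binary artifacts like 0.544999...9 round as the
    decimal .545 they represent."""
    q = decimal.Decimal(10) ** -ndigits
    snapped = repr(round(float(x), 10))
    return float(decimal.Decimal(snapped).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def format_estimate(x, ndigits=2, bold=False):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    s = f"{round_half_up(x, ndigits):.{ndigits}f}"
    return f"**{s}**" if bold else s


def markdown_table(df: pd.DataFrame) -> str:
    """Minimal GitHub-style markdown rendering (no external dependency)."""
    cols = [str(c) for c in df.columns]
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


def descriptives_table(composites: pd.DataFrame, traits_occasions) -> pd.DataFrame:
    """Per trait x occasion mean/SD/N plus lag-1 correlations, shaped like a
    longitudinal descriptives table."""
    rows = []
    for trait, occasions in traits_occasions.items():
        cols = [f"{trait}_{o}" for o in occasions
                if f"{trait}_{o}" in composites.columns]
        sub = composites[cols]
        lag1 = lag1_correlations(sub)
        row = {"trait": trait}
        for i, c in enumerate(cols):
            occ = occasions[i]
            row[f"M_{occ}"] = round_half_up(sub[c].mean())
            row[f"SD_{occ}"] = round_half_up(sub[c].std())
            row[f"N_{occ}"] = int(sub[c].notna().sum())
        row["mean_lag1_autocorr"] = round_half_up(
            mean_lag1_autocorrelation(lag1))
        rows.append(row)
    return pd.DataFrame(rows)


def coefficient_table(entries) -> pd.DataFrame:
    """Tidy coefficient table: entries are dicts with at least
    (outcome, predictor, model, estimate, ci_low, ci_high, significant)."""
    df = pd.DataFrame(list(entries))
    if df.empty:
        return pd.DataFrame(columns=["outcome", "predictor", "model",
                                     "estimate", "ci_low", "ci_high",
                                     "significant"])
    df["formatted"] = [
        format_estimate(r.estimate, bold=bool(getattr(r, "significant", False)))
        + (f" [{format_estimate(r.ci_low)}, {format_estimate(r.ci_high)}]"
           if np.isfinite(getattr(r, "ci_low", np.nan)) else "")
        for r in df.itertuples()
    ]
    return df


def render_tables(out_dir, descriptives=None, coefficients=None,
                  correlations=None, mediation=None):
    """Write CSV + markdown renderings of whichever inputs are available;
    missing inputs are flagged in the report rather than failing."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    md = ["# Results tables\n"]
    sections = [
        ("table1_descriptives", "Descriptives and stability", descriptives),
        ("table2_coefficients", "PGS regression coefficients", coefficients),
        ("table3_correlations", "Mediation-model correlations", correlations),
        ("table4_mediation", "Mediation decomposition", mediation),
    ]
    for stem, title, df in sections:
        md.append(f"\n## {title}\n")
        if df is None or (hasattr(df, "empty") and df.empty):
            md.append("_not available in this run_\n")
            continue
        if isinstance(df, pd.DataFrame) and df.index.name:
            df = df.reset_index()
        df.to_csv(out / f"{stem}.csv", index=False)
        shown = df.copy()
        for c in shown.columns:
            if shown[c].dtype.kind == "f":
                shown[c] = [format_estimate(v) for v in shown[c]]
        md.append(markdown_table(shown))
    report = out / "report.md"
    report.write_text("\n".join(md))
    return report
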