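"""Variable construction: composites, discipline CFA, cigarette binning,
attainment residualization."""

import numpy as np
import pytest
from sklearn.decomposition import FactorAnalysis

from twinpath.config import default_config
from twinpath.measures import (
    OneFactorCFA,
    build_composites,
    code_cigarettes,
    code_discipline_items,
    compose_gpa,
    compose_motivation,
    compose_motivation_teacher,
    fit_discipline_cfa,
    residualize_attainment,
)
from twinpath.simulate import simulate_cohort


class TestComposites:
    def test_gpa_examples(self):
        assert compose_gpa([4, 4, 4, 4], [4, 4, 4, 4]) == 4.0
        assert compose_gpa([4, 3, 3, 2], [2, 3, 3, 4]) == 3.0
        assert compose_gpa([3, 3, 2, 2], None) == 2.5

    def test_gpa_validation(self):
        with pytest.raises(ValueError):
            compose_gpa([5, 4, 4, 4], [4, 4, 4, 4])
        with pytest.raises(ValueError):
            compose_gpa([4, 4, 4], [4, 4, 4, 4])
        with pytest.raises(ValueError):
            compose_gpa(None, None)

    def test_motivation_examples(self):
        mid = [2.5] * 6
        assert compose_motivation(mid, mid) == 15.0  # 6 x midpoint
        assert compose_motivation([4, 4, 4, 4, 3, 3], [3, 3, 3, 3, 3, 3]) == 20.0
        assert compose_motivation_teacher(
            [[3] * 6, [4, 4, 3, 3, 3, 3], [4, 4, 4, 4, 3, 3]]) == 20.0

    def test_informant_order_invariance(self, rng):
        a, b = rng.uniform(1, 4, 6), rng.uniform(1, 4, 6)
        assert compose_motivation(a, b) == compose_motivation(b, a)
        ga, gb = rng.uniform(0, 4, 4), rng.uniform(0, 4, 4)
        assert compose_gpa(ga, gb) == compose_gpa(gb, ga)
        da = rng.integers(0, 3, 6).astype(float)
        db = rng.integers(0, 3, 6).astype(float)
        np.testing.assert_array_equal(code_discipline_items(da, db),
                                      code_discipline_items(db, da))

    def test_discipline_either_informant_max(self):
        assert code_discipline_items([0] * 6, [0] * 6).tolist() == [0] * 6
        got = code_discipline_items([2, 0, 1, 0, 0, 0], [1, 1, 0, 0, 2, 0])
        assert got.tolist() == [2, 1, 1, 0, 2, 0]
        passthrough = code_discipline_items(None, [1, 0, 2, 0, 1, 0])
        assert passthrough.tolist() == [1, 0, 2, 0, 1, 0]
        with pytest.raises(ValueError):
            code_discipline_items([3, 0, 0, 0, 0, 0], [0] * 6)
        with pytest.raises(ValueError):
            code_discipline_items([0.5, 0, 0, 0, 0, 0], [0] * 6)


class TestDisciplineCFA:
    def test_recovers_simulation_loadings(self, rng):
        """Items generated from a 1-factor model with standardized loadings
        .83 are recovered to that mean loading."""
        n, lam = 5000, 0.83
        f = rng.standard_normal(n)
        X = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, 6))
        std_loadings, scores, model = fit_discipline_cfa(X)
        assert std_loadings.mean() == pytest.approx(0.83, abs=0.02)
        assert model.converged_ and not model.heywood_
        assert scores.mean() == pytest.approx(0.0, abs=0.02)
        # independent oracle: sklearn's ML factor analysis
        fa = FactorAnalysis(n_components=1, svd_method="lapack").fit(X)
        oracle = np.abs(fa.components_.ravel())
        np.testing.assert_allclose(np.abs(model.loadings_), oracle, atol=0.01)

    def test_three_indicator_closed_form(self, rng):
        """Minimal identified case: loadings match the closed-form solution
        lambda_1 = sqrt(s12*s13/s23) from the sample covariance."""
        n = 2000
        f = rng.standard_normal(n)
        lams = np.array([0.9, 0.7, 0.5])
        X = f[:, None] * lams + rng.standard_normal((n, 3)) * \
            np.array([0.4, 0.6, 0.8])
        model = OneFactorCFA().fit(X)
        S = np.cov(X.T, ddof=0)
        closed = np.array([
            np.sqrt(S[0, 1] * S[0, 2] / S[1, 2]),
            np.sqrt(S[0, 1] * S[1, 2] / S[0, 2]),
            np.sqrt(S[0, 2] * S[1, 2] / S[0, 1]),
        ])
        np.testing.assert_allclose(np.abs(model.loadings_), closed, atol=1e-3)

    def test_uncorrelated_items_flagged_degenerate(self, rng):
        X = rng.standard_normal((2000, 6))
        model = OneFactorCFA().fit(X)
        assert model.degenerate_
        assert np.mean(model.std_loadings_**2) < 0.05
        strong = OneFactorCFA().fit(
            0.83 * rng.standard_normal((2000, 1)) * np.ones(6)
            + 0.56 * rng.standard_normal((2000, 6)))
        assert not strong.degenerate_

    def test_scores_monotone_in_items(self, rng):
        """With positive loadings the regression-score weights are all
        positive, so raising any item raises the score."""
        n = 600
        f = rng.standard_normal(n)
        X = 0.8 * f[:, None] + 0.4 * rng.standard_normal((n, 6))
        _, scores, model = fit_discipline_cfa(X)
        lam, u = model.loadings_, model.uniquenesses_
        w = np.linalg.solve(np.outer(lam, lam) + np.diag(u), lam)
        assert np.all(w > 0)
        bumped = model.transform(X + np.eye(6)[0] * 0.5)
        assert np.all(bumped > scores)
        # and the score tracks the item sum closely for exchangeable items
        assert np.corrcoef(scores, X.sum(axis=1))[0, 1] > 0.99

    def test_handles_missing_items(self, rng):
        n = 1000
        f = rng.standard_normal(n)
        X = 0.83 * f[:, None] + 0.56 * rng.standard_normal((n, 6))
        X[rng.random((n, 6)) < 0.15] = np.nan
        model = OneFactorCFA().fit(X)
        assert model.converged_
        assert model.std_loadings_.mean() == pytest.approx(0.83, abs=0.05)
        scores = model.transform(X)
        assert np.isfinite(scores).mean() > 0.99

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            OneFactorCFA().fit(rng.standard_normal((10, 6)))


class TestCigaretteCoding:
    @pytest.mark.parametrize("raw,expected", [
        (0, 0), (0.5, 1), (1, 2), (5, 2), (6, 3), (10, 3), (11, 4),
        (15, 4), (16, 5), (19, 5), (20, 6), (25, 6),
    ])
    def test_bin_table(self, raw, expected):
        assert code_cigarettes(raw) == expected

    def test_monotone_over_exhaustive_sweep(self):
        raw = np.linspace(0, 40, 4001)
        coded = code_cigarettes(raw)
        assert np.all(np.diff(coded) >= 0)
        assert coded[0] == 0 and coded[-1] == 6

    def test_negative_rejected_and_custom_bins(self):
        with pytest.raises(ValueError, match="negative"):
            code_cigarettes(-1.0)
        assert code_cigarettes(3.0, upper_bounds=(0, 1, 2, 3, 4, 5)) == 3
        with pytest.raises(ValueError):
            code_cigarettes(1.0, upper_bounds=(0, 1, 1, 3, 4, 5))


class TestAttainmentResidualization:
    def test_uncorrelated_age_reduces_to_centering(self, rng):
        cat = rng.integers(1, 7, 500).astype(float)
        age = np.full(500, 0.0) + rng.normal(30, 3, 500)
        # re-draw categories independent of age; slope ~ 0 at large n
        resid = residualize_attainment(cat, age)
        assert resid.mean() == pytest.approx(0.0, abs=1e-10)

    def test_exact_linear_fit_gives_zero_residuals(self):
        resid = residualize_attainment([2, 4, 6], [20, 30, 40])
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_generated_age_attainment_correlation(self):
        """The categorical attainment variable correlates .27 with age at
        report under the default generator (attenuation-corrected)."""
        cfg = default_config(seed=21, n_families=30000)
        p = simulate_cohort(cfg).persons
        r = np.corrcoef(p.ea_age, p.ea_category)[0, 1]
        assert r == pytest.approx(0.27, abs=0.015)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            residualize_attainment([2, 4], [20, 30])
        with pytest.raises(ValueError, match="identical"):
            residualize_attainment([2, 4, 6], [30, 30, 30])


def test_build_composites_schema(small_cohort_missing):
    _, data = small_cohort_missing
    comp = build_composites(data)
    assert {"gpa_11", "motiv_teacher_17", "cigs_per_day_24",
            "ea_residual", "family_id"} <= set(comp.columns)
    cigs = comp[[c for c in comp.columns if c.startswith("cigs_per_day")]]
    vals = cigs.to_numpy().ravel()
    vals = vals[np.isfinite(vals)]
    assert set(np.unique(vals)) <= set(range(7))
    # attainment residual centered among observed
    assert np.nanmean(comp["ea_residual"]) == pytest.approx(0.0, abs=1e-8)


def test_mean_lag1_autocorrelations_in_published_range(big_cohort):
    """Mean lag-1 autocorrelation of each composite falls in the published
    .37-.69 span for the academic/smoking trait families."""
    from twinpath.reporting import lag1_correlations, \
        mean_lag1_autocorrelation
    _, data = big_cohort
    comp = build_composites(data)
    for trait in ("gpa", "motiv_sp", "motiv_teacher", "discipline",
                  "cigs_per_day"):
        cols = [c for c in comp.columns if c.startswith(trait + "_")
                and c.rsplit("_", 1)[1].isdigit()]
        mean_r = mean_lag1_autocorrelation(lag1_correlations(comp[cols]))
        assert 0.30 <= mean_r <= 0.75, trait
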