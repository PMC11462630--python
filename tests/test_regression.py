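"""QSPR linear-regression stage: fit statistics, model selection, prediction."""

import math

import numpy as np
import pytest

from moftopo import (
    family_fits,
    fit_linear,
    predict,
    property_table,
    published_descriptor,
    regression_report,
    round_half_up,
    select_optimal,
)

# printed regression equations for the NHC-TM lattice at k=1
# (slope, intercept, se, F); intercepts carry one-ulp printer noise and the
# printed F runs a few 0.01% below the exact OLS value
REFERENCE_EQUATIONS_K1 = {
    "M1": (0.224, 6.399, 0.721, 443554.09),
    "M2": (0.181, 10.264, 1.071, 201083.98),
    "F": (0.087, 11.058, 1.143, 176547.28),
    "HZ": (0.044, 10.669, 1.108, 187971.83),
    "ReZ3": (0.034, 16.093, 1.599, 90158.66),
    "BM": (0.100, 8.538, 0.915, 275689.91),
    "TM": (0.059, 10.800, 1.120, 183992.04),
    "BMH": (0.038, 13.734, 1.385, 120139.99),
    "TMH": (0.022, 16.683, 1.653, 84413.05),
}

# optimal k=3 first-Zagreb equations per family, as printed
OPTIMAL_EQUATIONS = {
    "TM-Pc": (0.168, 17.263),
    "MOAPc": (0.180, 7.747),
    "MBHT": (0.193, 5.781),
    "NHC-TM": (0.175, 7.925),
}

# predicted energies at (4,4) and (4,5) from the printed optimal equations
PREDICTED_LARGE = {
    ("TM-Pc", 4, 4): 988.303,
    ("TM-Pc", 4, 5): 1197.967,
    ("MOAPc", 4, 4): 1847.347,
    ("MOAPc", 4, 5): 2216.707,
    ("MBHT", 4, 4): 936.813,
    ("MBHT", 4, 5): 1132.129,
    ("NHC-TM", 4, 4): 1253.925,
    ("NHC-TM", 4, 5): 1504.525,
}


class TestFitLinear:
    def test_perfect_fit(self):
        x = [1.0, 2.0, 3.0, 4.0]
        fit = fit_linear(x, [2 * v + 1 for v in x])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.se == 0.0
        assert math.isinf(fit.f_stat) and fit.exact

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_linear([1, 2], [1, 2])
        with pytest.raises(ValueError):
            fit_linear([3, 3, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_linear([1, 1, 2, 2, 3, 3][:3], [5.0, 5.0])

    def test_ols_identities(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 100, 12)
        y = 3.1 * x + 2.0 + rng.normal(0, 4.0, 12)
        fit = fit_linear(x, y)
        resid = y - (fit.slope * x + fit.intercept)
        assert resid.sum() == pytest.approx(0.0, abs=1e-8)
        sse = float(resid @ resid)
        sst = float(((y - y.mean()) ** 2).sum())
        assert fit.r2 == pytest.approx(1 - sse / sst, rel=1e-12)
        assert fit.f_stat == pytest.approx(
            (fit.n_points - 2) * fit.r2 / (1 - fit.r2), rel=1e-9
        )
        assert fit.adj_r2 == pytest.approx(
            1 - (1 - fit.r2) * (fit.n_points - 1) / (fit.n_points - 2), rel=1e-12
        )
        # regression line passes through the mean point
        assert predict(fit, float(x.mean())) == pytest.approx(float(y.mean()))

    def test_matches_statsmodels(self, descriptor_table):
        """Independent cross-check of all fit statistics against OLS from
        statsmodels on a reference column."""
        sm = pytest.importorskip("statsmodels.api")
        sub = descriptor_table.query(
            "family == 'NHC-TM' and k == 1 and descriptor == 'M1'"
        ).sort_values(["m", "n"])
        x, y = sub["value"].to_numpy(float), sub["energy"].to_numpy(float)
        fit = fit_linear(x, y)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-10)
        assert fit.slope == pytest.approx(res.params[1], rel=1e-10)
        assert fit.r2 == pytest.approx(res.rsquared, rel=1e-10)
        assert fit.adj_r2 == pytest.approx(res.rsquared_adj, rel=1e-10)
        assert fit.f_stat == pytest.approx(res.fvalue, rel=1e-8)
        assert fit.se == pytest.approx(math.sqrt(res.mse_resid), rel=1e-10)

    def test_parameter_recovery(self):
        """Fits on y = a x + b + gaussian noise recover the truth within
        3 standard errors for the vast majority of seeds (the +-3 SE
        interval with a 4-df variance estimate covers ~96%; the threshold
        is 3 binomial sigma below that)."""
        a, b, sigma, n = 0.2, 7.0, 1.0, 6
        covered = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.uniform(500, 4000, n)
            y = a * x + b + rng.normal(0, sigma, n)
            fit = fit_linear(x, y)
            sxx = float(((x - x.mean()) ** 2).sum())
            se_slope = fit.se / math.sqrt(sxx)
            se_inter = fit.se * math.sqrt(1 / n + x.mean() ** 2 / sxx)
            covered += (
                abs(fit.slope - a) < 3 * se_slope
                and abs(fit.intercept - b) < 3 * se_inter
            )
        assert covered >= 35


class TestReferenceReplication:
    def test_reference_equations(self, descriptor_table):
        """Slope at 3 d.p.; intercept/se within one printed ulp; F within
        0.1% (the printed F-values carry more rounding noise)."""
        fits = family_fits(descriptor_table, "NHC-TM", 1)
        for name, (slope, intercept, se, f) in REFERENCE_EQUATIONS_K1.items():
            fit = fits[name]
            assert round_half_up(fit.slope, 3) == slope, name
            assert abs(fit.intercept - intercept) <= 1.5e-3, name
            assert abs(fit.se - se) <= 1.5e-3, name
            assert fit.f_stat == pytest.approx(f, rel=1e-3), name

    def test_optimal_equations(self, descriptor_table):
        for fam, (slope, intercept) in OPTIMAL_EQUATIONS.items():
            fit = family_fits(descriptor_table, fam, 3)["M1"]
            assert round_half_up(fit.slope, 3) == slope, fam
            assert abs(fit.intercept - intercept) <= 1.5e-3, fam

    def test_report_rounding(self, descriptor_table):
        rep = regression_report(descriptor_table, "NHC-TM", 1)
        assert rep.loc["M1", "slope"] == 0.224
        assert rep.loc["M1", "se"] == 0.721
        assert rep.loc["M1", "r"] == 1.0
        assert set(rep.index) == set(REFERENCE_EQUATIONS_K1)


class TestSelection:
    def test_first_zagreb_optimal_at_k1(self, descriptor_table):
        fits = family_fits(descriptor_table, "NHC-TM", 1)
        name, k, _ = select_optimal([(n, 1, f) for n, f in fits.items()])
        assert name == "M1"

    def test_k3_most_accurate_held_out_prediction(self):
        """The reference analysis adopts the k=3 first-Zagreb model after
        comparing held-out NHC-TM(1,4) predictions across k using the
        quoted equations: with the tabulated energy 503.356 as truth, k=3
        gives the smallest error.  (Ranking by F statistic alone does not
        single out k=3 — the tabulated fixtures put the k=1 or k=2 F
        higher for three of the four families — and the quoted k=2
        intercept carries a decimal-shift misprint, so this comparison is
        meaningful only at quoted precision.)"""
        actual = 503.356
        quoted = {1: (0.224, 6.399), 2: (0.169, -4.33), 3: (0.175, 7.925)}
        errors = {}
        for k, (a, b) in quoted.items():
            x = published_descriptor("NHC-TM", "M1", k, 1, 4)
            errors[k] = abs(a * x + b - actual)
        assert min(errors, key=errors.get) == 3

    def test_single_fit_and_empty(self):
        fit = fit_linear([1, 2, 3], [1.0, 2.1, 2.9])
        assert select_optimal([("F", 2, fit)]) == ("F", 2, fit)
        with pytest.raises(ValueError):
            select_optimal([])

    def test_tie_break_by_se_then_order(self):
        f_hi = fit_linear([1, 2, 3, 4], [2, 4, 6, 8.01])
        fits = [("TM", 1, f_hi), ("M2", 1, f_hi)]
        assert select_optimal(fits)[0] == "M2"  # enumeration order breaks tie


class TestPrediction:
    def test_rounded_coefficient_mode(self):
        fit = fit_linear([0, 1, 2, 3], [1.0, 2.2345, 3.469, 4.7035])
        assert predict(fit, 10, round_coefficients_to=3) == pytest.approx(
            round_half_up(fit.slope, 3) * 10 + round_half_up(fit.intercept, 3)
        )

    def test_large_lattice_predictions_from_own_fit(self, descriptor_table):
        """Predictions from our own 3-d.p.-rounded optimal fits agree with
        the printed predictions to within 0.002 x (one coefficient ulp)."""
        for (fam, m, n), expected in PREDICTED_LARGE.items():
            fit = family_fits(descriptor_table, fam, 3)["M1"]
            x = published_descriptor(fam, "M1", 3, m, n)
            got = predict(fit, x, round_coefficients_to=3)
            assert abs(got - expected) <= 0.002 * x / 1000 + 1e-9, (fam, m, n)

    def test_large_lattice_predictions_printed_equations(self):
        """Applying the quoted equations at printed precision reproduces
        every printed predicted energy exactly."""
        for (fam, m, n), expected in PREDICTED_LARGE.items():
            a, b = OPTIMAL_EQUATIONS[fam]
            x = published_descriptor(fam, "M1", 3, m, n)
            assert round_half_up(a * x + b, 3) == expected, (fam, m, n)

    def test_moderate_lattice_prediction_series(self, descriptor_table):
        """NHC-TM(1,4) predictions for k=1,2,3 match the printed
        comparison (k=2 uses its equation exactly as printed)."""
        for k, expected in [(1, 501.887), (3, 502.125)]:
            fit = family_fits(descriptor_table, "NHC-TM", k)["M1"]
            x = published_descriptor("NHC-TM", "M1", k, 1, 4)
            got = predict(fit, x, round_coefficients_to=3)
            assert abs(got - expected) <= 0.0025, k
        x2 = published_descriptor("NHC-TM", "M1", 2, 1, 4)
        assert x2 == 2976
        assert round_half_up(0.169 * x2 - 4.33, 3) == 498.614


class TestPropertyTable:
    def test_join_shape(self, descriptor_table):
        # 4 families x 6 dims x 3 k x 9 descriptors
        assert len(descriptor_table) == 4 * 6 * 3 * 9
        assert {"family", "m", "n", "k", "descriptor", "value", "energy"} <= set(
            descriptor_table.columns
        )

    def test_insufficient_rows_error(self, descriptor_table):
        small = descriptor_table[
            (descriptor_table["m"] == 1) & (descriptor_table["n"] == 1)
        ]
        with pytest.raises(ValueError):
            family_fits(small, "TM-Pc", 1)
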