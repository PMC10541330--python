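"""Cohort statistics: exact tests, robust regression, summaries, tables."""

from __future__ import annotations

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from hrfph import (
    DegenerateTableError,
    MissingDataError,
    ValidationError,
    build_table,
    fisher_exact,
    logistic_fit,
    robust_ols,
    summarize,
)
from hrfph.stats import round_half_away

from oracles import fisher_p_bruteforce, hc1_sandwich_se, hypergeom_p_closed_form, ols_normal_equations


class TestFisherExact:
    def test_symmetric_2x2_closed_form(self):
        # margins (4,4)/(4,4): tail mass 34/70 by direct hypergeometric sums
        assert fisher_exact([[3, 1], [1, 3]]) == pytest.approx(34 / 70, abs=1e-14)

    def test_all_zero_outcome_column_is_uninformative(self):
        assert fisher_exact([[5, 0], [7, 0]]) == 1.0

    def test_zero_total_table_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            fisher_exact([[0, 0], [0, 0]])

    def test_agrees_with_scipy_on_random_2x2(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            t = rng.integers(0, 15, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact(t) == pytest.approx(
                scipy.stats.fisher_exact(t)[1], abs=1e-10
            )

    def test_freeman_halton_matches_bruteforce_on_3x2(self):
        # the lung-malformation layout: counts (0, 2, 3) of (5, 65, 13)
        table = [[5, 0], [63, 2], [10, 3]]
        assert fisher_exact(table) == pytest.approx(fisher_p_bruteforce(table), abs=1e-12)

    def test_freeman_halton_matches_r_fisher_test(self, tmp_path):
        """Independent cross-check against R's fisher.test on an r x c table."""
        table = [[5, 0], [63, 2], [10, 3]]
        script = (
            "m <- matrix(c(5, 63, 10, 0, 2, 3), nrow = 3);"
            "cat(sprintf('%.12f', fisher.test(m)$p.value))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        assert fisher_exact(table) == pytest.approx(float(out.stdout), abs=1e-6)

    @given(
        cells=st.lists(st.integers(0, 6), min_size=6, max_size=6),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_invariant_under_row_and_column_permutation(self, cells):
        t = np.asarray(cells).reshape(3, 2)
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            t = t + 1
        p = fisher_exact(t)
        for perm in itertools.permutations(range(3)):
            assert fisher_exact(t[list(perm)]) == pytest.approx(p, abs=1e-12)
        assert fisher_exact(t[:, ::-1]) == pytest.approx(p, abs=1e-12)

    def test_guard_on_large_tables(self):
        with pytest.raises(ValidationError):
            fisher_exact([[400, 200], [300, 100]])


class TestRobustOLS:
    def test_perfect_fit_has_zero_residual_and_zero_robust_se(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = robust_ols(2.0 + 3.0 * x, x)
        assert fit.params["x1"] == pytest.approx(3.0, abs=1e-10)
        assert fit.bse["x1"] == pytest.approx(0.0, abs=1e-10)

    def test_coefficients_match_normal_equations(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        X = np.column_stack([np.ones_like(x), x])
        beta = ols_normal_equations(y, X)
        fit = robust_ols(y, x)
        assert fit.params["const"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.params["x1"] == pytest.approx(beta[1], abs=1e-10)

    def test_hc1_matches_hand_coded_sandwich(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        y = 1.0 + 0.5 * x + rng.normal(scale=np.abs(x) + 0.1, size=10)
        X = np.column_stack([np.ones_like(x), x])
        se = hc1_sandwich_se(y, X)
        fit = robust_ols(y, x)
        assert fit.bse["const"] == pytest.approx(se[0], rel=1e-10)
        assert fit.bse["x1"] == pytest.approx(se[1], rel=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        perm = rng.permutation(30)
        a, b = robust_ols(y, x), robust_ols(y[perm], x[perm])
        assert a.params["x1"] == pytest.approx(b.params["x1"], rel=1e-12)
        assert a.bse["x1"] == pytest.approx(b.bse["x1"], rel=1e-12)

    def test_rank_deficient_design_rejected(self):
        x = np.ones((10, 2))
        with pytest.raises(ValidationError):
            robust_ols(np.arange(10.0), x)

    def test_reduces_to_classical_se_under_homoskedasticity(self):
        """Balanced one-way design, equal variances: HC1 ~ classical OLS SEs."""
        rng = np.random.default_rng(3)
        reps = 200
        x = np.repeat([0.0, 1.0, 2.0], reps)
        y = 1.0 + 0.5 * x + rng.normal(scale=1.0, size=x.size)
        fit = robust_ols(y, x)
        import statsmodels.api as sm

        classical = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.bse["x1"] == pytest.approx(classical.bse[1], rel=0.15)

    def test_logistic_fit_is_flagged_non_exact(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-x))).astype(float)
        fit = logistic_fit(y, x)
        assert fit.exact is False and fit.method == "logit_ml"
        assert fit.params["x1"] > 0


class TestSummaries:
    def test_singleton_median_and_iqr(self):
        s = summarize([8.0], "continuous")
        assert (s["median"], s["q1"], s["q3"]) == (8.0, 8.0, 8.0)

    def test_even_n_median_midpoint(self):
        assert summarize([1, 2, 3, 4], "continuous")["median"] == 2.5

    def test_mortality_style_percent(self):
        s = summarize([True] * 14 + [False] * 69, "dichotomous")
        assert (s["count"], s["denominator"], s["percent"]) == (14, 83, 17)

    def test_all_missing_raises(self):
        with pytest.raises(MissingDataError):
            summarize([None, float("nan")], "continuous")

    @pytest.mark.parametrize("x, expected", [(0.5, 1), (1.4, 1), (2.5, 3), (76.92, 77), (6.02, 6)])
    def test_round_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestBuildTable:
    def test_unit_counts(self):
        records = [
            {"category": "MILD", "died": False},
            {"category": "MODERATE", "died": True},
            {"category": "SEVERE", "died": True},
        ]
        table = build_table(records, "died")
        assert table.counts == ((1, 0), (0, 1), (0, 1))
        assert table.row_totals == (1, 1, 1)
        assert table.col_totals == (1, 2)

    def test_fixture_death_ecls_row(self, fixture_records, config):
        from hrfph.stats import scored_frame

        frame = scored_frame(fixture_records, config)
        table = build_table(frame, "death_or_ecls")
        assert table.row_totals == (5, 65, 13)
        assert tuple(row[1] for row in table.counts) == (0, 12, 10)

    def test_missing_outcomes_are_excluded_and_counted(self):
        records = [
            {"category": "MILD", "los_days": 4.0},
            {"category": "MODERATE", "los_days": None},
        ]
        table = build_table(pd.DataFrame(records), "los_days")
        assert table.n_excluded == 1

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            build_table([], "died")

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValidationError):
            build_table([{"category": "MILD", "died": True}], "nonesuch")
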