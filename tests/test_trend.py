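"""Ne-table assembly, random-forest scoring, partial dependence, and
segmented breakpoint regression."""

import numpy as np
import pandas as pd
import pytest

from paleopop import (
    NeTable,
    assemble_ne_table,
    breakpoint_grid_oracle,
    fit_rf,
    omission_sensitivity,
    partial_dependence,
    segmented_fit,
)
from paleopop.trend import SegmentedFitError


def site_frames(n_sites=4, dates=None, fn=None):
    dates = np.arange(1760.0, 2001.0, 10.0) if dates is None else dates
    fn = fn or (lambda d, s: 100.0 + d - 1700.0)
    return {
        f"S{i}": pd.DataFrame({"date_CE": dates, "ne_median": fn(dates, i)})
        for i in range(n_sites)
    }


def toy_table(n_sites=4, dates=None, fn=None) -> NeTable:
    return assemble_ne_table(site_frames(n_sites, dates, fn))


class TestAssembleNeTable:
    def test_row_count(self):
        dates = np.linspace(1750, 2000, 100)
        table = assemble_ne_table(site_frames(4, dates))
        assert len(table.data) == 400

    def test_clips_dates_before_1750(self):
        dates = np.arange(1700.0, 2001.0, 50.0)
        table = assemble_ne_table(site_frames(2, dates))
        assert table.data["date_CE"].min() >= 1750.0

    def test_covariate_mean_imputation_exact(self):
        frames = site_frames(2)
        dates = frames["S0"]["date_CE"]
        cov = {
            "S0": pd.DataFrame({"date_CE": dates, "thg": np.arange(len(dates), dtype=float)}),
            # S1 has no measurements at all -> fully imputed
            "S1": pd.DataFrame({"date_CE": [], "thg": []}),
        }
        table = assemble_ne_table(frames, covariates=cov)
        observed_mean = np.arange(len(dates), dtype=float).mean()
        s1 = table.data[table.data["site_id"] == "S1"]
        assert np.allclose(s1["thg_covariate"], observed_mean)

    def test_duplicate_site_date_rejected(self):
        df = pd.DataFrame(
            {"site_id": ["A", "A"], "date_CE": [1800.0, 1800.0], "ne_median": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="duplicated"):
            NeTable(df)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            assemble_ne_table({})


class TestFitRF:
    def test_learnable_date_signal(self):
        table = toy_table(fn=lambda d, s: 10.0 ** (1 + (d - 1700) / 300))
        report = fit_rf(table, n_trees=100, n_splits=10, seed=0)
        assert report.mean_score >= 0.95

    def test_pure_noise_scores_low(self):
        rng = np.random.default_rng(0)
        table = toy_table(fn=lambda d, s: 10.0 ** rng.normal(size=len(d)))
        report = fit_rf(table, n_trees=100, n_splits=10, seed=0)
        assert report.mean_score <= 0.1

    def test_same_seed_reproducible(self):
        table = toy_table()
        a = fit_rf(table, n_trees=50, seed=3)
        b = fit_rf(table, n_trees=50, seed=3)
        assert np.array_equal(a.scores, b.scores)
        for ta, tb in zip(a.test_indices, b.test_indices):
            assert np.array_equal(ta, tb)

    def test_splits_stratified_by_site(self):
        table = toy_table(n_sites=3)
        report = fit_rf(table, n_trees=20, n_splits=5, seed=1)
        n_per_site = len(table.data) // 3
        expected_test = max(int(round(0.2 * n_per_site)), 1)
        for te in report.test_indices:
            sites = table.data.iloc[te]["site_id"]
            assert all(count == expected_test for count in sites.value_counts())

    def test_small_site_triggers_global_fallback(self):
        frames = site_frames(2)
        frames["tiny"] = pd.DataFrame(
            {"date_CE": [1800.0, 1900.0], "ne_median": [10.0, 20.0]}
        )
        table = assemble_ne_table(frames)
        with pytest.warns(RuntimeWarning, match="global split"):
            fit_rf(table, n_trees=10, n_splits=2, seed=0)

    def test_log_scale_rejects_nonpositive_ne(self):
        table = toy_table(fn=lambda d, s: np.zeros(len(d)))
        with pytest.raises(ValueError, match="log"):
            fit_rf(table, n_trees=10)


class TestPartialDependence:
    def test_constant_model_flat_pd(self):
        table = toy_table(fn=lambda d, s: np.full(len(d), 100.0))
        report = fit_rf(table, n_trees=20, seed=0)
        curve = partial_dependence(report, "date")
        assert np.allclose(curve.values, curve.values[0])

    def test_additive_model_recovered_up_to_constant(self):
        # y = g(date) + h(site) on the log10 scale: PD(date) = g + const
        def fn(d, s):
            return 10.0 ** ((d - 1700.0) / 100.0 + 0.3 * s)

        table = toy_table(n_sites=3, fn=fn)
        report = fit_rf(table, n_trees=200, seed=1)
        grid = np.sort(table.data["date_CE"].unique())[3:-3]  # avoid edge bias
        curve = partial_dependence(report, "date", grid=grid)
        g = (grid - 1700.0) / 100.0
        dev = (curve.values - curve.values.mean()) - (g - g.mean())
        assert np.max(np.abs(dev)) < 0.05

    def test_matches_brute_force_on_toy(self):
        table = toy_table(n_sites=2, dates=np.arange(1800.0, 1850.0, 10.0))
        report = fit_rf(table, n_trees=30, seed=2)
        grid = np.array([1810.0, 1830.0])
        curve = partial_dependence(report, "date", grid=grid)
        col = report.feature_columns.index("date")
        manual = np.zeros((len(report.models), len(grid)))
        for mi, (model, tr) in enumerate(zip(report.models, report.train_indices)):
            base = report.design.to_numpy(dtype=float)[tr]
            for gi, g in enumerate(grid):
                rows = base.copy()
                rows[:, col] = g
                manual[mi, gi] = model.predict(rows).mean()
        assert np.allclose(curve.values, manual.mean(axis=0))

    def test_unknown_predictor_rejected(self):
        report = fit_rf(toy_table(), n_trees=10, seed=0)
        with pytest.raises(ValueError, match="unknown predictor"):
            partial_dependence(report, "depth")


class TestOmissionSensitivity:
    def test_date_only_signal_collapses_without_date(self):
        table = toy_table(fn=lambda d, s: 10.0 ** (1 + (d - 1700) / 300))
        res = omission_sensitivity(table, "date", n_trees=100, seed=0)
        assert res["pseudo_r2_full"] >= 0.9
        assert res["pseudo_r2_omitted"] <= 0.1

    def test_site_only_signal_insensitive_to_date(self):
        table = toy_table(n_sites=4, fn=lambda d, s: np.full(len(d), 10.0 ** (1 + s)))
        res = omission_sensitivity(table, "date", n_trees=100, seed=0)
        assert abs(res["delta"]) < 0.05

    def test_omitting_only_predictor_rejected(self):
        table = toy_table()
        with pytest.raises(ValueError):
            omission_sensitivity(table, "date", predictors=("date",))


def two_segment(x, psi, b0, s1, s2, noise=0.0, rng=None):
    y = b0 + s1 * (x - x[0]) + np.clip(x - psi, 0, None) * (s2 - s1)
    if noise:
        y = y + rng.normal(0, noise, size=len(x))
    return y


class TestSegmentedFit:
    x = np.arange(1750.0, 2011.0, 2.0)

    def test_exact_on_noiseless_piecewise_linear(self):
        y = np.where(self.x < 1800, 0.0, 0.1 * (self.x - 1800))
        fit = segmented_fit((self.x, y), start=1810.0)
        assert fit.psi == pytest.approx(1800.0, abs=1e-6)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope_left == pytest.approx(0.0, abs=1e-12)
        assert fit.slope_right == pytest.approx(0.1, abs=1e-10)

    def test_constructed_breakpoint_1784(self):
        y = two_segment(self.x, 1784.0, 5.0, 0.01, 0.1)
        fit = segmented_fit((self.x, y), start=1800.0)
        assert abs(fit.psi - 1784.0) <= 2.0  # within grid resolution

    def test_ci_coverage_under_gaussian_noise(self):
        """99% delta-method CI covers the true breakpoint in >= 97% of 500
        noisy replicates."""
        rng = np.random.default_rng(12)
        psi_true = 1880.0
        hits = runs = 0
        for _ in range(500):
            y = two_segment(self.x, psi_true, 1.0, 0.0, 0.02, noise=0.1, rng=rng)
            try:
                fit = segmented_fit((self.x, y), start=1850.0, ci_level=0.99)
            except SegmentedFitError:
                continue
            runs += 1
            hits += fit.ci[0] <= psi_true <= fit.ci[1]
        assert runs >= 490
        assert hits >= 0.97 * runs

    def test_agrees_with_grid_oracle_on_noisy_instances(self):
        rng = np.random.default_rng(13)
        step = self.x[1] - self.x[0]
        agree = 0
        for _ in range(100):
            psi_true = rng.uniform(1800, 1950)
            y = two_segment(self.x, psi_true, 0.0, 0.0, 0.05, noise=0.05, rng=rng)
            fit = segmented_fit((self.x, y), start=1870.0)
            psi_oracle = breakpoint_grid_oracle((self.x, y))
            agree += abs(fit.psi - psi_oracle) <= step
        assert agree == 100

    def test_flat_data_gives_no_credible_sharp_breakpoint(self):
        """Pure noise must not produce a reportable breakpoint: each of 20
        seeds either fails to converge, or yields a wide CI (> 50% of the
        range), or explains essentially nothing (adjusted R^2 < 0.5) --
        never a sharp, well-supported break."""
        rng = np.random.default_rng(14)
        span = self.x[-1] - self.x[0]
        for _ in range(20):
            y = rng.normal(0, 1.0, size=len(self.x))
            try:
                fit = segmented_fit((self.x, y), start=1880.0, ci_level=0.99)
            except (SegmentedFitError, ValueError):
                continue
            sharp = fit.ci[1] - fit.ci[0] <= 0.5 * span
            credible = fit.adj_r2 >= 0.5
            assert not (sharp and credible)

    def test_bootstrap_ci_contains_point_estimate(self):
        rng = np.random.default_rng(15)
        y = two_segment(self.x, 1850.0, 0.0, 0.0, 0.05, noise=0.03, rng=rng)
        fit = segmented_fit((self.x, y), start=1850.0, ci_method="bootstrap", n_boot=199)
        assert fit.ci[0] <= fit.psi <= fit.ci[1]

    def test_start_outside_range_rejected(self):
        y = two_segment(self.x, 1850.0, 0.0, 0.0, 0.05)
        with pytest.raises(ValueError, match="outside"):
            segmented_fit((self.x, y), start=2500.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            segmented_fit((self.x[:5], np.zeros(5)), start=1755.0)


class TestGridOracle:
    def test_unique_interior_break_found(self):
        x = np.arange(0.0, 101.0, 1.0)
        y = np.clip(x - 40.0, 0, None)
        assert breakpoint_grid_oracle((x, y)) == 40.0

    def test_monotone_data_tie_goes_to_earliest(self):
        x = np.arange(0.0, 21.0, 1.0)
        y = 2.0 * x  # single line: every candidate fits exactly
        assert breakpoint_grid_oracle((x, y)) == x[1]
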