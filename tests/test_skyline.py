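"""Skyline inference: interval bookkeeping, likelihood oracles, MCMC checks."""

import numpy as np
import pytest
from scipy.integrate import quad

from paleopop import (
    PiecewiseNe,
    SamplingDesign,
    SkylineConfig,
    TimedTree,
    classic_skyline,
    coalescent_intervals,
    coalescent_loglik,
    fit_bayesian_skyline,
    make_ne_trajectory,
    simulate_genealogy,
    summarize_trajectory,
)
from paleopop.skyline import CoalescentIntervals, hpd_interval


def two_tip_tree(tau: float = 10.0) -> TimedTree:
    return TimedTree.from_newick(
        f"(A:{tau},B:{tau});", 2000.0, {"A": 2000.0, "B": 2000.0}
    )


def three_tip_serial_tree() -> TimedTree:
    # 2 tips at height 0, 1 at height 5; coalescences at heights 3 and 8
    newick = "((A:3,B:3):5,C:3);"
    return TimedTree.from_newick(newick, 2000.0, {"A": 2000.0, "B": 2000.0, "C": 1995.0})


class TestCoalescentIntervals:
    def test_two_tip_single_interval(self):
        iv = coalescent_intervals(two_tip_tree(10.0))
        assert len(iv.lengths) == 1
        assert iv.lengths[0] == pytest.approx(10.0)
        assert iv.k[0] == 2 and iv.events == ("coalescence",)

    def test_hand_traced_serial_sample(self):
        iv = coalescent_intervals(three_tip_serial_tree())
        assert np.allclose(iv.lengths, [3, 2, 3])
        assert list(iv.k) == [2, 1, 2]
        assert iv.events == ("coalescence", "sampling", "coalescence")

    def test_interval_lengths_sum_to_root_height(self, constant_traj):
        rng = np.random.default_rng(17)
        design = SamplingDesign("S", ((2000.0, 8), (1950.0, 4), (1800.0, 4)))
        for _ in range(5):
            tree = simulate_genealogy(design, constant_traj, rng)
            iv = coalescent_intervals(tree)
            assert iv.lengths.sum() == pytest.approx(tree.root_height, rel=1e-9)


class TestClassicSkyline:
    def test_closed_form_values(self):
        iv = CoalescentIntervals(
            lengths=np.array([10.0, 1.0, 0.0]),
            k=np.array([2, 5, 3]),
            events=("coalescence", "coalescence", "coalescence"),
            end_heights=np.array([10.0, 11.0, 11.0]),
        )
        est = classic_skyline(iv)["ne_hat"].tolist()
        assert est == [10.0, 10.0, 0.0]  # k(k-1)w/2


class TestCoalescentLoglik:
    def test_two_tip_constant_ne_closed_form(self):
        iv = coalescent_intervals(two_tip_tree(10.0))
        ll = coalescent_loglik(iv, PiecewiseNe.constant(10.0))
        assert ll == pytest.approx(-np.log(10) - 1.0, abs=1e-12)

    def test_doubling_ne_short_interval_limit(self):
        # as tau -> 0 the density ratio tends to exactly 1/2
        iv = coalescent_intervals(two_tip_tree(1e-9))
        delta = coalescent_loglik(iv, PiecewiseNe.constant(2.0)) - coalescent_loglik(
            iv, PiecewiseNe.constant(1.0)
        )
        assert delta == pytest.approx(-np.log(2.0), abs=1e-8)

    def test_mle_over_constant_ne_is_classic_estimate(self):
        iv = coalescent_intervals(two_tip_tree(7.0))
        classic = classic_skyline(iv)["ne_hat"].iloc[0]
        grid = np.linspace(0.5 * classic, 2 * classic, 2001)
        lls = [coalescent_loglik(iv, PiecewiseNe.constant(v)) for v in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(classic, rel=1e-3)

    def test_agrees_with_quadrature_oracle_on_random_piecewise(self, constant_traj):
        rng = np.random.default_rng(4)
        design = SamplingDesign("S", ((2000.0, 6), (1900.0, 4)))
        for _ in range(5):
            tree = simulate_genealogy(design, constant_traj, rng)
            iv = coalescent_intervals(tree)
            bounds = np.sort(rng.uniform(0, tree.root_height, size=3))
            values = rng.uniform(50, 5000, size=4)
            pw = PiecewiseNe(bounds, values)

            def inv_ne(h):
                return 1.0 / pw.at(h)

            oracle = 0.0
            for w, k, ev, h in zip(iv.lengths, iv.k, iv.events, iv.end_heights):
                if k >= 2 and w > 0:
                    integral, _ = quad(
                        inv_ne, h - w, h, points=list(bounds), limit=200,
                        epsabs=1e-13, epsrel=1e-13,
                    )
                    oracle -= k * (k - 1) / 2.0 * integral
                if ev == "coalescence":
                    oracle -= np.log(pw.at(h))
            assert coalescent_loglik(iv, pw) == pytest.approx(oracle, abs=1e-8)

    def test_nonpositive_ne_rejected(self):
        with pytest.raises(ValueError):
            PiecewiseNe(np.array([]), np.array([0.0]))


class TestBayesianSkyline:
    def test_same_seed_identical_draws(self, fifty_tip_tree):
        cfg = SkylineConfig(n_groups=5, chain_length=5000, thinning=5, seed=3)
        a = fit_bayesian_skyline(fifty_tip_tree, cfg)
        b = fit_bayesian_skyline(fifty_tip_tree, cfg)
        assert np.array_equal(a.draws, b.draws)

    def test_constant_truth_coverage_and_accuracy(self, constant_traj):
        """20 trees from Ne=1000: group medians within a factor 2 of the
        truth in >= 85% of cases and per-group 95% HPD coverage >= 85%
        (5 groups x 20 replicate fits; simultaneous all-group coverage
        would only be ~0.95^5)."""
        rng = np.random.default_rng(8)
        design = SamplingDesign("S", ((2000.0, 50),))
        trees = [simulate_genealogy(design, constant_traj, rng) for _ in range(20)]
        covered = within2 = total = 0
        for rep in range(20):
            cfg = SkylineConfig(n_groups=5, chain_length=20_000, thinning=10, seed=rep)
            post = fit_bayesian_skyline([trees[rep]], cfg)
            med = np.median(post.draws, axis=0)
            for g in range(post.n_groups):
                lo, hi = hpd_interval(post.draws[:, g])
                covered += lo <= 1000.0 <= hi
                within2 += 500.0 <= med[g] <= 2000.0
                total += 1
        assert covered >= 0.85 * total
        assert within2 >= 0.85 * total
        # pooled fit: strong accuracy with all 20 trees
        cfg = SkylineConfig(n_groups=5, chain_length=20_000, thinning=10, seed=0)
        pooled = fit_bayesian_skyline(trees, cfg)
        med = np.median(pooled.draws, axis=0)
        assert np.all(med > 500) and np.all(med < 2000)

    def test_group_medians_track_classic_skyline(self, fifty_tip_tree):
        """m = number of events: posterior group medians correlate with the
        per-interval classic estimates (Spearman >= 0.8)."""
        from scipy.stats import spearmanr

        iv = coalescent_intervals(fifty_tip_tree)
        cfg = SkylineConfig(
            n_groups=iv.n_coalescences, chain_length=200_000, thinning=20, seed=5
        )
        post = fit_bayesian_skyline(fifty_tip_tree, cfg)
        classic = classic_skyline(iv).sort_values("height")["ne_hat"].to_numpy()
        med = np.median(post.draws, axis=0)
        rho = spearmanr(classic, med).statistic
        assert rho >= 0.8

    def test_posterior_matches_grid_integration_on_toy(self):
        """Empirical detailed balance: the 2-group toy posterior agrees
        with dense grid integration (total variation < 0.05)."""
        tree = three_tip_serial_tree()
        cfg = SkylineConfig(n_groups=2, chain_length=100_000, thinning=5, seed=9)
        post = fit_bayesian_skyline(tree, cfg)
        # both groups carry sufficient statistics c=1, A=3 and a log-uniform
        # prior on [1e-3 s, 1e3 s] with s = 3 (median classic estimate)
        lo, hi = np.log(3e-3), np.log(3e3)
        grid = np.linspace(lo, hi, 4001)
        for g in range(2):
            log_draws = np.log(post.draws[:, g])
            dens = np.exp(-1.0 * grid - 3.0 * np.exp(-grid))
            dens /= np.trapezoid(dens, grid)
            bins = np.linspace(lo, hi, 26)
            p_mcmc, _ = np.histogram(log_draws, bins=bins, density=False)
            p_mcmc = p_mcmc / p_mcmc.sum()
            cdf = np.interp(bins, grid, np.concatenate([[0], np.cumsum(np.diff(grid) * 0.5 * (dens[1:] + dens[:-1]))]))
            p_exact = np.diff(cdf)
            p_exact /= p_exact.sum()
            tv = 0.5 * np.abs(p_mcmc - p_exact).sum()
            assert tv < 0.05

    def test_more_trees_shrink_hpd_widths(self, constant_traj):
        rng = np.random.default_rng(10)
        design = SamplingDesign("S", ((2000.0, 30),))
        trees = [simulate_genealogy(design, constant_traj, rng) for _ in range(12)]
        widths = []
        for n in (2, 12):
            cfg = SkylineConfig(n_groups=4, chain_length=20_000, thinning=10, seed=1)
            post = fit_bayesian_skyline(trees[:n], cfg)
            hpds = [hpd_interval(post.draws[:, g]) for g in range(post.n_groups)]
            widths.append(np.mean([np.log(hi / lo) for lo, hi in hpds]))
        assert widths[1] < widths[0]

    def test_too_many_groups_rejected(self):
        tree = two_tip_tree()
        with pytest.raises(ValueError):
            fit_bayesian_skyline(tree, SkylineConfig(n_groups=5, chain_length=100))

    def test_sigmoidal_increase_located_by_median_slope(self):
        """10-fold sigmoidal increase at 1784: the steepest 30-yr rise of
        the summarised median trajectory falls within +-20 yr of the truth
        in >= 80% of seeded replicates."""
        traj = make_ne_trajectory(
            "sigmoidal_breakpoint", base_ne=100, fold_change=10,
            breakpoint_date=1784, steepness=0.2,
        )
        design = SamplingDesign("S", tuple((2010.0 - 50.0 * j, 10) for j in range(6)))
        rng = np.random.default_rng(11)
        hits = 0
        n_rep, lag = 20, 15  # 30-yr centred slope on a 2-yr grid
        for rep in range(n_rep):
            tree = simulate_genealogy(design, traj, rng)
            cfg = SkylineConfig(n_groups=25, chain_length=40_000, thinning=10, seed=rep)
            post = fit_bayesian_skyline(tree, cfg)
            lo = max(2010.0 - tree.root_height, 1750.0)
            grid = np.arange(np.ceil(lo / 2) * 2, 2010.1, 2.0)
            summ = summarize_trajectory(post, grid)
            y = np.log10(summ["ne_median"].to_numpy())
            x = summ["date_CE"].to_numpy()
            slope = (y[2 * lag:] - y[:-2 * lag]) / (x[2 * lag:] - x[:-2 * lag])
            hits += abs(x[lag:-lag][np.argmax(slope)] - 1784.0) <= 20.0
        assert hits >= int(0.8 * n_rep)


class TestSummarizeTrajectory:
    def test_flat_draws_give_flat_median(self, fifty_tip_tree):
        cfg = SkylineConfig(n_groups=3, chain_length=5000, thinning=5, seed=2)
        post = fit_bayesian_skyline(fifty_tip_tree, cfg)
        post.draws[:] = 123.0
        summ = summarize_trajectory(post, np.linspace(1500, 2000, 20))
        assert np.all(summ["ne_median"] == 123.0)
        assert np.all(summ["hpd_lo"] == 123.0) and np.all(summ["hpd_hi"] == 123.0)

    def test_single_date_grid(self, fifty_tip_tree):
        cfg = SkylineConfig(n_groups=3, chain_length=5000, thinning=5, seed=2)
        post = fit_bayesian_skyline(fifty_tip_tree, cfg)
        summ = summarize_trajectory(post, [1990.0])
        assert len(summ) == 1 and {"ne_median", "hpd_lo", "hpd_hi"} <= set(summ)

    def test_grid_outside_span_rejected(self, fifty_tip_tree):
        cfg = SkylineConfig(n_groups=3, chain_length=5000, thinning=5, seed=2)
        post = fit_bayesian_skyline(fifty_tip_tree, cfg)
        with pytest.raises(ValueError, match="span"):
            summarize_trajectory(post, [2050.0])

    def test_median_changes_only_at_group_boundaries(self, fifty_tip_tree):
        cfg = SkylineConfig(n_groups=4, chain_length=5000, thinning=5, seed=2)
        post = fit_bayesian_skyline(fifty_tip_tree, cfg)
        # freeze draws to a deterministic step function over groups
        post.draws[:] = np.arange(1, post.n_groups + 1) * 100.0
        grid = np.linspace(2000.0 - post.group_edges[-1] + 1e-6, 2000.0, 200)
        summ = summarize_trajectory(post, grid)
        changes = np.flatnonzero(np.diff(summ["ne_median"].to_numpy()) != 0)
        change_dates = summ["date_CE"].to_numpy()[changes]
        boundary_dates = 2000.0 - post.group_edges[1:-1]
        for cd in change_dates:
            assert np.min(np.abs(boundary_dates - cd)) < (grid[1] - grid[0]) + 1e-9
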