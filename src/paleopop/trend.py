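"""Multi-site Ne trend modelling and breakpoint dating.

The per-site skyline summaries are assembled into a long table of
(site, date, median Ne), modelled with random-forest regressions of Ne on
date and site over ten stratified 80/20 train/test splits, reduced to the
partial dependence of the prediction on calendar date, and finally dated
with a single-breakpoint segmented regression (iterative-linearisation
fit with a delta-method confidence interval for the breakpoint), plus an
exhaustive profile-search oracle used for verification.

The random forest itself comes from scikit-learn; splitting, the held-out
pseudo-R^2 (1 - SSE/SST on test rows), partial dependence, the omission
sensitivity analysis, and the segmented regression are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "NeTable",
    "RFRunReport",
    "PartialDependenceCurve",
    "BreakpointFit",
    "SegmentedFitError",
    "assemble_ne_table",
    "fit_rf",
    "partial_dependence",
    "omission_sensitivity",
    "segmented_fit",
    "breakpoint_grid_oracle",
]

DATE_FLOOR = 1750.0


@dataclass
class NeTable:
    """Long-format (site_id, date_CE, ne_median [, thg_covariate]) table."""

    data: pd.DataFrame
    date_floor: float = DATE_FLOOR

    def __post_init__(self) -> None:
        required = {"site_id", "date_CE", "ne_median"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"NeTable lacks columns {sorted(missing)}")
        if self.data.duplicated(["site_id", "date_CE"]).any():
            raise ValueError("duplicated (site, date) rows in NeTable")

    @property
    def sites(self) -> list[str]:
        return sorted(self.data["site_id"].unique())


def assemble_ne_table(
    per_site: dict[str, pd.DataFrame],
    grid=None,
    covariates: dict[str, pd.DataFrame] | None = None,
    date_floor: float = DATE_FLOOR,
) -> NeTable:
    """Stack per-site trajectory summaries into one modelling table.

    Parameters
    ----------
    per_site
        site_id -> DataFrame with columns ``date_CE`` and ``ne_median``
        (the output of skyline summarisation).
    grid
        Optional calendar grid to which each site is restricted.
    covariates
        Optional site_id -> DataFrame(date_CE, thg) of sediment total
        mercury; missing values are imputed by the overall mean of the
        observed values.
    date_floor
        Dates earlier than this (default 1750 CE, the extrapolation floor
        of the age-depth models) are dropped.
    """
    if not per_site:
        raise ValueError("no per-site trajectories supplied")
    frames = []
    for site, df in per_site.items():
        sub = df[["date_CE", "ne_median"]].copy()
        if grid is not None:
            sub = sub[sub["date_CE"].isin(np.asarray(grid, dtype=float))]
        sub = sub[sub["date_CE"] >= date_floor]
        sub.insert(0, "site_id", site)
        if covariates and site in covariates:
            cov = covariates[site].rename(columns={covariates[site].columns[-1]: "thg_covariate"})
            sub = sub.merge(cov, on="date_CE", how="left")
        frames.append(sub)
    table = pd.concat(frames, ignore_index=True)
    if covariates:
        if "thg_covariate" not in table.columns:
            table["thg_covariate"] = np.nan
        mean = table["thg_covariate"].mean()
        table["thg_covariate"] = table["thg_covariate"].fillna(mean)
    return NeTable(table, date_floor=date_floor)


@dataclass
class RFRunReport:
    """Fitted random-forest models with their stratified splits and scores."""

    models: list[RandomForestRegressor]
    train_indices: list[np.ndarray]
    test_indices: list[np.ndarray]
    scores: np.ndarray  # per-split held-out pseudo-R^2
    feature_columns: list[str]
    design: pd.DataFrame  # encoded predictor matrix (all rows)
    response: np.ndarray  # possibly log10-transformed
    response_scale: str
    predictors: tuple[str, ...]

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))


def _encode(table: NeTable, predictors: tuple[str, ...]) -> tuple[pd.DataFrame, list[str]]:
    cols = []
    frames = []
    df = table.data
    if "date" in predictors:
        frames.append(df[["date_CE"]].rename(columns={"date_CE": "date"}))
        cols.append("date")
    if "site" in predictors:
        onehot = pd.get_dummies(df["site_id"], prefix="site", dtype=float)
        frames.append(onehot)
        cols.extend(onehot.columns)
    if "thg" in predictors:
        if "thg_covariate" not in df.columns:
            raise ValueError("table has no thg_covariate column")
        frames.append(df[["thg_covariate"]])
        cols.append("thg_covariate")
    if not frames:
        raise ValueError("no predictors left to fit")
    design = pd.concat(frames, axis=1)
    return design, cols


def _stratified_splits(
    table: NeTable, n_splits: int, test_frac: float, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    df = table.data
    site_rows = {s: np.flatnonzero((df["site_id"] == s).to_numpy()) for s in table.sites}
    small = [s for s, r in site_rows.items() if len(r) < 5]
    train_sets, test_sets = [], []
    for _ in range(n_splits):
        if small:
            warnings.warn(
                f"sites {small} have < 5 rows; falling back to a global split",
                RuntimeWarning,
                stacklevel=3,
            )
            perm = rng.permutation(len(df))
            n_test = max(int(round(test_frac * len(df))), 1)
            test = np.sort(perm[:n_test])
        else:
            parts = []
            for s, rows in site_rows.items():
                perm = rng.permutation(rows)
                n_test = max(int(round(test_frac * len(rows))), 1)
                parts.append(perm[:n_test])
            test = np.sort(np.concatenate(parts))
        mask = np.ones(len(df), dtype=bool)
        mask[test] = False
        train_sets.append(np.flatnonzero(mask))
        test_sets.append(test)
    return train_sets, test_sets


def fit_rf(
    table: NeTable,
    n_trees: int = 5000,
    n_splits: int = 10,
    test_frac: float = 0.2,
    seed: int = 0,
    response_scale: str = "log10",
    predictors: tuple[str, ...] = ("date", "site"),
) -> RFRunReport:
    """Random forests of (transformed) median Ne on date and site.

    Each of ``n_splits`` random splits holds out ``test_frac`` of every
    site's rows (stratified, mirroring the class balance among sites);
    pseudo-R^2 = 1 - SSE/SST is computed on the held-out rows.
    """
    if response_scale not in ("log10", "natural"):
        raise ValueError("response_scale must be 'log10' or 'natural'")
    design, cols = _encode(table, predictors)
    y = table.data["ne_median"].to_numpy(dtype=float)
    if response_scale == "log10":
        if np.any(y <= 0):
            raise ValueError("non-positive Ne cannot be log-transformed")
        y = np.log10(y)

    rng = np.random.default_rng(seed)
    train_sets, test_sets = _stratified_splits(table, n_splits, test_frac, rng)
    models, scores = [], []
    x = design.to_numpy(dtype=float)
    for si, (tr, te) in enumerate(zip(train_sets, test_sets)):
        model = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        model.fit(x[tr], y[tr])
        pred = model.predict(x[te])
        sse = float(np.sum((y[te] - pred) ** 2))
        sst = float(np.sum((y[te] - np.mean(y[te])) ** 2))
        scores.append(1.0 - sse / sst if sst > 0 else 0.0)
        models.append(model)
    return RFRunReport(
        models=models,
        train_indices=train_sets,
        test_indices=test_sets,
        scores=np.asarray(scores),
        feature_columns=cols,
        design=design,
        response=y,
        response_scale=response_scale,
        predictors=predictors,
    )


@dataclass
class PartialDependenceCurve:
    """Averaged model prediction as the date predictor sweeps a grid."""

    grid: np.ndarray
    values: np.ndarray  # averaged over rows and models
    per_model: np.ndarray = field(default=None)  # (n_models, len(grid))

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("PD grid must be strictly increasing")


def partial_dependence(
    report: RFRunReport, predictor: str = "date", grid=None
) -> PartialDependenceCurve:
    """True partial dependence: average prediction over the empirical joint
    distribution of the remaining predictors (each model's training rows),
    then across models."""
    if predictor not in report.feature_columns:
        raise ValueError(f"unknown predictor {predictor!r}")
    col = report.feature_columns.index(predictor)
    x_all = report.design.to_numpy(dtype=float)
    if grid is None:
        grid = np.unique(x_all[:, col])
    grid = np.asarray(grid, dtype=float)
    per_model = np.empty((len(report.models), len(grid)))
    for mi, (model, tr) in enumerate(zip(report.models, report.train_indices)):
        base = x_all[tr]
        # one batched predict call: rows tiled over the grid values
        stacked = np.repeat(base, len(grid), axis=0)
        stacked[:, col] = np.tile(grid, len(base))
        pred = model.predict(stacked).reshape(len(base), len(grid))
        per_model[mi] = pred.mean(axis=0)
    return PartialDependenceCurve(grid=grid, values=per_model.mean(axis=0), per_model=per_model)


def omission_sensitivity(
    table: NeTable,
    predictor: str = "date",
    n_trees: int = 5000,
    n_splits: int = 10,
    test_frac: float = 0.2,
    seed: int = 0,
    response_scale: str = "log10",
    predictors: tuple[str, ...] = ("date", "site"),
) -> dict[str, float]:
    """Mean held-out pseudo-R^2 with and without one predictor."""
    if predictor not in predictors:
        raise ValueError(f"{predictor!r} is not among the predictors {predictors}")
    reduced = tuple(p for p in predictors if p != predictor)
    if not reduced:
        raise ValueError("cannot omit the only predictor")
    full = fit_rf(table, n_trees, n_splits, test_frac, seed, response_scale, predictors)
    part = fit_rf(table, n_trees, n_splits, test_frac, seed, response_scale, reduced)
    return {
        "pseudo_r2_full": full.mean_score,
        "pseudo_r2_omitted": part.mean_score,
        "delta": full.mean_score - part.mean_score,
    }


class SegmentedFitError(RuntimeError):
    """Raised when the segmented regression fails; carries the trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = list(trace)


@dataclass(frozen=True)
class BreakpointFit:
    """Two-segment linear fit: breakpoint (CE), slopes, CI, adjusted R^2."""

    psi: float
    slope_left: float
    slope_right: float
    ci: tuple[float, float]
    ci_level: float
    adj_r2: float
    trace: tuple[float, ...]
    se_psi: float
    converged: bool


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares with coefficient covariance; returns (beta, cov, rss)."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    n, p = x.shape
    dof = max(n - p, 1)
    xtx_inv = np.linalg.pinv(x.T @ x)
    cov = xtx_inv * (rss / dof)
    return beta, cov, rss


def segmented_fit(
    curve,
    start: float = 1800.0,
    ci_level: float = 0.99,
    tol: float = 1e-8,
    max_iter: int = 100,
    ci_method: str = "delta",
    n_boot: int = 999,
    seed: int = 0,
) -> BreakpointFit:
    """Single-breakpoint segmented regression by iterative linearisation.

    At each step the working model y ~ 1 + x + (x - psi)_+ + gamma * V,
    with V = -1{x > psi}, is fit by least squares and psi is updated by
    psi <- psi + gamma_hat / beta2_hat until the gap term vanishes.  The
    default breakpoint CI is the delta-method interval
    psi +/- z * SE(gamma_hat) / |beta2_hat|; ``ci_method='bootstrap'``
    replaces it by a case-resampling percentile interval.

    ``curve`` may be a PartialDependenceCurve or an (x, y) pair.
    """
    if isinstance(curve, PartialDependenceCurve):
        x, y = curve.grid, curve.values
    else:
        x, y = (np.asarray(v, dtype=float) for v in curve)
    if len(x) < 6:
        raise ValueError("need at least 6 points for a segmented fit")
    if not (x.min() < start < x.max()):
        raise ValueError(f"starting value {start} outside the data range")

    psi = float(start)
    trace = [psi]
    converged = False
    yscale = max(float(np.std(y)), 1e-12)
    beta = cov = None
    damping = 1.0
    prev_step = None
    for _ in range(max_iter):
        u = np.clip(x - psi, 0.0, None)
        v = -(x > psi).astype(float)
        design = np.column_stack([np.ones_like(x), x, u, v])
        beta, cov, _ = _ols(design, y)
        gamma, beta2 = beta[3], beta[2]
        if abs(beta2) < 1e-14:
            raise SegmentedFitError("no detectable slope change (beta2 ~ 0)", trace)
        step = gamma / beta2
        # halve the update when its direction flips (oscillation across a
        # grid gap), which turns the iteration into a bisection of gamma's root
        if prev_step is not None and step * prev_step < 0:
            damping *= 0.5
        prev_step = step
        psi_new = psi + damping * step
        if not (x.min() <= psi_new <= x.max()):
            raise SegmentedFitError(
                f"breakpoint escaped the data range at {psi_new:.1f}", trace
            )
        trace.append(psi_new)
        # converged when the gap term vanishes or the breakpoint stops moving
        if abs(gamma) < tol * yscale or abs(psi_new - psi) < 1e-6 * (x.max() - x.min()):
            psi = psi_new
            converged = True
            break
        psi = psi_new
    if not converged:
        raise SegmentedFitError(
            f"segmented fit did not converge in {max_iter} iterations", trace
        )

    se_gamma = float(np.sqrt(max(cov[3, 3], 0.0)))
    se_psi = se_gamma / abs(beta[2])

    # final two-segment model at the converged breakpoint
    u = np.clip(x - psi, 0.0, None)
    design = np.column_stack([np.ones_like(x), x, u])
    beta_f, _, rss = _ols(design, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    n, p = len(x), design.shape[1]
    if sst > 0 and n > p:
        r2 = 1.0 - rss / sst
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    else:
        adj_r2 = 1.0 if rss <= 1e-20 else 0.0

    from scipy.stats import norm

    if ci_method == "delta":
        z = norm.ppf(0.5 + ci_level / 2.0)
        ci = (psi - z * se_psi, psi + z * se_psi)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boot = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                fit = segmented_fit(
                    (x[idx], y[idx]), start=psi, ci_level=ci_level,
                    tol=tol, max_iter=max_iter, ci_method="delta",
                )
                boot.append(fit.psi)
            except (SegmentedFitError, ValueError):
                continue
        if len(boot) < n_boot // 2:
            raise SegmentedFitError("bootstrap CI failed on most resamples", trace)
        lo, hi = np.percentile(boot, [50 * (1 - ci_level), 50 * (1 + ci_level)])
        ci = (float(lo), float(hi))
    else:
        raise ValueError("ci_method must be 'delta' or 'bootstrap'")

    return BreakpointFit(
        psi=float(psi),
        slope_left=float(beta_f[1]),
        slope_right=float(beta_f[1] + beta_f[2]),
        ci=(float(min(ci)), float(max(ci))),
        ci_level=ci_level,
        adj_r2=float(adj_r2),
        trace=tuple(trace),
        se_psi=float(se_psi),
        converged=converged,
    )


def breakpoint_grid_oracle(curve) -> float:
    """Exhaustive profile search for the RSS-minimising breakpoint.

    Every interior grid date is tried as the breakpoint of a two-segment
    least-squares fit; ties go to the earliest date.
    """
    if isinstance(curve, PartialDependenceCurve):
        x, y = curve.grid, curve.values
    else:
        x, y = (np.asarray(v, dtype=float) for v in curve)
    best_rss, best_psi = np.inf, None
    for psi in x[1:-1]:
        design = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
        _, _, rss = _ols(design, y)
        if rss < best_rss - 1e-12:
            best_rss, best_psi = rss, float(psi)
    return best_psi
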