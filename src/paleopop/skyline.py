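"""Coalescent likelihood and Bayesian skyline reconstruction of Ne(t).

The heterochronous coalescent decomposes a timed genealogy into intervals
between successive events (sampling times and coalescences), each carrying
an active-lineage count k.  For piecewise-constant Ne the log-likelihood is

    log L = sum_coalescences -log Ne(t_c)
          - sum_intervals k(k-1)/2 * integral dt / Ne(t)

with the integral exact on the pieces.  The classic skyline inverts each
coalescent interval in closed form, N_hat = k(k-1) w / 2, and serves as an
oracle for the Bayesian estimator.

The Bayesian skyline groups coalescent events into m contiguous groups
(near-equal event counts, pooled over trees when several genealogies of
the same site are supplied) and samples per-group Ne by Metropolis-Hastings
with multiplier proposals under an independent log-uniform prior.  Because
group boundaries are fixed during a run, the likelihood factorises over
groups through the sufficient statistics (c_g, A_g): the number of
coalescences in group g and the accumulated pair intensity
A_g = sum k(k-1)/2 * dt within it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import TimedTree

__all__ = [
    "CoalescentIntervals",
    "SkylineConfig",
    "SkylinePosterior",
    "PiecewiseNe",
    "coalescent_intervals",
    "classic_skyline",
    "coalescent_loglik",
    "fit_bayesian_skyline",
    "summarize_trajectory",
    "hpd_interval",
    "effective_sample_size",
]

COALESCENCE = "coalescence"
SAMPLING = "sampling"


@dataclass(frozen=True)
class CoalescentIntervals:
    """Event-to-event decomposition of a timed tree, present to root.

    ``lengths[i]`` is the duration (years) of interval i, ``k[i]`` the
    active lineage count during it, ``events[i]`` the type of the event
    terminating it, and ``end_heights[i]`` that event's height.
    """

    lengths: np.ndarray
    k: np.ndarray
    events: tuple[str, ...]
    end_heights: np.ndarray
    start_height: float = 0.0

    def __post_init__(self) -> None:
        if not (len(self.lengths) == len(self.k) == len(self.events) == len(self.end_heights)):
            raise ValueError("interval arrays must have equal length")

    @property
    def n_coalescences(self) -> int:
        return sum(1 for e in self.events if e == COALESCENCE)

    @property
    def coalescent_heights(self) -> np.ndarray:
        return self.end_heights[[e == COALESCENCE for e in self.events]]

    @property
    def root_height(self) -> float:
        return float(self.end_heights[-1]) if len(self.end_heights) else self.start_height


def coalescent_intervals(tree: TimedTree) -> CoalescentIntervals:
    """Extract intervals, lineage counts, and event bookkeeping from a tree."""
    heights = tree.node_heights()
    events: list[tuple[float, int, int]] = []  # (height, order, +lineages)
    # sampling events: tips grouped by height (same horizon -> one event)
    tip_h: dict[float, int] = {}
    for node, h in heights.items():
        if node.is_leaf():
            key = round(h, 9)
            tip_h[key] = tip_h.get(key, 0) + 1
        else:
            if len(node.child_nodes()) != 2:
                raise ValueError("multifurcating node: intervals undefined")
            events.append((h, 0, -1))  # coalescence processed first on ties
    for h, count in tip_h.items():
        events.append((h, 1, count))
    events.sort(key=lambda e: (e[0], e[1]))

    if events[0][2] < 0:
        raise ValueError("tree has a coalescence before any sampled tip")
    start = events[0][0]
    k = events[0][2]
    cur = start
    lengths, ks, types, ends = [], [], [], []
    for h, _, delta in events[1:]:
        if h < cur - 1e-9:
            raise ValueError("negative interval encountered")
        lengths.append(h - cur)
        ks.append(k)
        types.append(COALESCENCE if delta < 0 else SAMPLING)
        ends.append(h)
        if delta < 0 and k < 2:
            raise ValueError("coalescence with fewer than 2 active lineages")
        k += delta
        cur = h
    return CoalescentIntervals(
        lengths=np.asarray(lengths, dtype=float),
        k=np.asarray(ks, dtype=np.int64),
        events=tuple(types),
        end_heights=np.asarray(ends, dtype=float),
        start_height=float(start),
    )


def classic_skyline(intervals: CoalescentIntervals) -> pd.DataFrame:
    """Closed-form per-interval estimates N_hat = k(k-1) w / 2.

    Returns one row per interval terminating in a coalescence, with the
    event height and estimate.
    """
    if intervals.k[0] < 2 and intervals.n_coalescences == 0:
        raise ValueError("need at least one coalescence (>= 2 tips)")
    rows = []
    for w, k, ev, h in zip(
        intervals.lengths, intervals.k, intervals.events, intervals.end_heights
    ):
        if ev == COALESCENCE:
            rows.append({"height": h, "ne_hat": k * (k - 1) * w / 2.0})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PiecewiseNe:
    """Piecewise-constant Ne over tree height: values[i] applies on
    (boundaries[i-1], boundaries[i]] with boundaries[-1] implicitly inf."""

    boundaries: np.ndarray  # ascending internal breakpoints (heights)
    values: np.ndarray  # len(boundaries) + 1 positive levels

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if len(v) != len(b) + 1:
            raise ValueError("need len(values) == len(boundaries) + 1")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("Ne must be positive everywhere")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "values", v)

    @classmethod
    def constant(cls, ne: float) -> "PiecewiseNe":
        return cls(np.array([]), np.array([float(ne)]))

    def at(self, heights) -> np.ndarray:
        idx = np.searchsorted(self.boundaries, np.asarray(heights, dtype=float), side="left")
        return self.values[idx]

    def inverse_integral(self, a: float, b: float) -> float:
        """Exact integral of 1/Ne over heights [a, b]."""
        if b < a:
            raise ValueError("integration bounds out of order")
        edges = np.concatenate([[a], self.boundaries[(self.boundaries > a) & (self.boundaries < b)], [b]])
        mids = 0.5 * (edges[:-1] + edges[1:])
        return float(np.sum(np.diff(edges) / self.at(mids)))


def coalescent_loglik(intervals: CoalescentIntervals, piecewise_ne: PiecewiseNe) -> float:
    """Heterochronous coalescent log-likelihood for piecewise-constant Ne."""
    ll = 0.0
    start = intervals.start_height
    for w, k, ev, h in zip(
        intervals.lengths, intervals.k, intervals.events, intervals.end_heights
    ):
        if k >= 2:
            ll -= k * (k - 1) / 2.0 * piecewise_ne.inverse_integral(h - w, h)
        if ev == COALESCENCE:
            ll -= np.log(piecewise_ne.at(h))
        start = h
    return float(ll)


@dataclass(frozen=True)
class SkylineConfig:
    """Settings of the grouped-skyline MCMC."""

    n_groups: int = 25
    chain_length: int = 50_000
    thinning: int = 10
    burn_in: float = 0.10
    proposal_scale: float = 1.0  # half-width of the log-space random walk
    seed: int = 0
    n_chains: int = 1
    tree_mixing: bool = False
    stochastic_group_sizes: bool = False
    ess_floor: float = 100.0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("need at least one group")
        if self.chain_length < 1 or self.thinning < 1 or self.n_chains < 1:
            raise ValueError("chain settings must be positive")
        if not 0 <= self.burn_in <= 0.5:
            raise ValueError("burn_in fraction must lie in [0, 0.5]")
        if self.proposal_scale <= 0:
            raise ValueError("proposal_scale must be positive")


@dataclass
class SkylinePosterior:
    """Posterior draws of grouped piecewise-constant Ne."""

    draws: np.ndarray  # (n_draws, m)
    group_edges: np.ndarray  # (m + 1,) heights, [0, ..., root span]
    loglik_trace: np.ndarray
    ess: np.ndarray
    most_recent_date: float
    config: SkylineConfig
    warnings: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return self.draws.shape[1]

    def ne_at_heights(self, heights) -> np.ndarray:
        """Draws of Ne at given heights: (n_draws, len(heights))."""
        h = np.asarray(heights, dtype=float)
        idx = np.clip(
            np.searchsorted(self.group_edges[1:-1], h, side="left"), 0, self.n_groups - 1
        )
        return self.draws[:, idx]


def _group_edges(
    coal_heights: np.ndarray, m: int, rng: np.random.Generator | None, stochastic: bool
) -> np.ndarray:
    """Group pooled coalescent events into m contiguous height bins.

    Deterministic mode spreads the remainder starting from the past
    (oldest) end; the stochastic mode draws group sizes from a uniform
    composition.  Returns m+1 edges from 0 to the oldest event height.
    """
    n = len(coal_heights)
    if m > n:
        raise ValueError(f"n_groups={m} exceeds the {n} coalescent events")
    hs = np.sort(coal_heights)
    if stochastic:
        assert rng is not None
        cuts = np.sort(rng.choice(np.arange(1, n), size=m - 1, replace=False)) if m > 1 else np.array([], dtype=int)
    else:
        base, rem = divmod(n, m)
        sizes = np.full(m, base, dtype=int)
        if rem:
            sizes[-rem:] += 1  # remainder spread from the past end
        cuts = np.cumsum(sizes)[:-1]
    internal = hs[cuts - 1] if len(cuts) else np.array([])
    return np.concatenate([[0.0], internal, [hs[-1]]])


def _sufficient_stats(
    interval_sets: list[CoalescentIntervals], edges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group (c_g, A_g): coalescence counts and pair intensities."""
    m = len(edges) - 1
    c = np.zeros(m)
    a = np.zeros(m)
    internal = edges[1:-1]
    for iv in interval_sets:
        for w, k, ev, h in zip(iv.lengths, iv.k, iv.events, iv.end_heights):
            if ev == COALESCENCE:
                g = min(int(np.searchsorted(internal, h, side="left")), m - 1)
                c[g] += 1
            if k < 2 or w == 0:
                continue
            lo, hi = h - w, h
            pieces = np.concatenate([[lo], internal[(internal > lo) & (internal < hi)], [hi]])
            for p0, p1 in zip(pieces[:-1], pieces[1:]):
                g = min(int(np.searchsorted(internal, 0.5 * (p0 + p1), side="left")), m - 1)
                a[g] += k * (k - 1) / 2.0 * (p1 - p0)
    return c, a


def _run_chain(
    stats: list[tuple[np.ndarray, np.ndarray]],
    m: int,
    config: SkylineConfig,
    rng: np.random.Generator,
    log_lo: float,
    log_hi: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One MH chain over per-group log-Ne; returns (draws, loglik trace)."""
    n_trees = len(stats)
    c_all = np.stack([c for c, _ in stats])
    a_all = np.stack([a for _, a in stats])
    if config.tree_mixing and n_trees > 1:
        t_idx = int(rng.integers(n_trees))
    else:
        t_idx = None
        c_sum, a_sum = c_all.sum(axis=0), a_all.sum(axis=0)

    log_ne = np.full(m, 0.5 * (log_lo + log_hi))

    def group_ll(log_v: np.ndarray, c: np.ndarray, a: np.ndarray) -> np.ndarray:
        return -c * log_v - a * np.exp(-log_v)

    keep = max((config.chain_length - int(config.burn_in * config.chain_length)) // config.thinning, 1)
    draws = np.empty((keep, m))
    ll_trace = np.empty(keep)
    stored = 0
    burn_end = config.chain_length - keep * config.thinning
    for it in range(config.chain_length):
        if t_idx is not None:
            t_idx = int(rng.integers(n_trees))
            c_cur, a_cur = c_all[t_idx], a_all[t_idx]
        else:
            c_cur, a_cur = c_sum, a_sum
        prop = log_ne + config.proposal_scale * (rng.random(m) - 0.5) * 2.0
        cur_ll = group_ll(log_ne, c_cur, a_cur)
        prop_ll = group_ll(prop, c_cur, a_cur)
        inside = (prop >= log_lo) & (prop <= log_hi)
        accept = inside & (np.log(rng.random(m)) < prop_ll - cur_ll)
        log_ne = np.where(accept, prop, log_ne)
        if it >= burn_end and (it - burn_end) % config.thinning == config.thinning - 1:
            draws[stored] = np.exp(log_ne)
            ll_trace[stored] = group_ll(log_ne, c_cur, a_cur).sum()
            stored += 1
    return draws[:stored], ll_trace[:stored]


def fit_bayesian_skyline(
    trees: list[TimedTree] | TimedTree, config: SkylineConfig
) -> SkylinePosterior:
    """Grouped Bayesian skyline MCMC over one or several timed genealogies.

    Several trees are treated as independent genealogies of the same
    demography (log-likelihoods summed) unless ``config.tree_mixing`` is
    set, in which case one tree is drawn uniformly per iteration, mixing
    over a posterior tree sample.
    """
    if isinstance(trees, TimedTree):
        trees = [trees]
    if not trees:
        raise ValueError("need at least one timed tree")
    interval_sets = [coalescent_intervals(t) for t in trees]
    coal_heights = np.concatenate([iv.coalescent_heights for iv in interval_sets])
    rng = np.random.default_rng(config.seed)
    edges = _group_edges(coal_heights, config.n_groups, rng, config.stochastic_group_sizes)
    m = config.n_groups

    stats = [_sufficient_stats([iv], edges) for iv in interval_sets]
    # prior scale anchored on the classic-skyline magnitude
    classic = np.concatenate(
        [classic_skyline(iv)["ne_hat"].to_numpy() for iv in interval_sets]
    )
    scale = max(float(np.median(classic[classic > 0])) if np.any(classic > 0) else 1.0, 1e-12)
    log_lo, log_hi = np.log(1e-3 * scale), np.log(1e3 * scale)

    chain_draws, chain_lls = [], []
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for ss in seeds:
        d, ll = _run_chain(stats, m, config, np.random.default_rng(ss), log_lo, log_hi)
        chain_draws.append(d)
        chain_lls.append(ll)
    draws = np.vstack(chain_draws)
    ll_trace = np.concatenate(chain_lls)

    ess = np.array([effective_sample_size(draws[:, g]) for g in range(m)])
    notes: list[str] = []
    if np.any(ess < config.ess_floor):
        low = int(np.sum(ess < config.ess_floor))
        notes.append(
            f"{low} of {m} groups have ESS below {config.ess_floor:.0f}; "
            "consider a longer chain"
        )
        warnings.warn(notes[-1], RuntimeWarning, stacklevel=2)
    return SkylinePosterior(
        draws=draws,
        group_edges=edges,
        loglik_trace=ll_trace,
        ess=ess,
        most_recent_date=trees[0].most_recent_date,
        config=config,
        warnings=notes,
    )


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    n_in = max(int(np.ceil(mass * n)), 1)
    if n_in >= n:
        return float(x[0]), float(x[-1])
    widths = x[n_in:] - x[: n - n_in]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + n_in])


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0:
            break
        s += acf[lag]
    return float(n / (1.0 + 2.0 * s))


def summarize_trajectory(
    posterior: SkylinePosterior,
    calendar_grid,
    tree: TimedTree | None = None,
    hpd_mass: float = 0.95,
) -> pd.DataFrame:
    """Posterior median and central HPD of Ne at each calendar grid date.

    The grid must lie within the reconstructed span: [root date,
    most recent tip date] of the underlying genealogies.
    """
    grid = np.asarray(calendar_grid, dtype=float)
    t0 = posterior.most_recent_date
    span = posterior.group_edges[-1]
    if tree is not None:
        t0 = tree.most_recent_date
        span = max(span, tree.root_height)
    heights = t0 - grid
    if np.any(heights < -1e-9) or np.any(heights > span + 1e-9):
        raise ValueError(
            f"grid outside the reconstructed span [{t0 - span:.1f}, {t0:.1f}] CE"
        )
    ne = posterior.ne_at_heights(np.clip(heights, 0.0, span))
    med = np.median(ne, axis=0)
    hpd = np.array([hpd_interval(ne[:, j], hpd_mass) for j in range(ne.shape[1])])
    return pd.DataFrame(
        {
            "date_CE": grid,
            "ne_median": med,
            "hpd_lo": hpd[:, 0],
            "hpd_hi": hpd[:, 1],
        }
    )
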