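"""End-to-end chain: study -> skylines -> Ne table -> RF PD -> breakpoint.

``recover_breakpoint`` runs the full inference chain on a synthetic study
(or on supplied genealogies) and returns the dated demographic breakpoint
with its confidence interval, the per-split random-forest scores, and the
intermediate products, so parameter-recovery experiments are one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import TimedTree
from .skyline import SkylineConfig, fit_bayesian_skyline, summarize_trajectory
from .study import StudyConfig, default_study_config, generate_core_study
from .trend import (
    BreakpointFit,
    NeTable,
    PartialDependenceCurve,
    assemble_ne_table,
    fit_rf,
    partial_dependence,
    segmented_fit,
)

__all__ = ["BreakpointRecovery", "recover_breakpoint", "site_skyline_summaries"]


@dataclass
class BreakpointRecovery:
    fit: BreakpointFit
    pd_curve: PartialDependenceCurve
    ne_table: NeTable
    rf_scores: np.ndarray
    summaries: dict[str, pd.DataFrame]

    @property
    def psi(self) -> float:
        return self.fit.psi


def site_skyline_summaries(
    genealogies: dict[str, list[TimedTree]],
    grid_step: float = 2.0,
    date_floor: float = 1750.0,
    n_groups: int = 25,
    chain_length: int = 40_000,
    thinning: int = 10,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-site grouped-skyline fits summarised on a calendar grid.

    The group count is capped at the available coalescent events per site;
    the calendar grid runs from max(root date, ``date_floor``) to the most
    recent tip, in ``grid_step``-year steps aligned on multiples of the
    step so grids are comparable across sites.
    """
    summaries: dict[str, pd.DataFrame] = {}
    sub_seeds = np.random.SeedSequence(seed).spawn(len(genealogies))
    for (site, trees), ss in zip(sorted(genealogies.items()), sub_seeds):
        n_events = sum(t.n_tips - 1 for t in trees)
        cfg = SkylineConfig(
            n_groups=min(n_groups, n_events),
            chain_length=chain_length,
            thinning=thinning,
            seed=int(ss.generate_state(1)[0] % (2**31 - 1)),
        )
        post = fit_bayesian_skyline(trees, cfg)
        t0 = trees[0].most_recent_date
        oldest = t0 - min(t.root_height for t in trees)
        lo = max(oldest, date_floor)
        start = np.ceil(lo / grid_step) * grid_step
        stop = np.floor(t0 / grid_step) * grid_step
        grid = np.arange(start, stop + 0.5 * grid_step, grid_step)
        summaries[site] = summarize_trajectory(post, grid)
    return summaries


def recover_breakpoint(
    config: StudyConfig | None = None,
    seed: int = 0,
    genealogies: dict[str, list[TimedTree]] | None = None,
    n_groups: int = 25,
    chain_length: int = 40_000,
    rf_trees: int = 500,
    n_splits: int = 10,
    start: float = 1800.0,
    ci_level: float = 0.99,
    grid_step: float = 2.0,
    date_floor: float = 1750.0,
) -> BreakpointRecovery:
    """Full chain from (simulated) genealogies to a dated breakpoint.

    When ``genealogies`` is None a synthetic study is generated from
    ``config`` (default: the reference 4-site study) with the given seed;
    the analysis itself never sees the simulation truth.
    """
    ss = np.random.SeedSequence(seed)
    s_study, s_sky, s_rf = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3))
    if genealogies is None:
        config = config or default_study_config(simulate_seqs=False)
        _, genealogies, _ = generate_core_study(config, s_study)
    summaries = site_skyline_summaries(
        genealogies,
        grid_step=grid_step,
        date_floor=date_floor,
        n_groups=n_groups,
        chain_length=chain_length,
        seed=s_sky,
    )
    table = assemble_ne_table(summaries, date_floor=date_floor)
    report = fit_rf(table, n_trees=rf_trees, n_splits=n_splits, seed=s_rf)
    dates = np.sort(table.data["date_CE"].unique())
    curve = partial_dependence(report, "date", grid=dates)
    fit = segmented_fit(curve, start=start, ci_level=ci_level)
    return BreakpointRecovery(
        fit=fit,
        pd_curve=curve,
        ne_table=table,
        rf_scores=report.scores,
        summaries=summaries,
    )
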