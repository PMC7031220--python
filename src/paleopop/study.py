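"""Synthetic multi-site sediment-core studies with known ground truth.

Each study comprises several sites (a dated core each); per site a
heterochronous genealogy is simulated under a site-specific Ne trajectory
that, by default, increases ten-fold through a logistic transition centred
on a shared breakpoint date (1784 CE).  Tips become amplicon variants with
per-sample abundances, sequences evolve along the genealogy under
GTR + Gamma with an uncorrelated lognormal clock, and kit- and
cross-sample contaminant variants can be injected so the corresponding
filters have a recoverable truth.

Default study conditions: 4 sites, 6 horizons per core (50-year spacing,
topmost 2010 CE), 10 variants per horizon, base Ne 100 with a 10-fold
sigmoidal increase at 1784 CE (steepness 0.2 / yr, a sharp step-like
onset), clock mean rate 1e-3
substitutions/site/yr with lognormal sdev 1.0.

One RNG stream is used per study and forked per site, so adding a site
leaves the others' genealogies unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .coalescent import SamplingDesign, TimedTree, simulate_genealogy
from .seqevolve import ClockModel, SubstitutionModel, simulate_branch_rates, simulate_sequences
from .trajectories import NeTrajectory, make_ne_trajectory

__all__ = [
    "SiteConfig",
    "StudyConfig",
    "StudyTruth",
    "default_study_config",
    "generate_core_study",
    "inject_contamination",
]

CONTROL_SAMPLE_ID = "CTRL"
CONTROL_SITE_ID = "__control__"


@dataclass(frozen=True)
class SiteConfig:
    design: SamplingDesign
    trajectory: NeTrajectory


@dataclass(frozen=True)
class StudyConfig:
    sites: tuple[SiteConfig, ...]
    n_trees_per_site: int = 1
    sequence_length: int = 300
    clock: ClockModel = field(default_factory=ClockModel)
    substitution: SubstitutionModel = field(default_factory=lambda: SubstitutionModel(gamma_shape=0.5, n_categories=4))
    kit_rate: float = 0.0
    cross_rate: float = 0.0
    simulate_seqs: bool = True
    grid_step: float = 0.1

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("need at least one site")
        labels = [s.design.site_id for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError(f"conflicting site labels: {labels}")
        for s in self.sites:
            if len(s.design.horizons) < 2:
                raise ValueError("each site needs at least two horizons")
        if not (0 <= self.kit_rate <= 1 and 0 <= self.cross_rate <= 1):
            raise ValueError("contamination rates must lie in [0, 1]")


def default_study_config(
    n_sites: int = 4,
    n_horizons: int = 6,
    tips_per_horizon: int = 10,
    top_date: float = 2010.0,
    horizon_spacing: float = 50.0,
    base_ne: float = 100.0,
    fold_change: float = 10.0,
    breakpoint_date: float = 1784.0,
    steepness: float = 0.2,
    kit_rate: float = 0.0,
    cross_rate: float = 0.0,
    sequence_length: int = 300,
    simulate_seqs: bool = True,
) -> StudyConfig:
    """The reference study layout (shared sigmoidal breakpoint across sites)."""
    traj = make_ne_trajectory(
        "sigmoidal_breakpoint",
        base_ne=base_ne,
        fold_change=fold_change,
        breakpoint_date=breakpoint_date,
        steepness=steepness,
    )
    sites = []
    for i in range(n_sites):
        horizons = tuple(
            (top_date - j * horizon_spacing, tips_per_horizon) for j in range(n_horizons)
        )
        design = SamplingDesign(site_id=f"S{i + 1:02d}", horizons=horizons)
        sites.append(SiteConfig(design=design, trajectory=traj))
    return StudyConfig(
        sites=tuple(sites),
        kit_rate=kit_rate,
        cross_rate=cross_rate,
        sequence_length=sequence_length,
        simulate_seqs=simulate_seqs,
    )


@dataclass
class StudyTruth:
    """Ground truth emitted with every synthetic study."""

    trajectories: dict[str, NeTrajectory]
    breakpoint_date: float | None
    kit_contaminants: set[str] = field(default_factory=set)
    cross_contaminants: set[str] = field(default_factory=set)
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "breakpoint_date": self.breakpoint_date,
            "seed": self.seed,
            "trajectories": {
                site: {
                    "kind": t.kind,
                    "base_ne": t.base_ne,
                    "fold_change": t.fold_change,
                    "breakpoint_date": t.breakpoint_date,
                    "steepness": t.steepness,
                }
                for site, t in self.trajectories.items()
            },
            "kit_contaminants": sorted(self.kit_contaminants),
            "cross_contaminants": sorted(self.cross_contaminants),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def generate_core_study(
    config: StudyConfig, seed: int
) -> tuple[AbundanceMatrix, dict[str, list[TimedTree]], StudyTruth]:
    """Generate one synthetic study: abundances, genealogies, and truth.

    Every tip of every genealogy becomes a distinct variant whose read
    count is drawn from a geometric abundance distribution; each horizon is
    one sample, and a (possibly empty) negative-control sample is always
    present.  The same seed reproduces the study exactly.
    """
    root_ss = np.random.SeedSequence(seed)
    site_seeds = root_ss.spawn(len(config.sites) + 1)
    study_rng = np.random.default_rng(site_seeds[-1])

    genealogies: dict[str, list[TimedTree]] = {}
    records: list[dict] = []
    sample_rows: dict[str, dict] = {}
    sequences: dict[str, str] = {}

    for site_cfg, ss in zip(config.sites, site_seeds[:-1]):
        rng = np.random.default_rng(ss)
        site = site_cfg.design.site_id
        trees = []
        for t_idx in range(config.n_trees_per_site):
            tree = simulate_genealogy(
                site_cfg.design, site_cfg.trajectory, rng, grid_step=config.grid_step
            )
            trees.append(tree)
        genealogies[site] = trees

        for h_idx, (date, _) in enumerate(site_cfg.design.horizons):
            sample_rows[f"{site}_s{h_idx}"] = {
                "site_id": site,
                "date_CE": float(date),
                "is_control": False,
            }
        # abundances from the first genealogy's tips (one variant per tip)
        tree = trees[0]
        if config.simulate_seqs:
            rates = simulate_branch_rates(tree, config.clock, rng)
            aln = simulate_sequences(
                tree, rates, config.substitution, config.sequence_length, rng
            )
        else:
            aln = {}
        for label in sorted(tree.tip_dates):
            h_idx = int(label.split("|")[1][1:])
            records.append(
                {
                    "variant_id": label,
                    "sample_id": f"{site}_s{h_idx}",
                    "count": int(rng.geometric(1.0 / 50.0)),
                }
            )
            if aln:
                sequences[label] = aln[label]

    sample_rows[CONTROL_SAMPLE_ID] = {
        "site_id": CONTROL_SITE_ID,
        "date_CE": np.nan,
        "is_control": True,
    }
    samples = pd.DataFrame.from_dict(sample_rows, orient="index")
    samples.index.name = "sample_id"
    long = pd.DataFrame.from_records(records)
    counts = (
        long.pivot_table(
            index="variant_id", columns="sample_id", values="count", fill_value=0,
            aggfunc="sum",
        )
        .reindex(columns=samples.index, fill_value=0)
    )
    matrix = AbundanceMatrix(counts, samples, sequences or None)

    breakpoints = {
        s.design.site_id: s.trajectory.breakpoint_date
        for s in config.sites
        if s.trajectory.kind == "sigmoidal_breakpoint"
    }
    shared_bp = (
        next(iter(breakpoints.values()))
        if breakpoints and len(set(breakpoints.values())) == 1
        else None
    )
    truth = StudyTruth(
        trajectories={s.design.site_id: s.trajectory for s in config.sites},
        breakpoint_date=shared_bp,
        seed=seed,
    )
    if config.kit_rate > 0 or config.cross_rate > 0:
        matrix = inject_contamination(
            matrix, config.kit_rate, config.cross_rate, study_rng, truth=truth
        )
    return matrix, genealogies, truth


def inject_contamination(
    matrix: AbundanceMatrix,
    kit_rate: float,
    cross_rate: float,
    seed: int | np.random.Generator,
    truth: StudyTruth | None = None,
) -> AbundanceMatrix:
    """Inject kit and cross-sample contaminant variants into a study.

    A fraction ``kit_rate`` of variants (rounded) is marked as kit
    contamination: each gains a count in the negative control and in a
    random non-control sample.  A fraction ``cross_rate`` of the remaining
    variants is duplicated into a second sample of the same site
    (cross-sample contamination).  Injected IDs are recorded on ``truth``.
    """
    if not (0 <= kit_rate <= 1 and 0 <= cross_rate <= 1):
        raise ValueError("contamination rates must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kit_rate == 0 and cross_rate == 0:
        return matrix
    counts = matrix.counts.copy()
    controls = matrix.control_samples
    variant_ids = np.array(matrix.variant_ids)
    n = len(variant_ids)

    kit_ids: list[str] = []
    if kit_rate > 0:
        if not controls:
            raise ValueError("kit contamination needs a control sample")
        n_kit = int(round(kit_rate * n))
        kit_ids = sorted(rng.choice(variant_ids, size=n_kit, replace=False))
        non_control = [s for s in matrix.sample_ids if s not in controls]
        for vid in kit_ids:
            counts.loc[vid, controls[0]] += int(rng.geometric(1.0 / 10.0))
            extra = non_control[int(rng.integers(len(non_control)))]
            counts.loc[vid, extra] += int(rng.geometric(1.0 / 10.0))

    cross_ids: list[str] = []
    if cross_rate > 0:
        pool = np.array(sorted(set(variant_ids) - set(kit_ids)))
        n_cross = int(round(cross_rate * len(pool)))
        candidates = sorted(rng.choice(pool, size=n_cross, replace=False)) if n_cross else []
        for vid in candidates:
            present = [
                s for s in matrix.sample_ids
                if counts.loc[vid, s] > 0 and not matrix.samples.loc[s, "is_control"]
            ]
            if not present:
                continue
            home = present[0]
            site = matrix.samples.loc[home, "site_id"]
            others = [s for s in matrix.site_samples(site) if s not in present]
            if not others:
                continue
            target = others[int(rng.integers(len(others)))]
            counts.loc[vid, target] += max(int(counts.loc[vid, home] // 2), 1)
            cross_ids.append(vid)

    if truth is not None:
        truth.kit_contaminants.update(kit_ids)
        truth.cross_contaminants.update(cross_ids)
    return AbundanceMatrix(counts, matrix.samples, matrix.sequences)
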