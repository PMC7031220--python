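"""Serially-sampled (heterochronous) coalescent simulation under time-varying Ne.

Genealogies of variants recovered from dated sediment horizons are
heterochronous: each tip enters the process at the deposition date of its
horizon.  Looking backwards from the most recent horizon, k active lineages
coalesce with instantaneous rate k(k-1) / (2 Ne(t)).  For a time-varying
trajectory the waiting time to the next coalescence is drawn by inverting
the cumulative coalescent intensity

    Lambda(h) = integral_0^h du / Ne(most_recent_date - u)

which is computed on a fine height grid with Ne held constant within each
cell (piecewise-constant approximation, default 0.1-yr cells) and inverted
by linear interpolation.  Sampling events truncate the current waiting-time
draw; by the memorylessness of the underlying inhomogeneous Poisson
process, redrawing after each event is exact.

Internal time unit is height: years before ``most_recent_date``.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .trajectories import NeTrajectory

__all__ = ["SamplingDesign", "TimedTree", "simulate_genealogy"]


@dataclass(frozen=True)
class SamplingDesign:
    """Dated sampling layout of one sediment core.

    ``horizons`` lists (deposition date CE, number of tips) from the core
    top downwards, so dates must be strictly decreasing.  ``most_recent_date``
    anchors height zero; it defaults to the topmost horizon date.
    """

    site_id: str
    horizons: tuple[tuple[float, int], ...]
    most_recent_date: float | None = None

    def __post_init__(self) -> None:
        if len(self.horizons) == 0:
            raise ValueError("a sampling design needs at least one horizon")
        dates = [d for d, _ in self.horizons]
        if any(b >= a for a, b in zip(dates, dates[1:])):
            raise ValueError("horizon dates must strictly decrease with depth")
        if any(n < 1 for _, n in self.horizons):
            raise ValueError("every horizon needs at least one tip")
        if self.most_recent_date is None:
            object.__setattr__(self, "most_recent_date", float(dates[0]))
        elif self.most_recent_date < dates[0]:
            raise ValueError("most_recent_date precedes the newest horizon")

    @property
    def n_tips(self) -> int:
        return sum(n for _, n in self.horizons)


class TimedTree:
    """Binary genealogy with branch lengths in years and dated tips.

    Wraps a :class:`dendropy.Tree` whose edge lengths are in calendar
    years, together with the CE date of height zero and a tip -> date map.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        most_recent_date: float,
        tip_dates: dict[str, float],
        validate: bool = True,
    ):
        self.tree = tree
        self.most_recent_date = float(most_recent_date)
        self.tip_dates = {str(k): float(v) for k, v in tip_dates.items()}
        self._heights: dict[int, float] | None = None
        if validate:
            self.validate()

    # -- geometry ---------------------------------------------------------

    def node_heights(self) -> dict[dendropy.Node, float]:
        """Height (years before most_recent_date) of every node."""
        root = self.tree.seed_node
        depth: dict[dendropy.Node, float] = {root: 0.0}
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        leaves = [n for n in self.tree.leaf_node_iter()]
        first = leaves[0]
        root_height = depth[first] + self._tip_height(first)
        return {node: root_height - d for node, d in depth.items()}

    def _tip_height(self, leaf: dendropy.Node) -> float:
        label = leaf.taxon.label
        if label not in self.tip_dates:
            raise ValueError(f"tip {label!r} has no deposition date")
        return self.most_recent_date - self.tip_dates[label]

    @property
    def root_height(self) -> float:
        return max(self.node_heights().values())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def validate(self, tol: float = 1e-9) -> None:
        heights = self.node_heights()
        for node, h in heights.items():
            if node.is_leaf():
                expected = self._tip_height(node)
                if abs(h - expected) > tol * max(1.0, abs(expected)) + tol:
                    raise ValueError(
                        f"tip {node.taxon.label!r} height {h:.6g} disagrees with its "
                        f"deposition date (expected height {expected:.6g})"
                    )
            else:
                if len(node.child_nodes()) != 2:
                    raise ValueError("tree is not strictly binary")
                for child in node.child_nodes():
                    if heights[child] > h + tol:
                        raise ValueError("parent node below its child (negative branch)")

    # -- serialisation ----------------------------------------------------

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(
        cls, newick: str, most_recent_date: float, tip_dates: dict[str, float]
    ) -> "TimedTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree, most_recent_date, tip_dates)


class _IntensityGrid:
    """Lazily extended cumulative coalescent intensity Lambda(h).

    Ne is frozen at the midpoint of each grid cell, making Lambda piecewise
    linear and its inverse exact by interpolation.
    """

    def __init__(self, traj: NeTrajectory, most_recent_date: float, step: float = 0.1):
        if step <= 0:
            raise ValueError("grid step must be positive")
        self.traj = traj
        self.t0 = float(most_recent_date)
        self.step = float(step)
        self.heights = np.array([0.0])
        self.cum = np.array([0.0])
        self._extend_to(16.0)

    def _extend_to(self, h: float) -> None:
        while self.heights[-1] < h:
            n_new = max(256, len(self.heights))
            start = self.heights[-1]
            edges = start + self.step * np.arange(1, n_new + 1)
            mids = edges - 0.5 * self.step
            ne = np.asarray(self.traj(self.t0 - mids), dtype=float)
            if np.any(ne <= 0):
                raise ValueError("Ne trajectory is non-positive on the required time range")
            cum_new = self.cum[-1] + np.cumsum(self.step / ne)
            self.heights = np.concatenate([self.heights, edges])
            self.cum = np.concatenate([self.cum, cum_new])

    def value(self, h: float) -> float:
        self._extend_to(h)
        return float(np.interp(h, self.heights, self.cum))

    def invert(self, lam: float) -> float:
        """Smallest h with Lambda(h) = lam."""
        while self.cum[-1] < lam:
            self._extend_to(self.heights[-1] * 2 + 16.0)
        return float(np.interp(lam, self.cum, self.heights))


def simulate_genealogy(
    design: SamplingDesign,
    traj: NeTrajectory,
    seed: int | np.random.Generator,
    grid_step: float = 0.1,
) -> TimedTree:
    """Simulate one genealogy for a dated core under an Ne trajectory.

    Parameters
    ----------
    design
        Dated horizons with tip counts.
    traj
        Strictly positive Ne as a function of calendar date.
    seed
        Integer seed or a numpy Generator (consumed in place).
    grid_step
        Height-grid resolution (years) of the intensity inversion.

    Returns
    -------
    TimedTree
        Binary tree with ``design.n_tips`` leaves; tip labels are
        ``{site}|h{horizon_index}|{replicate}``.
    """
    if design.n_tips < 2:
        raise ValueError("need at least 2 tips overall to coalesce")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    taxon_ns = dendropy.TaxonNamespace()
    tip_dates: dict[str, float] = {}
    sampling_events: list[tuple[float, list[dendropy.Node]]] = []
    for h_idx, (date, count) in enumerate(design.horizons):
        height = design.most_recent_date - date
        nodes = []
        for rep in range(count):
            label = f"{design.site_id}|h{h_idx}|{rep}"
            taxon = taxon_ns.new_taxon(label)
            node = dendropy.Node(taxon=taxon)
            node.height = height
            nodes.append(node)
            tip_dates[label] = date
        sampling_events.append((height, nodes))
    sampling_events.sort(key=lambda e: e[0])

    grid = _IntensityGrid(traj, design.most_recent_date, step=grid_step)
    active: list[dendropy.Node] = []
    pending = list(sampling_events)
    h = pending[0][0]

    while pending or len(active) > 1:
        if len(active) < 2:
            height, nodes = pending.pop(0)
            h = height
            active.extend(nodes)
            continue
        k = len(active)
        pair_rate = k * (k - 1) / 2.0
        target = grid.value(h) + rng.exponential(1.0) / pair_rate
        h_coal = grid.invert(target)
        if pending and pending[0][0] < h_coal:
            height, nodes = pending.pop(0)
            h = height
            active.extend(nodes)
            continue
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent = dendropy.Node()
        parent.height = h_coal
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = h_coal - child.height
        active = [n for idx, n in enumerate(active) if idx not in (i, j)]
        active.append(parent)
        h = h_coal

    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = active[0]
    return TimedTree(tree, design.most_recent_date, tip_dates)
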