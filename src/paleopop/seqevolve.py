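"""Branch-rate and sequence simulation along timed genealogies.

Branch rates follow either a strict clock or an uncorrelated lognormal
relaxed clock: rates are i.i.d. lognormal across branches, parameterised so
that the *arithmetic* mean of the rate distribution equals ``mean_rate``
(mu = ln(mean_rate) - sdev^2 / 2).  Sequences evolve under a GTR
substitution model with discrete-Gamma rate variation across sites; the
rate matrix is scaled to one expected substitution per unit branch length
so that branch length x branch rate is an expected per-site distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .coalescent import TimedTree

__all__ = [
    "ClockModel",
    "SubstitutionModel",
    "simulate_branch_rates",
    "simulate_sequences",
]

BASES = np.array(["A", "C", "G", "T"])
# exchangeability order follows the usual upper-triangle convention
PAIR_ORDER = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))


@dataclass(frozen=True)
class ClockModel:
    """Molecular clock: strict or uncorrelated lognormal across branches."""

    mean_rate: float = 1e-3  # substitutions / site / year
    lognormal_sdev: float = 1.0  # sigma of log(rate)
    mode: str = "uncorrelated_lognormal"

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be > 0")
        if self.lognormal_sdev < 0:
            raise ValueError("lognormal_sdev must be >= 0")
        if self.mode not in ("strict", "uncorrelated_lognormal"):
            raise ValueError(f"unknown clock mode {self.mode!r}")


@dataclass(frozen=True)
class SubstitutionModel:
    """GTR + discrete-Gamma model of nucleotide substitution."""

    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_frequencies: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 1.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6 or any(s < 0 for s in self.exchangeabilities):
            raise ValueError("need 6 non-negative exchangeabilities")
        freqs = np.asarray(self.base_frequencies, dtype=float)
        if len(freqs) != 4 or np.any(freqs <= 0):
            raise ValueError("need 4 positive base frequencies")
        if abs(freqs.sum() - 1.0) > 1e-6:
            raise ValueError(f"base frequencies sum to {freqs.sum():.8f}, not 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    @property
    def freqs(self) -> np.ndarray:
        f = np.asarray(self.base_frequencies, dtype=float)
        return f / f.sum()

    def rate_matrix(self) -> np.ndarray:
        """GTR generator scaled to 1 expected substitution / unit length."""
        pi = self.freqs
        q = np.zeros((4, 4))
        for s, (a, b) in zip(self.exchangeabilities, PAIR_ORDER):
            i, j = BASES.tolist().index(a), BASES.tolist().index(b)
            q[i, j] = s * pi[j]
            q[j, i] = s * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(pi, np.diag(q))
        if mu <= 0:
            raise ValueError("degenerate substitution model (zero total rate)")
        return q / mu

    def category_rates(self) -> np.ndarray:
        """Mean rate of each discrete Gamma category (overall mean 1)."""
        k, a = self.n_categories, self.gamma_shape
        if k == 1:
            return np.array([1.0])
        edges = gamma_dist.ppf(np.arange(1, k) / k, a, scale=1.0 / a)
        cuts = np.concatenate([[0.0], a * edges, [np.inf]])
        lower = gammainc(a + 1.0, cuts[:-1])
        upper = np.where(np.isinf(cuts[1:]), 1.0, gammainc(a + 1.0, cuts[1:]))
        return k * (upper - lower)

    def transition_operator(self):
        """Closure t -> P(t) via symmetric eigendecomposition of Q."""
        pi = self.freqs
        q = self.rate_matrix()
        sq = np.sqrt(pi)
        sym = (q * sq[:, None]) / sq[None, :]
        sym = 0.5 * (sym + sym.T)  # enforce exact symmetry
        lam, u = np.linalg.eigh(sym)
        left = u / sq[:, None]
        right = u.T * sq[None, :]

        def p_matrix(t: float) -> np.ndarray:
            p = (left * np.exp(lam * t)) @ right
            p = np.clip(p, 0.0, None)
            return p / p.sum(axis=1, keepdims=True)

        return p_matrix

    @classmethod
    def jc(cls, gamma_shape: float = 1.0, n_categories: int = 1) -> "SubstitutionModel":
        return cls(gamma_shape=gamma_shape, n_categories=n_categories)


def simulate_branch_rates(
    tree: TimedTree | dendropy.Tree,
    clock: ClockModel,
    seed: int | np.random.Generator,
) -> dict[dendropy.Node, float]:
    """Draw one substitution rate per branch (keyed by the child node)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dtree = tree.tree if isinstance(tree, TimedTree) else tree
    nodes = [n for n in dtree.preorder_node_iter() if n.parent_node is not None]
    for n in nodes:
        if n.edge.length is not None and n.edge.length < 0:
            raise ValueError("tree has negative branch lengths")
    if clock.mode == "strict" or clock.lognormal_sdev == 0:
        return {n: clock.mean_rate for n in nodes}
    sigma = clock.lognormal_sdev
    mu = np.log(clock.mean_rate) - 0.5 * sigma**2
    draws = rng.lognormal(mean=mu, sigma=sigma, size=len(nodes))
    return {n: float(r) for n, r in zip(nodes, draws)}


def simulate_sequences(
    tree: TimedTree | dendropy.Tree,
    rates: dict[dendropy.Node, float],
    model: SubstitutionModel,
    length: int,
    seed: int | np.random.Generator,
) -> dict[str, str]:
    """Evolve an alignment along the tree; returns tip label -> sequence.

    Sites are independently assigned to a Gamma rate category; the root
    sequence is drawn from the stationary base frequencies.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dtree = tree.tree if isinstance(tree, TimedTree) else tree

    pi = model.freqs
    p_of = model.transition_operator()
    cat_rates = model.category_rates()
    site_cat = rng.integers(0, len(cat_rates), size=length)

    root = dtree.seed_node
    states: dict[dendropy.Node, np.ndarray] = {
        root: rng.choice(4, size=length, p=pi)
    }
    out: dict[str, str] = {}
    if root.is_leaf():  # degenerate single-node tree
        out[root.taxon.label] = "".join(BASES[states[root]])

    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        parent_state = states[node.parent_node]
        branch_rate = rates.get(node)
        if branch_rate is None:
            raise ValueError("missing branch rate for a node")
        blen = node.edge.length or 0.0
        child = np.empty(length, dtype=np.int64)
        for c, r in enumerate(cat_rates):
            mask = site_cat == c
            if not mask.any():
                continue
            d = blen * branch_rate * r
            p = p_of(d)
            cum = np.cumsum(p, axis=1)
            u = rng.random(mask.sum())
            child[mask] = np.minimum(
                (u[:, None] > cum[parent_state[mask]]).sum(axis=1), 3
            )
        states[node] = child
        if node.is_leaf():
            out[node.taxon.label] = "".join(BASES[child])
        # free parent states once all children visited
    return out
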