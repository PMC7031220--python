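"""Variant filtering ahead of demographic inference.

Order matters and the pipeline enforces it: kit-contaminant removal against
the sequenced negative control comes first, then per-site removal of
variants present in more than one sample of a site (cross-contamination),
then alignment occupancy filtering, then capping each sample at the 50 most
phylogenetically diverse variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .abundance import AbundanceMatrix

__all__ = [
    "dereplicate",
    "remove_control_variants",
    "remove_cross_sample_variants",
    "occupancy_filter",
    "phylodiversity_cap",
    "ControlRemovalReport",
]

GAP_CHARS = frozenset("-.")


def dereplicate(
    sequences_per_sample: dict[str, list[str]],
    sample_meta: pd.DataFrame | None = None,
) -> AbundanceMatrix:
    """Collapse identical sequences into variants with per-sample counts.

    Variant IDs are assigned in order of first appearance over samples
    sorted by ID (``var00001``, ...), so output is deterministic.  Total
    read counts are conserved per sample.
    """
    sample_ids = sorted(sequences_per_sample)
    seq_to_id: dict[str, str] = {}
    rows: dict[str, dict[str, int]] = {}
    for sid in sample_ids:
        for seq in sequences_per_sample[sid]:
            if not seq:
                raise ValueError("empty sequence encountered")
            vid = seq_to_id.get(seq)
            if vid is None:
                vid = f"var{len(seq_to_id) + 1:05d}"
                seq_to_id[seq] = vid
                rows[vid] = {}
            rows[vid][sid] = rows[vid].get(sid, 0) + 1
    counts = pd.DataFrame(
        [[rows[v].get(s, 0) for s in sample_ids] for v in rows],
        index=list(rows),
        columns=sample_ids,
        dtype=np.int64,
    )
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {"site_id": "unknown", "date_CE": np.nan, "is_control": False},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    sequences = {vid: seq for seq, vid in seq_to_id.items()}
    return AbundanceMatrix(counts, sample_meta.loc[sample_ids], sequences)


@dataclass(frozen=True)
class ControlRemovalReport:
    n_total: int
    n_removed: int
    removed_ids: tuple[str, ...]

    @property
    def percent(self) -> float:
        if self.n_total == 0:
            return 0.0
        return round(100.0 * self.n_removed / self.n_total, 1)

    def __str__(self) -> str:
        return (
            f"{self.n_removed} of {self.n_total} variants present in the "
            f"negative control ({self.percent}%) removed"
        )


def remove_control_variants(
    matrix: AbundanceMatrix,
) -> tuple[AbundanceMatrix, ControlRemovalReport]:
    """Drop every variant detected (count > 0) in any negative control.

    Uses presence, not an abundance threshold.  Raises if the matrix has no
    control sample, since the filter would silently do nothing.
    """
    controls = matrix.control_samples
    if not controls:
        raise ValueError(
            "no negative-control sample in the matrix; kit-contaminant "
            "removal requires one sample flagged is_control"
        )
    in_control = matrix.counts[controls].sum(axis=1) > 0
    removed = tuple(matrix.counts.index[in_control])
    report = ControlRemovalReport(
        n_total=matrix.n_variants, n_removed=len(removed), removed_ids=removed
    )
    return matrix.drop_variants(removed), report


def remove_cross_sample_variants(
    matrix: AbundanceMatrix, site: str
) -> AbundanceMatrix:
    """Within one site, keep only variants seen in exactly one sample.

    Counts of removed variants are zeroed in that site's samples only; the
    rule is per site, so presence at other sites is untouched.  Variants
    left with no counts anywhere are dropped.
    """
    site_samples = matrix.site_samples(site)
    if not site_samples:
        raise ValueError(f"unknown site {site!r}")
    presence = (matrix.counts[site_samples] > 0).sum(axis=1)
    multi = matrix.counts.index[presence > 1]
    counts = matrix.counts.copy()
    counts.loc[multi, site_samples] = 0
    return AbundanceMatrix(counts, matrix.samples, matrix.sequences).prune_empty_variants()


def _column_occupancy(rows: list[str]) -> np.ndarray:
    arr = np.array([list(r) for r in rows])
    is_base = ~np.isin(arr, list(GAP_CHARS))
    return is_base.mean(axis=0)


def occupancy_filter(
    alignment: dict[str, str], threshold: float = 0.10, iterate: bool = True
) -> dict[str, str]:
    """Remove sequences carrying bases in low-occupancy alignment columns.

    A column's occupancy is its fraction of non-gap characters.  Sequences
    with a base in any column of occupancy < threshold are removed; by
    default the rule is re-applied until no further column falls below the
    threshold (``iterate=False`` gives the single-pass variant).
    """
    if not 0 < threshold <= 1:
        raise ValueError("occupancy threshold must be in (0, 1]")
    if not alignment:
        return {}
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    current = dict(alignment)
    while current:
        ids = list(current)
        arr = np.array([list(current[i]) for i in ids])
        is_base = ~np.isin(arr, list(GAP_CHARS))
        occupancy = is_base.mean(axis=0)
        bad_cols = occupancy < threshold
        if not bad_cols.any():
            break
        offender = is_base[:, bad_cols].any(axis=1)
        if not offender.any():
            break
        current = {i: s for i, s, o in zip(ids, (current[i] for i in ids), offender) if not o}
        if not iterate:
            break
    return current


def phylodiversity_cap(
    variants_in_sample: list[str],
    tree_or_distance,
    cap: int = 50,
    abundances: dict[str, int] | None = None,
) -> list[str]:
    """Reduce a sample to its ``cap`` most phylogenetically diverse variants.

    If the sample holds more than ``cap`` variants, pairwise patristic
    distances are clustered with Ward's method, the dendrogram is cut into
    ``cap`` groups, and each group is represented by its medoid (total
    within-group distance; ties broken by higher abundance, then by
    lexicographic variant ID).

    ``tree_or_distance`` is either a dendropy tree whose tip labels cover
    the variants, or a square distance DataFrame.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    ids = list(variants_in_sample)
    if len(ids) <= cap:
        return ids

    dist = _patristic_matrix(tree_or_distance, ids)
    condensed = squareform(dist, checks=False)
    groups = fcluster(linkage(condensed, method="ward"), t=cap, criterion="maxclust")

    abundances = abundances or {}
    chosen: list[str] = []
    for g in np.unique(groups):
        members = np.where(groups == g)[0]
        totals = dist[np.ix_(members, members)].sum(axis=1)
        order = sorted(
            range(len(members)),
            key=lambda i: (
                totals[i],
                -abundances.get(ids[members[i]], 0),
                ids[members[i]],
            ),
        )
        chosen.append(ids[members[order[0]]])
    return sorted(chosen, key=ids.index)


def _patristic_matrix(tree_or_distance, ids: list[str]) -> np.ndarray:
    if isinstance(tree_or_distance, pd.DataFrame):
        missing = [i for i in ids if i not in tree_or_distance.index]
        if missing:
            raise ValueError(f"distance matrix lacks variants {missing[:5]}")
        return tree_or_distance.loc[ids, ids].to_numpy(dtype=float)
    tree = getattr(tree_or_distance, "tree", tree_or_distance)
    if not isinstance(tree, dendropy.Tree):
        raise TypeError("expected a dendropy tree, TimedTree, or distance DataFrame")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [i for i in ids if i not in taxa]
    if missing:
        raise ValueError(f"tree lacks tips for variants {missing[:5]}")
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
            out[i, j] = out[j, i] = d
    return out
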