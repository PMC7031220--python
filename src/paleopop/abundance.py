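"""Variant x sample abundance matrix with site/date/control annotations."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix"]

SAMPLE_COLUMNS = ["site_id", "date_CE", "is_control"]


class AbundanceMatrix:
    """Counts of each variant in each sample, plus sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by variant_id with one integer column per
        sample_id.
    samples
        DataFrame indexed by sample_id with columns ``site_id``,
        ``date_CE`` and boolean ``is_control``.
    sequences
        Optional variant_id -> nucleotide string map.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        sequences: dict[str, str] | None = None,
    ):
        counts = counts.copy()
        samples = samples.copy()
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate variant IDs: {dupes[:5]}")
        missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
        if missing:
            raise ValueError(f"sample metadata lacks columns {missing}")
        if set(counts.columns) != set(samples.index):
            raise ValueError("counts columns and sample metadata index disagree")
        counts = counts[list(samples.index)]
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.samples = samples
        self.sequences = dict(sequences) if sequences else None

    # -- basic views ------------------------------------------------------

    @property
    def variant_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def control_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["is_control"].astype(bool)])

    @property
    def n_variants(self) -> int:
        return len(self.counts.index)

    def site_samples(self, site_id: str) -> list[str]:
        hit = self.samples.index[
            (self.samples["site_id"] == site_id) & (~self.samples["is_control"].astype(bool))
        ]
        return list(hit)

    def sites(self) -> list[str]:
        mask = ~self.samples["is_control"].astype(bool)
        return sorted(self.samples.loc[mask, "site_id"].unique())

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.counts, self.samples, self.sequences)

    def drop_variants(self, variant_ids) -> "AbundanceMatrix":
        keep = [v for v in self.counts.index if v not in set(variant_ids)]
        seqs = {v: s for v, s in (self.sequences or {}).items() if v in set(keep)} or None
        return AbundanceMatrix(self.counts.loc[keep], self.samples, seqs)

    def prune_empty_variants(self) -> "AbundanceMatrix":
        present = self.counts.index[self.counts.sum(axis=1) > 0]
        seqs = (
            {v: s for v, s in (self.sequences or {}).items() if v in set(present)} or None
        )
        return AbundanceMatrix(self.counts.loc[present], self.samples, seqs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AbundanceMatrix):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.samples.equals(other.samples)
            and (self.sequences or {}) == (other.sequences or {})
        )

    # -- serialisation ----------------------------------------------------

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        long = (
            self.counts.rename_axis("variant_id")
            .reset_index()
            .melt(id_vars="variant_id", var_name="sample_id", value_name="count")
        )
        long = long[long["count"] > 0].sort_values(["variant_id", "sample_id"])
        long.to_csv(counts_path, sep="\t", index=False)
        self.samples.rename_axis("sample_id").reset_index().to_csv(
            samples_path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(
        cls, counts_path: str | Path, samples_path: str | Path
    ) -> "AbundanceMatrix":
        long = pd.read_csv(counts_path, sep="\t")
        for col in ("variant_id", "sample_id", "count"):
            if col not in long.columns:
                raise ValueError(f"counts table lacks required column {col!r}")
        samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
        counts = (
            long.pivot_table(
                index="variant_id", columns="sample_id", values="count", fill_value=0,
                aggfunc="sum",
            )
            .reindex(columns=samples.index, fill_value=0)
        )
        return cls(counts, samples)
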