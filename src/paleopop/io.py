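"""Readers/writers and run manifests.

FASTA via Biopython, Newick/NEXUS tree samples via dendropy (the NEXUS
translate-table dialect emitted by Bayesian phylogenetics software is
handled by dendropy's nexus reader), TSV via pandas with explicit
required-column checks, YAML study configurations, and a JSON manifest
(config hash, seed, package and library versions, input checksums) written
next to every CLI run so outputs are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coalescent import TimedTree

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_trees",
    "write_trees",
    "read_timed_trees",
    "read_table",
    "write_table",
    "read_config",
    "write_manifest",
    "sha256_file",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=str(i), description="") for i, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_trees(path: str | Path, schema: str | None = None) -> dendropy.TreeList:
    """Read a tree sample; schema inferred from the suffix when omitted."""
    if schema is None:
        suffix = Path(path).suffix.lower()
        schema = "nexus" if suffix in (".nex", ".nexus", ".trees", ".t") else "newick"
    return dendropy.TreeList.get(path=str(path), schema=schema)


def write_trees(trees, path: str | Path, schema: str = "newick") -> None:
    tl = dendropy.TreeList()
    for t in trees:
        tl.append(t.tree if isinstance(t, TimedTree) else t, taxon_import_strategy="add")
    tl.write(path=str(path), schema=schema, suppress_rooting=True)


def read_timed_trees(
    tree_path: str | Path,
    tip_dates: dict[str, float] | pd.DataFrame,
    most_recent_date: float | None = None,
    schema: str | None = None,
) -> list[TimedTree]:
    """Read a tree sample and attach tip deposition dates.

    ``tip_dates`` is either a tip -> date map or a DataFrame with columns
    ``tip_id`` and ``date_CE`` (the sidecar TSV convention: dates live
    beside the trees, never inside tip labels).
    """
    if isinstance(tip_dates, pd.DataFrame):
        for col in ("tip_id", "date_CE"):
            if col not in tip_dates.columns:
                raise ValueError(f"tip-date table lacks required column {col!r}")
        tip_dates = dict(zip(tip_dates["tip_id"].astype(str), tip_dates["date_CE"]))
    if most_recent_date is None:
        most_recent_date = max(tip_dates.values())
    return [
        TimedTree(t, most_recent_date, tip_dates) for t in read_trees(tree_path, schema)
    ]


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: int | None,
    config: dict | None = None,
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
) -> Path:
    """Write run metadata (config hash, seed, versions, checksums)."""
    import numpy
    import scipy
    import sklearn

    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config or {}, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "versions": {
            "paleopop": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "dendropy": dendropy.__version__,
        },
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "outputs": {str(p): sha256_file(p) for p in outputs},
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
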