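"""Shared helpers: named RNG sub-streams and delimited-text I/O conventions.

All tabular artifacts are TSV.  Feature matrices are oriented samples x
features with the sample ID as index; missing measurements are NaN.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "substream",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a master seed.

    Streams are keyed by name so re-running a single stage draws the same
    numbers regardless of what ran before it.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples x features TSV (first column = sample ID)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> pd.DataFrame:
    """Read pathway sets from an (extended) GMT file.

    Columns: pathway_id, category (the GMT description slot), members
    (list of feature IDs).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            rows.append(
                {"pathway_id": parts[0], "category": parts[1], "members": parts[2:]}
            )
    return pd.DataFrame(rows, columns=["pathway_id", "category", "members"])


def write_gmt(sets: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for _, row in sets.iterrows():
            fh.write("\t".join([row["pathway_id"], row["category"], *row["members"]]) + "\n")
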