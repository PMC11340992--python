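"""Plain-text readers and writers for cohort artifacts.

All formats are human-inspectable: square TSV connectivity matrices with
node ids as the first row and column and NA on the diagonal, CSV phenotype
and atlas tables, and edge masks in two equivalent renderings (binary TSV
matrix and an edge-list CSV of ``node_i, node_j, polarity`` pairs with
i < j, 0-based node ids).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import CohortConnectomes, ConnectivityMatrix
from .cpm import EdgeMask

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_cohort_dir",
    "read_timeseries_tsv",
    "read_phenotypes",
    "write_mask",
    "read_mask",
    "config_hash",
]


def read_matrix_tsv(path) -> ConnectivityMatrix:
    """Read one participant matrix (participant id = file stem)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    node_ids = df.index.to_numpy(dtype=int)
    cols = df.columns.to_numpy(dtype=int)
    if not np.array_equal(node_ids, cols):
        raise ValueError(f"{path}: row and column node ids differ")
    return ConnectivityMatrix(
        participant_id=path.stem, node_ids=node_ids, z=df.to_numpy(dtype=float)
    )


def write_matrix_tsv(matrix: ConnectivityMatrix, path) -> None:
    pd.DataFrame(matrix.z, index=matrix.node_ids, columns=matrix.node_ids).to_csv(
        path, sep="\t", na_rep="NA", index_label="node_id", float_format="%.10g"
    )


def read_cohort_dir(matrices_dir) -> CohortConnectomes:
    """Read every ``*.tsv`` matrix in a directory (sorted by filename)."""
    d = Path(matrices_dir)
    paths = sorted(d.glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no .tsv matrices found in {d}")
    return CohortConnectomes([read_matrix_tsv(p) for p in paths])


def read_timeseries_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a node x time TSV (first column node_id) -> (node_ids, data)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return df.index.to_numpy(dtype=int), df.to_numpy(dtype=float)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" not in df.columns:
        raise ValueError(f"{path}: phenotype table lacks participant_id")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_mask(mask: EdgeMask, prefix) -> None:
    """Write both renderings: ``<prefix>.matrix.tsv`` and ``<prefix>.edges.csv``."""
    prefix = Path(prefix)
    pd.DataFrame(
        mask.to_matrix(), index=mask.node_ids, columns=mask.node_ids
    ).to_csv(prefix.with_suffix(".matrix.tsv"), sep="\t", index_label="node_id")
    df = pd.DataFrame(sorted(mask.edges), columns=["node_i", "node_j"])
    df["polarity"] = mask.polarity
    df.to_csv(prefix.with_suffix(".edges.csv"), index=False)


def read_mask(
    path, polarity: str | None = None, node_ids: Sequence[int] | None = None
) -> EdgeMask:
    """Read a mask from either rendering (detected by extension)."""
    path = Path(path)
    if path.suffix == ".tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = df.index.to_numpy(dtype=int)
        if polarity is None:
            raise ValueError("polarity must be given when reading a matrix mask")
        return EdgeMask.from_matrix(df.to_numpy(dtype=int), ids, polarity)
    df = pd.read_csv(path)
    pols = set(df["polarity"]) if "polarity" in df.columns and len(df) else set()
    if polarity is None:
        if len(pols) > 1:
            raise ValueError(f"{path}: mixed polarities {pols}; pass polarity=")
        polarity = pols.pop() if pols else "high"
    edges = frozenset(zip(df["node_i"].astype(int), df["node_j"].astype(int)))
    if node_ids is None:
        node_ids = sorted({n for e in edges for n in e})
    return EdgeMask(polarity=polarity, edges=edges, node_ids=tuple(node_ids))


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
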