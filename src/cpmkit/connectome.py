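"""Connectivity-matrix construction, node harmonization, and cohort QC.

A connectome here is a symmetric node-by-node matrix of Fisher
z-transformed Pearson correlations between regional BOLD time courses.
The diagonal is undefined (a node's correlation with itself carries no
information) and is stored as NaN; every summary in this package excludes
it.  Cohorts are harmonized to a common node list by dropping any parcel
that is absent from too many participants, and participants are screened
on head motion (mean framewise displacement) and a coverage flag before
any modeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NodeAtlas",
    "ConnectivityMatrix",
    "CohortConnectomes",
    "QCResult",
    "fisher_z_connectivity",
    "detect_missing_nodes",
    "harmonize_nodes",
    "qc_filter",
    "CLIP_EPS",
]

#: correlations are clipped to |r| <= 1 - CLIP_EPS before the z-transform so
#: that perfectly (anti)correlated time series map to a large finite value
#: (atanh(1 - 1e-7) ~= 8.4) instead of +/-inf.
CLIP_EPS = 1e-7


@dataclass(frozen=True)
class NodeAtlas:
    """Lookup from node id to canonical-network label.

    Parameters
    ----------
    table : pandas.DataFrame
        Two columns, ``node_id`` (unique integers) and ``network_name``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        cols = {"node_id", "network_name"}
        if not cols.issubset(self.table.columns):
            raise ValueError(f"atlas table requires columns {sorted(cols)}")
        if self.table["node_id"].duplicated().any():
            dupes = self.table.loc[self.table["node_id"].duplicated(), "node_id"]
            raise ValueError(f"duplicate atlas node ids: {sorted(set(dupes))}")

    @property
    def node_ids(self) -> np.ndarray:
        return self.table["node_id"].to_numpy()

    @property
    def networks(self) -> list[str]:
        return sorted(self.table["network_name"].unique())

    def nodes_in(self, network_name: str) -> list[int]:
        """Node ids labeled ``network_name`` (empty list if none)."""
        sel = self.table["network_name"] == network_name
        return [int(v) for v in self.table.loc[sel, "node_id"]]

    @classmethod
    def from_csv(cls, path) -> "NodeAtlas":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class ConnectivityMatrix:
    """One participant's symmetric Fisher-z connectivity matrix.

    ``z[i, j]`` is the Fisher z-transformed Pearson correlation between the
    time courses of ``node_ids[i]`` and ``node_ids[j]``; the diagonal is NaN.
    A node that was absent for this participant appears as an all-NaN
    row/column.
    """

    participant_id: str
    node_ids: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.node_ids)
        if self.z.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.z.shape} does not match {n} node ids"
            )
        if n:
            if not np.array_equal(np.isnan(self.z), np.isnan(self.z.T)):
                raise ValueError(
                    f"matrix for {self.participant_id} has an asymmetric NaN pattern"
                )
            d = self.z - self.z.T
            d = d[np.isfinite(d)]
            if d.size and np.max(np.abs(d)) > 1e-10:
                raise ValueError(f"matrix for {self.participant_id} is not symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def missing_nodes(self) -> list[int]:
        """Node ids whose entire row (off-diagonal) is NaN."""
        n = self.n_nodes
        if n == 0:
            return []
        off = ~np.eye(n, dtype=bool)
        masked = np.where(off, self.z, np.nan)
        all_nan = np.all(np.isnan(masked), axis=1)
        return [int(i) for i in self.node_ids[all_nan]]

    def subset(self, keep_ids: Sequence[int]) -> "ConnectivityMatrix":
        """Restrict to ``keep_ids``, preserving the current node order."""
        keep = np.isin(self.node_ids, list(keep_ids))
        return ConnectivityMatrix(
            participant_id=self.participant_id,
            node_ids=self.node_ids[keep],
            z=self.z[np.ix_(keep, keep)],
        )


@dataclass
class CohortConnectomes:
    """A list of connectivity matrices sharing one node ordering."""

    matrices: list[ConnectivityMatrix]

    def __post_init__(self) -> None:
        if self.matrices:
            ref = self.matrices[0].node_ids
            for m in self.matrices[1:]:
                if not np.array_equal(m.node_ids, ref):
                    raise ValueError(
                        f"participant {m.participant_id} has a different node "
                        "ordering; harmonize the cohort first"
                    )

    @property
    def node_ids(self) -> np.ndarray:
        if not self.matrices:
            return np.array([], dtype=int)
        return self.matrices[0].node_ids

    @property
    def participant_ids(self) -> list[str]:
        return [m.participant_id for m in self.matrices]

    @property
    def n_participants(self) -> int:
        return len(self.matrices)

    def stack(self) -> np.ndarray:
        """(n_participants, n_nodes, n_nodes) array view of the cohort."""
        return np.stack([m.z for m in self.matrices])

    def edge_table(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized upper-triangle view.

        Returns
        -------
        values : (n_participants, n_edges) array of z-values.
        pairs : (n_edges, 2) array of node-id pairs, id_i < id_j.
        """
        n = len(self.node_ids)
        iu, ju = np.triu_indices(n, k=1)
        z3 = self.stack()
        values = z3[:, iu, ju]
        ids = self.node_ids
        pairs = np.column_stack([ids[iu], ids[ju]])
        # canonical orientation: smaller node id first
        flip = pairs[:, 0] > pairs[:, 1]
        pairs[flip] = pairs[flip][:, ::-1]
        return values, pairs

    def subset_participants(self, participant_ids: Iterable[str]) -> "CohortConnectomes":
        wanted = set(participant_ids)
        return CohortConnectomes(
            [m for m in self.matrices if m.participant_id in wanted]
        )


def fisher_z_connectivity(
    timeseries: np.ndarray,
    node_ids: Sequence[int] | None = None,
    participant_id: str = "",
) -> ConnectivityMatrix:
    """Fisher z-transformed Pearson correlation between every node pair.

    Parameters
    ----------
    timeseries : (n_nodes, n_timepoints) array
        One row per node.  Rows that are entirely NaN are treated as a
        missing node and propagate NaN through their row/column of ``z``.
    node_ids : optional sequence of int
        Defaults to ``0..n_nodes-1``.
    participant_id : str
        Carried through to the result.

    Raises
    ------
    ValueError
        If fewer than 3 timepoints are supplied or any present node has a
        constant time course (its correlation is undefined).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a 2-D node x time array")
    n_nodes, n_t = ts.shape
    if n_t < 3:
        raise ValueError(f"need >= 3 timepoints, got {n_t}")
    if node_ids is None:
        node_ids = np.arange(n_nodes)
    node_ids = np.asarray(node_ids, dtype=int)

    missing = np.all(np.isnan(ts), axis=1)
    present = ~missing
    sd = np.std(ts[present], axis=1)
    if np.any(sd == 0):
        bad = node_ids[present][sd == 0]
        raise ValueError(
            f"constant time series for node(s) {bad.tolist()}: "
            "correlation undefined"
        )

    z = np.full((n_nodes, n_nodes), np.nan)
    if present.sum() >= 2:
        r = np.corrcoef(ts[present])
        r = np.clip(r, -1 + CLIP_EPS, 1 - CLIP_EPS)
        zsub = np.arctanh(r)
        zsub = 0.5 * (zsub + zsub.T)  # enforce bit-exact symmetry
        np.fill_diagonal(zsub, np.nan)
        idx = np.flatnonzero(present)
        z[np.ix_(idx, idx)] = zsub
    return ConnectivityMatrix(participant_id=participant_id, node_ids=node_ids, z=z)


def detect_missing_nodes(cohort: CohortConnectomes) -> dict[str, list[int]]:
    """Map participant id -> node ids with an all-NaN row in their matrix."""
    out: dict[str, list[int]] = {}
    for m in cohort.matrices:
        miss = m.missing_nodes()
        if miss:
            out[m.participant_id] = miss
    return out


def harmonize_nodes(
    cohort: CohortConnectomes,
    missing: Mapping[str, Iterable[int]] | None = None,
    min_participants_missing: int = 3,
) -> tuple[CohortConnectomes, list[int]]:
    """Drop nodes missing from at least ``min_participants_missing`` participants.

    A node absent from that many participants is removed from *every*
    participant so the cohort shares one node list; nodes missing from fewer
    participants are retained.  The surviving node ordering is preserved.

    Parameters
    ----------
    missing : optional mapping participant_id -> iterable of node ids
        If omitted, missingness is detected as all-NaN rows.

    Returns
    -------
    (harmonized cohort, sorted list of removed node ids)
    """
    if missing is None:
        missing = detect_missing_nodes(cohort)
    counts: dict[int, int] = {}
    for nodes in missing.values():
        for nid in set(int(n) for n in nodes):
            counts[nid] = counts.get(nid, 0) + 1
    removed = sorted(n for n, c in counts.items() if c >= min_participants_missing)
    if not removed:
        return cohort, []
    keep = [int(n) for n in cohort.node_ids if n not in set(removed)]
    if not keep:
        raise ValueError("harmonization would remove every node")
    new = CohortConnectomes([m.subset(keep) for m in cohort.matrices])
    return new, removed


@dataclass(frozen=True)
class QCResult:
    """Outcome of cohort-level quality control."""

    retained_ids: list[str]
    n_input: int
    n_coverage_fail: int
    n_fd_fail: int

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)


def qc_filter(phenotypes: pd.DataFrame, fd_threshold: float = 0.15) -> QCResult:
    """Exclude participants with failed coverage or excessive head motion.

    Coverage failures (``coverage_ok == False``) are removed first; among the
    remainder, participants with mean framewise displacement strictly greater
    than ``fd_threshold`` (mm) are removed.  A participant sitting exactly at
    the threshold is retained.  Exclusion reasons never double-count:
    ``n_input - n_retained == n_coverage_fail + n_fd_fail``.
    """
    required = {"participant_id", "mean_fd", "coverage_ok"}
    missing_cols = required - set(phenotypes.columns)
    if missing_cols:
        raise ValueError(f"phenotype table missing columns {sorted(missing_cols)}")
    if phenotypes["mean_fd"].isna().any():
        raise ValueError("mean_fd contains missing values")

    cov_ok = phenotypes["coverage_ok"].astype(bool)
    n_cov_fail = int((~cov_ok).sum())
    survivors = phenotypes[cov_ok]
    fd_ok = survivors["mean_fd"] <= fd_threshold
    n_fd_fail = int((~fd_ok).sum())
    retained = survivors.loc[fd_ok, "participant_id"].astype(str).tolist()
    return QCResult(
        retained_ids=retained,
        n_input=len(phenotypes),
        n_coverage_fail=n_cov_fail,
        n_fd_fail=n_fd_fail,
    )
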