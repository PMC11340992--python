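"""Connectome-based predictive modeling (CPM).

CPM is a supervised procedure for deriving brain-wide predictive models
from functional connectivity: for each leave-one-out fold, every edge is
correlated with the behavioral measure across training participants; edges
with significantly positive correlations form the fold's "high" network and
significantly negative edges the "low" network.  A participant's *network
strength* is the mean Fisher-z value over a network's edges, and a simple
linear model of behavior on training-set strength predicts the held-out
participant.  The final consensus masks keep only edges selected in every
fold, and can then be applied to any compatible cohort to score network
strength.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectome import CohortConnectomes, ConnectivityMatrix

__all__ = [
    "EdgeMask",
    "CPMModel",
    "select_edges",
    "network_strength",
    "train_cpm_loo",
    "apply_model",
    "save_model",
    "load_model",
]

Edge = tuple[int, int]


def _canon(edges: Iterable[Sequence[int]]) -> frozenset[Edge]:
    """Canonical unordered-pair form: (min_id, max_id), 0-based node ids."""
    out = set()
    for i, j in edges:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"self-edge ({i}, {j}) is not allowed")
        out.add((i, j) if i < j else (j, i))
    return frozenset(out)


@dataclass(frozen=True)
class EdgeMask:
    """A binary, symmetric edge set with a polarity label.

    ``edges`` are unordered node-id pairs stored as (i, j) with i < j; the
    matrix rendering over ``node_ids`` is symmetric with ones exactly at the
    mask's edges and zeros elsewhere (diagonal included).
    """

    polarity: str
    edges: frozenset[Edge]
    node_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.polarity not in {"high", "low"}:
            raise ValueError(f"polarity must be 'high' or 'low', got {self.polarity!r}")
        object.__setattr__(self, "edges", _canon(self.edges))
        object.__setattr__(self, "node_ids", tuple(int(n) for n in self.node_ids))
        known = set(self.node_ids)
        stray = {n for e in self.edges for n in e} - known
        if stray:
            raise ValueError(f"mask edges reference unknown node ids {sorted(stray)}")

    def __len__(self) -> int:
        return len(self.edges)

    def to_matrix(self) -> np.ndarray:
        pos = {nid: k for k, nid in enumerate(self.node_ids)}
        n = len(self.node_ids)
        m = np.zeros((n, n), dtype=int)
        for i, j in self.edges:
            m[pos[i], pos[j]] = m[pos[j], pos[i]] = 1
        return m

    @classmethod
    def from_matrix(
        cls, matrix: np.ndarray, node_ids: Sequence[int], polarity: str
    ) -> "EdgeMask":
        m = np.asarray(matrix)
        ids = np.asarray(node_ids, dtype=int)
        if m.shape != (len(ids), len(ids)):
            raise ValueError("mask matrix shape does not match node ids")
        if not np.array_equal(m, m.T):
            raise ValueError("mask matrix must be symmetric")
        iu, ju = np.nonzero(np.triu(m, k=1))
        return cls(polarity=polarity, edges=_canon(zip(ids[iu], ids[ju])), node_ids=ids)

    def restrict_to(self, node_ids: Sequence[int]) -> "EdgeMask":
        """Drop edges incident to any node outside ``node_ids``."""
        keep = set(int(n) for n in node_ids)
        edges = {e for e in self.edges if e[0] in keep and e[1] in keep}
        ids = tuple(n for n in self.node_ids if n in keep)
        return EdgeMask(polarity=self.polarity, edges=frozenset(edges), node_ids=ids)


@dataclass
class CPMModel:
    """Trained CPM: per-fold selections and fits plus consensus masks."""

    per_fold_pos_edges: list[frozenset[Edge]]
    per_fold_neg_edges: list[frozenset[Edge]]
    per_fold_fit: list[dict[str, tuple[float, float] | None]]
    consensus_high: EdgeMask
    consensus_low: EdgeMask
    selection_threshold: float
    n_train: int

    @property
    def n_folds(self) -> int:
        return len(self.per_fold_pos_edges)


def _edge_behavior_correlation(
    values: np.ndarray, behavior: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-tailed p of each edge (column) against behavior.

    Constant edges get r = NaN, p = NaN and are therefore never selected.
    """
    n = len(behavior)
    bc = behavior - behavior.mean()
    sb = np.sqrt((bc**2).sum())
    vc = values - values.mean(axis=0)
    sv = np.sqrt((vc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (vc.T @ bc) / (sv * sb)
    r = np.where(sv == 0, np.nan, r)
    # guard rounding excursions beyond +/-1
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def select_edges(
    cohort: CohortConnectomes,
    behavior: Sequence[float],
    threshold: float = 0.01,
) -> tuple[frozenset[Edge], frozenset[Edge]]:
    """Select behavior-correlated edges.

    Positively selected edges have across-participant Pearson r > 0 with
    two-tailed p below ``threshold``; negative edges analogously with r < 0.
    The two sets are disjoint by construction, and edges that are constant
    across participants are never selected (their correlation is undefined).
    """
    behavior = np.asarray(behavior, dtype=float)
    if cohort.n_participants < 4:
        raise ValueError("edge selection needs at least 4 participants")
    if len(behavior) != cohort.n_participants:
        raise ValueError("behavior length does not match cohort size")
    if np.ptp(behavior) == 0:
        raise ValueError("behavior is constant; edge selection undefined")
    values, pairs = cohort.edge_table()
    r, p = _edge_behavior_correlation(values, behavior)
    sig = p < threshold
    pos = _canon(pairs[sig & (r > 0)])
    neg = _canon(pairs[sig & (r < 0)])
    return pos, neg


def network_strength(matrix: ConnectivityMatrix, mask: EdgeMask) -> float:
    """Mean Fisher-z connectivity over a mask's edges for one participant.

    Each unordered edge contributes once.  Raises if the mask is empty
    (strength is undefined) or references nodes absent from the matrix.
    """
    if len(mask.edges) == 0:
        raise ValueError("empty edge mask: network strength undefined")
    pos = {int(nid): k for k, nid in enumerate(matrix.node_ids)}
    absent = sorted({n for e in mask.edges for n in e} - pos.keys())
    if absent:
        raise ValueError(
            f"mask nodes absent from matrix of {matrix.participant_id}: {absent}"
        )
    ii = np.array([pos[i] for i, _ in mask.edges])
    jj = np.array([pos[j] for _, j in mask.edges])
    return float(np.mean(matrix.z[ii, jj]))


def _strength_from_values(
    values: np.ndarray, pairs: np.ndarray, edges: frozenset[Edge]
) -> np.ndarray:
    """Vectorized mean strength over ``edges`` for each row of ``values``."""
    key = {tuple(p): k for k, p in enumerate(map(tuple, pairs))}
    idx = np.array([key[e] for e in edges])
    return values[:, idx].mean(axis=1)


def train_cpm_loo(
    cohort: CohortConnectomes,
    behavior: Sequence[float],
    threshold: float = 0.01,
) -> tuple[CPMModel, pd.DataFrame]:
    """Train a CPM under leave-one-out cross-validation.

    For each fold, edges are selected on the n-1 training participants, the
    training behavior is regressed on training network strength (ordinary
    least squares, separately per polarity), and the held-out participant's
    behavior is predicted from their own strength.  A fold that selects no
    edges for a polarity contributes an undefined (NaN) prediction and an
    empty set to the consensus intersection.

    Returns
    -------
    model : CPMModel
        Fold logs plus consensus masks (the edges present in every fold).
    predictions : DataFrame
        Columns ``participant_id``, ``pred_high``, ``pred_low``.
    """
    behavior = np.asarray(behavior, dtype=float)
    n = cohort.n_participants
    if n < 5:
        raise ValueError("leave-one-out training needs at least 5 participants")
    if len(behavior) != n:
        raise ValueError("behavior length does not match cohort size")
    values, pairs = cohort.edge_table()

    fold_pos: list[frozenset[Edge]] = []
    fold_neg: list[frozenset[Edge]] = []
    fold_fit: list[dict[str, tuple[float, float] | None]] = []
    preds = {"high": np.full(n, np.nan), "low": np.full(n, np.nan)}

    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        r, p = _edge_behavior_correlation(values[train], behavior[train])
        sig = p < threshold
        pos = _canon(pairs[sig & (r > 0)])
        neg = _canon(pairs[sig & (r < 0)])
        fold_pos.append(pos)
        fold_neg.append(neg)
        fits: dict[str, tuple[float, float] | None] = {}
        for pol, edges in (("high", pos), ("low", neg)):
            if not edges:
                fits[pol] = None
                continue
            s_train = _strength_from_values(values[train], pairs, edges)
            slope, intercept = np.polyfit(s_train, behavior[train], deg=1)
            fits[pol] = (float(slope), float(intercept))
            s_test = _strength_from_values(values[i : i + 1], pairs, edges)[0]
            preds[pol][i] = slope * s_test + intercept
        fold_fit.append(fits)

    if all(not e for e in fold_pos) and all(not e for e in fold_neg):
        raise ValueError(
            "no edges selected in any fold for either polarity; "
            "threshold too strict or no signal"
        )

    node_ids = tuple(int(v) for v in cohort.node_ids)
    consensus_high = EdgeMask(
        "high", frozenset.intersection(*fold_pos), node_ids=node_ids
    )
    consensus_low = EdgeMask(
        "low", frozenset.intersection(*fold_neg), node_ids=node_ids
    )
    model = CPMModel(
        per_fold_pos_edges=fold_pos,
        per_fold_neg_edges=fold_neg,
        per_fold_fit=fold_fit,
        consensus_high=consensus_high,
        consensus_low=consensus_low,
        selection_threshold=float(threshold),
        n_train=n,
    )
    predictions = pd.DataFrame(
        {
            "participant_id": cohort.participant_ids,
            "pred_high": preds["high"],
            "pred_low": preds["low"],
        }
    )
    return model, predictions


def apply_model(
    cohort: CohortConnectomes,
    model: CPMModel,
    include_combined: bool = False,
) -> pd.DataFrame:
    """Score every participant's network strength under the consensus masks.

    Returns one row per participant with ``high_strength`` and
    ``low_strength`` (mean z over the consensus high/low edges).  An empty
    consensus mask yields NaN for that polarity with a warning; if both are
    empty this is an error.  ``include_combined`` adds
    ``combined_strength = high_strength - low_strength``, an optional
    summary contrasting the two networks.
    """
    masks = {"high_strength": model.consensus_high, "low_strength": model.consensus_low}
    if all(len(m) == 0 for m in masks.values()):
        raise ValueError("both consensus masks are empty; nothing to score")
    out: dict[str, list] = {"participant_id": cohort.participant_ids}
    for col, mask in masks.items():
        if len(mask) == 0:
            warnings.warn(
                f"consensus mask for {mask.polarity!r} is empty; "
                f"{col} is undefined (NaN)",
                stacklevel=2,
            )
            out[col] = [np.nan] * cohort.n_participants
        else:
            out[col] = [network_strength(m, mask) for m in cohort.matrices]
    df = pd.DataFrame(out)
    if include_combined:
        df["combined_strength"] = df["high_strength"] - df["low_strength"]
    return df


# ---------------------------------------------------------------------------
# model bundle persistence (directory of plain-text files)
# ---------------------------------------------------------------------------


def _write_edges_csv(path: Path, edges: frozenset[Edge], polarity: str) -> None:
    df = pd.DataFrame(sorted(edges), columns=["node_i", "node_j"])
    df["polarity"] = polarity
    df.to_csv(path, index=False)


def save_model(model: CPMModel, out_dir) -> None:
    """Write a model bundle: consensus masks, fold logs, and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .io import write_mask  # deferred to avoid import cycle

    write_mask(model.consensus_high, out / "consensus_high")
    write_mask(model.consensus_low, out / "consensus_low")
    folds = []
    for k in range(model.n_folds):
        fit = model.per_fold_fit[k]
        folds.append(
            {
                "fold": k,
                "pos_edges": sorted(map(list, model.per_fold_pos_edges[k])),
                "neg_edges": sorted(map(list, model.per_fold_neg_edges[k])),
                "fit_high": list(fit["high"]) if fit.get("high") else None,
                "fit_low": list(fit["low"]) if fit.get("low") else None,
            }
        )
    (out / "folds.json").write_text(json.dumps(folds, indent=1))
    manifest = {
        "selection_threshold": model.selection_threshold,
        "n_train": model.n_train,
        "n_folds": model.n_folds,
        "node_ids": list(model.consensus_high.node_ids),
        "consensus_high_edges": len(model.consensus_high),
        "consensus_low_edges": len(model.consensus_low),
    }
    (out / "model.json").write_text(json.dumps(manifest, indent=1))


def load_model(model_dir) -> CPMModel:
    d = Path(model_dir)
    manifest = json.loads((d / "model.json").read_text())
    from .io import read_mask

    node_ids = tuple(manifest["node_ids"])
    high = read_mask(d / "consensus_high.edges.csv", node_ids=node_ids)
    low = read_mask(d / "consensus_low.edges.csv", node_ids=node_ids)
    folds = json.loads((d / "folds.json").read_text())
    return CPMModel(
        per_fold_pos_edges=[_canon(f["pos_edges"]) if f["pos_edges"] else frozenset() for f in folds],
        per_fold_neg_edges=[_canon(f["neg_edges"]) if f["neg_edges"] else frozenset() for f in folds],
        per_fold_fit=[
            {
                "high": tuple(f["fit_high"]) if f["fit_high"] else None,
                "low": tuple(f["fit_low"]) if f["fit_low"] else None,
            }
            for f in folds
        ],
        consensus_high=high,
        consensus_low=low,
        selection_threshold=manifest["selection_threshold"],
        n_train=manifest["n_train"],
    )
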