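"""Synthetic connectome cohorts with planted, recoverable structure.

The generator emulates the statistical shape of a resting-state aging
cohort as consumed by the analysis chain: symmetric Fisher-z connectivity
matrices on a ~268-node functional parcellation with a handful of nodes
missing from a few participants, a latent behavioral trait that drives a
set of "signal" edges up (positive polarity) or down (negative polarity), a
positively skewed biomarker monotonically coupled to the trait, cognitive
composites negatively coupled to it, and a mean framewise-displacement
motion covariate confounded with high-network strength.  Every planted
quantity is returned in a :class:`GroundTruth` record so recovery can be
tested against what was actually simulated.

The dependence structure of (behavior, motion, biomarker) is a Gaussian
copula: a trivariate standard normal with correlation matrix

    [[1,      r_bf,   r_bm],
     [r_bf,   1,      r_fm],
     [r_bm,   r_fm,   1]]

where ``r_bm = 2*sin(pi*target_strength_outcome_rho/6)`` converts the
requested Spearman correlation to the latent Pearson scale (exact for
bivariate normals), ``r_bf`` is the motion confound, and the
motion-biomarker entry ``r_fm`` is solved so that the behavior-biomarker
correlation is the same marginally and partially given motion:

    r_fm = r_bm*r_bf * (1 - sqrt((1 - r_bf^2)(1 - r_bm^2)))
           / (r_bf^2 + r_bm^2*(1 - r_bf^2))

This makes ``target_strength_outcome_rho`` mean one thing to every
consumer: the planted rank correlation between signal-edge strength and
the biomarker, whether or not motion is partialed out.  Because the
strength score carries residual edge noise of ``edge_noise_sd/sqrt(K)``
over ``K`` signal edges, the latent behavior couplings are pre-inflated by
the analytic attenuation factor so the *strength-level* correlations land
on their targets.  Monotone marginal transforms (lognormal motion,
exponential-skew biomarker) preserve the planted rank correlations exactly
in expectation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectome import CohortConnectomes, ConnectivityMatrix, NodeAtlas

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_cohort",
    "write_cohort",
    "make_atlas",
    "CANONICAL_NETWORKS",
]

#: canonical-network labels with approximate node shares of a 268-node
#: functional parcellation (default mode fixed near 35/268; the rest split
#: the remainder in plausible proportions).
CANONICAL_NETWORKS: dict[str, float] = {
    "DMN": 35 / 268,
    "VAN": 28 / 268,
    "DAN": 28 / 268,
    "FPN": 30 / 268,
    "visual": 40 / 268,
    "somatomotor": 45 / 268,
    "subcortical": 62 / 268,
}

#: participants whose mean framewise displacement exceeds this value (mm)
#: are flagged for exclusion downstream.
FD_THRESHOLD_MM = 0.15


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    The defaults describe the cohort this package's analyses are sized for:
    a 324-participant roster on a 268-node parcellation, 134 positive and
    134 negative signal edges, a motion-strength confound of 0.48, six
    missing-prone nodes, and exclusion fractions of 5/324 (coverage) and
    30/324 (motion).

    Parameters
    ----------
    n_timepoints : int
        0 emits connectivity matrices directly; a positive value emits
        node x time series whose empirical connectivity approximates the
        planted matrices (sampling noise ~ 1/sqrt(n_timepoints)).
    effect_size : float
        Additive coupling (z-units per SD of behavior) between the latent
        behavior and each signal edge.
    target_strength_outcome_rho : float
        Planted Spearman correlation between high-signal-edge mean strength
        and the biomarker.
    motion_confound_rho : float
        Planted latent correlation between mean FD and behavior (hence,
        approximately, high-model strength).
    biomarker_skew : float
        Log-scale SD of the biomarker; larger -> more right skew.
    frac_missing_nodes : float
        Fraction of nodes absent from (exactly) three random participants.
    frac_fd_fail, frac_coverage_fail : float
        Exact fractions of the roster failing each QC rule (rounded to
        counts; motion failures are drawn from coverage-passing rows).
    """

    seed: int
    n_participants: int = 324
    n_nodes: int = 268
    n_timepoints: int = 0
    n_signal_pos_edges: int = 134
    n_signal_neg_edges: int = 134
    effect_size: float = 0.08
    target_strength_outcome_rho: float = 0.4
    motion_confound_rho: float = 0.48
    biomarker_skew: float = 1.0
    frac_missing_nodes: float = 6 / 268
    frac_fd_fail: float = 30 / 324
    frac_coverage_fail: float = 5 / 324
    # secondary shape parameters
    edge_noise_sd: float = 0.10
    baseline_mean: float = 0.30
    baseline_sd: float = 0.15
    cognition_coupling: float = 0.35
    behavior_noise_sd: float = 0.20
    fd_log_sd: float = 0.45

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_nodes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_timepoints < 0:
            raise ValueError("n_timepoints must be >= 0 (0 emits matrices)")
        for name in ("n_signal_pos_edges", "n_signal_neg_edges"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_missing_nodes", "frac_fd_fail", "frac_coverage_fail"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.n_signal_pos_edges + self.n_signal_neg_edges > max_edges:
            raise ValueError(
                f"{self.n_signal_pos_edges} + {self.n_signal_neg_edges} signal "
                f"edges exceed the {max_edges} available node pairs"
            )
        if abs(self.target_strength_outcome_rho) > 1 or abs(self.motion_confound_rho) > 1:
            raise ValueError("planted correlations must lie in [-1, 1]")


@dataclass
class GroundTruth:
    """What was actually planted in one generated cohort."""

    signal_pos_edges: frozenset[tuple[int, int]]
    signal_neg_edges: frozenset[tuple[int, int]]
    latent_behavior: np.ndarray
    planted_rhos: dict[str, float]
    missing_nodes: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.signal_pos_edges & self.signal_neg_edges:
            raise ValueError("positive and negative signal edge sets overlap")


def _strength_attenuation(config: SimConfig) -> float:
    """Correlation shrinkage of the positive-signal-edge mean strength.

    Averaging ``K = n_signal_pos_edges`` edges leaves residual noise of
    ``edge_noise_sd / sqrt(K)`` on top of the ``effect_size * behavior``
    signal, so any correlation with the latent behavior is multiplied by
    ``effect_size / hypot(effect_size, edge_noise_sd / sqrt(K))``.
    """
    if config.effect_size == 0 or config.n_signal_pos_edges == 0:
        return 1.0
    return float(
        config.effect_size
        / np.hypot(
            config.effect_size,
            config.edge_noise_sd / np.sqrt(config.n_signal_pos_edges),
        )
    )


def _copula_correlation(config: SimConfig) -> np.ndarray:
    """Latent 3x3 correlation of (behavior, fd, biomarker); raises if infeasible.

    The planted targets refer to the *strength* score, so the latent
    behavior couplings are inflated by the analytic edge-noise attenuation
    factor; the fd-biomarker entry is the (smaller) root of the quadratic
    that makes the strength-biomarker partial correlation given fd equal to
    the marginal one, so the planted target survives motion adjustment.
    """
    r_sm = 2.0 * np.sin(np.pi * config.target_strength_outcome_rho / 6.0)
    r_sf = config.motion_confound_rho
    denom = r_sf**2 + r_sm**2 * (1.0 - r_sf**2)
    if denom == 0.0:
        r_fm = 0.0
    else:
        r_fm = (
            r_sm * r_sf
            * (1.0 - np.sqrt((1.0 - r_sf**2) * (1.0 - r_sm**2)))
            / denom
        )
    a = _strength_attenuation(config)
    r_bm = r_sm / a
    r_bf = r_sf / a
    if abs(r_bm) >= 1.0 or abs(r_bf) >= 1.0:
        raise ValueError(
            "requested correlation structure is infeasible after edge-noise "
            f"compensation: target_strength_outcome_rho="
            f"{config.target_strength_outcome_rho}, "
            f"motion_confound_rho={config.motion_confound_rho}, "
            f"effect_size={config.effect_size}, "
            f"edge_noise_sd={config.edge_noise_sd}"
        )
    R = np.array([[1.0, r_bf, r_bm], [r_bf, 1.0, r_fm], [r_bm, r_fm, 1.0]])
    if np.linalg.eigvalsh(R)[0] < -1e-10:
        raise ValueError(
            "requested correlation structure is not positive semidefinite: "
            f"target_strength_outcome_rho={config.target_strength_outcome_rho}, "
            f"motion_confound_rho={config.motion_confound_rho}"
        )
    return R


def _fd_from_latent(
    fd_latent: np.ndarray, coverage_ok: np.ndarray, n_fd_fail: int, log_sd: float
) -> np.ndarray:
    """Map the motion latent to mean FD (mm), monotonically, with an exact
    count of coverage-passing participants above the exclusion threshold.

    Coverage-passing participants are ranked on the latent and placed at
    lognormal plotting-position quantiles; the location parameter is solved
    so exactly ``n_fd_fail`` of them land above ``FD_THRESHOLD_MM``.
    """
    m = int(coverage_ok.sum())
    if m == 0:
        return np.exp(np.log(0.08) + log_sd * fd_latent)
    n_fd_fail = min(n_fd_fail, m)
    if n_fd_fail == 0:
        p_thresh = (m - 0.25) / m
    elif n_fd_fail == m:
        p_thresh = 0.25 / m
    else:
        p_thresh = (m - n_fd_fail) / m
    mu = np.log(FD_THRESHOLD_MM) - log_sd * sps.norm.ppf(p_thresh)

    fd = np.empty_like(fd_latent)
    lat_ok = fd_latent[coverage_ok]
    order = np.argsort(lat_ok)
    ranks = np.empty(m, dtype=float)
    ranks[order] = np.arange(m)
    pp = (ranks + 0.5) / m
    fd[coverage_ok] = np.exp(mu + log_sd * sps.norm.ppf(pp))
    # coverage failures never reach the motion rule; give them the same
    # marginal directly from their latent
    fd[~coverage_ok] = np.exp(mu + log_sd * fd_latent[~coverage_ok])
    return fd


def _nearest_correlation(r: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped positive-definite correlation matrix."""
    w, v = np.linalg.eigh(r)
    w = np.clip(w, eps, None)
    a = (v * w) @ v.T
    d = np.sqrt(np.diag(a))
    return a / np.outer(d, d)


def generate_cohort(
    config: SimConfig,
) -> tuple[CohortConnectomes, pd.DataFrame, GroundTruth]:
    """Generate one cohort of connectomes, phenotypes, and ground truth.

    All randomness comes from a single ``numpy.random.default_rng(seed)``
    stream with a fixed draw order, so identical configs yield identical
    cohorts.  Signal-edge values are ``baseline + effect_size*behavior``
    (positive polarity; subtracted for negative) plus Gaussian edge noise;
    the biomarker is ``exp(biomarker_skew * latent)``; composites are
    negatively coupled to behavior; QC failures occur at exact configured
    counts.

    Returns
    -------
    (cohort, phenotypes, truth)
        Phenotype columns: participant_id, behavior, biomarker, pacc_like,
        mem_like, ef_like, mean_fd, coverage_ok, group.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_participants, config.n_nodes
    R = _copula_correlation(config)

    # --- draw order is part of the determinism contract -------------------
    latent = rng.standard_normal((3, n))
    latent = np.linalg.cholesky(R) @ latent
    behavior_latent, fd_latent, bio_latent = latent

    iu, ju = np.triu_indices(p, k=1)
    n_edges = len(iu)
    n_sig = config.n_signal_pos_edges + config.n_signal_neg_edges
    sig_idx = rng.choice(n_edges, size=n_sig, replace=False)
    pos_idx = sig_idx[: config.n_signal_pos_edges]
    neg_idx = sig_idx[config.n_signal_pos_edges :]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_edges)
    values = baseline[None, :] + config.edge_noise_sd * rng.standard_normal((n, n_edges))
    values[:, pos_idx] += config.effect_size * behavior_latent[:, None]
    values[:, neg_idx] -= config.effect_size * behavior_latent[:, None]

    # --- QC flags at exact counts -----------------------------------------
    n_cov_fail = int(round(config.frac_coverage_fail * n))
    n_fd_fail = int(round(config.frac_fd_fail * n))
    coverage_ok = np.ones(n, dtype=bool)
    if n_cov_fail:
        coverage_ok[rng.choice(n, size=n_cov_fail, replace=False)] = False
    mean_fd = _fd_from_latent(fd_latent, coverage_ok, n_fd_fail, config.fd_log_sd)

    # --- missing nodes: each missing-prone node absent from 3 participants -
    n_missing_nodes = int(round(config.frac_missing_nodes * p))
    missing: dict[int, list[int]] = {}
    if n_missing_nodes:
        if n < 3:
            raise ValueError("missing-node simulation needs >= 3 participants")
        # plant missingness among QC-passing participants so that the
        # "missing from >= 3 analyzed participants" rule fires even after
        # participant exclusions
        passing = np.flatnonzero(coverage_ok & (mean_fd <= FD_THRESHOLD_MM))
        pool = passing if len(passing) >= 3 else np.arange(n)
        miss_nodes = rng.choice(p, size=n_missing_nodes, replace=False)
        for node in miss_nodes:
            who = rng.choice(pool, size=3, replace=False)
            missing[int(node)] = sorted(int(w) for w in who)

    # --- phenotypes --------------------------------------------------------
    biomarker = np.exp(config.biomarker_skew * bio_latent)
    c = config.cognition_coupling
    comp_noise = np.sqrt(1.0 - c**2)
    composites = {
        name: -c * behavior_latent + comp_noise * rng.standard_normal(n)
        for name in ("pacc_like", "mem_like", "ef_like")
    }
    behavior_obs = behavior_latent + config.behavior_noise_sd * rng.standard_normal(n)

    # diagnostic labels follow biomarker rank with CN/MCI/AD shares ~ .52/.38/.10
    qtiles = np.searchsorted(
        np.quantile(biomarker, [149 / 289, 258 / 289]), biomarker, side="right"
    )
    group = np.array(["CN", "MCI", "AD"])[qtiles]

    pids = [f"sub-{k:04d}" for k in range(n)]
    phenotypes = pd.DataFrame(
        {
            "participant_id": pids,
            "behavior": behavior_obs,
            "biomarker": biomarker,
            "pacc_like": composites["pacc_like"],
            "mem_like": composites["mem_like"],
            "ef_like": composites["ef_like"],
            "mean_fd": mean_fd,
            "coverage_ok": coverage_ok,
            "group": group,
        }
    )

    # --- assemble matrices (or time series -> matrices) --------------------
    node_ids = np.arange(p)
    matrices: list[ConnectivityMatrix] = []
    part_missing: dict[int, set[int]] = {}
    for node, who in missing.items():
        for w in who:
            part_missing.setdefault(w, set()).add(node)

    if config.n_timepoints == 0:
        for k, pid in enumerate(pids):
            z = np.full((p, p), np.nan)
            z[iu, ju] = values[k]
            z[ju, iu] = values[k]
            drop = part_missing.get(k)
            if drop:
                idx = sorted(drop)
                z[idx, :] = np.nan
                z[:, idx] = np.nan
            matrices.append(ConnectivityMatrix(pid, node_ids, z))
    else:
        if config.n_timepoints < p + 1:
            raise ValueError(
                "time-series mode needs n_timepoints > n_nodes for a "
                "full-rank empirical correlation"
            )
        from .connectome import fisher_z_connectivity

        for k, pid in enumerate(pids):
            z = np.zeros((p, p))
            z[iu, ju] = values[k]
            z[ju, iu] = values[k]
            r = np.tanh(z)
            np.fill_diagonal(r, 1.0)
            L = np.linalg.cholesky(_nearest_correlation(r))
            ts = L @ rng.standard_normal((p, config.n_timepoints))
            drop = part_missing.get(k)
            if drop:
                ts[sorted(drop), :] = np.nan
            matrices.append(
                fisher_z_connectivity(ts, node_ids=node_ids, participant_id=pid)
            )

    cohort = CohortConnectomes(matrices)
    truth = GroundTruth(
        signal_pos_edges=frozenset(
            (int(iu[e]), int(ju[e])) for e in pos_idx
        ),
        signal_neg_edges=frozenset(
            (int(iu[e]), int(ju[e])) for e in neg_idx
        ),
        latent_behavior=behavior_latent.copy(),
        planted_rhos={
            "strength_vs_biomarker_spearman": config.target_strength_outcome_rho,
            "fd_vs_behavior_latent": config.motion_confound_rho,
            "behavior_vs_composites": -config.cognition_coupling,
        },
        missing_nodes={node: [pids[w] for w in who] for node, who in missing.items()},
    )
    return cohort, phenotypes, truth


def make_atlas(
    node_ids: Sequence[int],
    network_shares: dict[str, float] | None = None,
) -> NodeAtlas:
    """Assign nodes to canonical networks in contiguous blocks.

    Block sizes follow ``network_shares`` (default
    :data:`CANONICAL_NETWORKS`), mimicking the spatially contiguous layout
    of a functional parcellation.  The assignment is deterministic in the
    node ordering.
    """
    shares = network_shares or CANONICAL_NETWORKS
    ids = [int(v) for v in node_ids]
    n = len(ids)
    names = list(shares)
    raw = np.array([shares[k] for k in names]) / sum(shares.values()) * n
    sizes = np.floor(raw + 1e-9).astype(int)
    # distribute the rounding remainder over the largest networks
    for k in np.argsort(sizes)[::-1][: n - sizes.sum()]:
        sizes[k] += 1
    labels = np.repeat(names, sizes)
    return NodeAtlas(pd.DataFrame({"node_id": ids, "network_name": labels}))


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------


def _matrix_frame(m: ConnectivityMatrix) -> pd.DataFrame:
    return pd.DataFrame(m.z, index=m.node_ids, columns=m.node_ids)


def write_cohort(
    cohort: CohortConnectomes,
    phenotypes: pd.DataFrame,
    truth: GroundTruth,
    out_dir,
    config: SimConfig | None = None,
) -> dict:
    """Write a cohort to plain-text files and return the manifest.

    Layout: ``matrices/<participant_id>.tsv`` (square TSV, node ids as the
    first row and column, diagonal written as NA), ``phenotypes.csv``,
    ``ground_truth.json`` (signal edges with polarity, latent behavior,
    planted correlations, missing-node record), ``atlas.csv`` and
    ``manifest.json`` (file list plus seed).
    """
    if cohort.n_participants == 0:
        raise ValueError("refusing to write an empty cohort")
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)

    files = []
    for m in cohort.matrices:
        rel = f"matrices/{m.participant_id}.tsv"
        _matrix_frame(m).to_csv(
            out / rel, sep="\t", na_rep="NA", index_label="node_id",
            float_format="%.10g",
        )
        files.append(rel)

    phenotypes.to_csv(out / "phenotypes.csv", index=False, float_format="%.10g")
    files.append("phenotypes.csv")

    atlas = make_atlas(cohort.node_ids)
    atlas.to_csv(out / "atlas.csv")
    files.append("atlas.csv")

    gt = {
        "signal_edges": (
            [[i, j, "high"] for i, j in sorted(truth.signal_pos_edges)]
            + [[i, j, "low"] for i, j in sorted(truth.signal_neg_edges)]
        ),
        "latent_behavior": {
            pid: float(b)
            for pid, b in zip(cohort.participant_ids, truth.latent_behavior)
        },
        "planted_rhos": truth.planted_rhos,
        "missing_nodes": truth.missing_nodes,
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    files.append("ground_truth.json")

    manifest = {
        "files": files,
        "n_participants": cohort.n_participants,
        "n_nodes": int(len(cohort.node_ids)),
        "seed": config.seed if config is not None else None,
        "config": asdict(config) if config is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
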