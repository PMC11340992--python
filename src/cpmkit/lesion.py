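"""Computational lesioning of canonical networks.

Lesioning asks whether a connectome-wide association is carried by one
canonical network (default mode, ventral/dorsal attention, fronto-parietal,
...): all nodes of the target network are removed from every participant's
matrix, every mask edge incident to a removed node is deleted (both
within-network and between-network connections), network strength is
recomputed from the surviving edges, and the lesioned association with the
outcome is compared to the whole-brain association with Steiger's Z for
dependent correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectome import CohortConnectomes, NodeAtlas
from .cpm import CPMModel, EdgeMask, network_strength
from .stats import SteigerResult, partial_spearman, steiger_z

__all__ = ["LesionResult", "lesion_network", "lesion_analysis"]


@dataclass(frozen=True)
class LesionResult:
    """Whole-brain vs lesioned association for one canonical network."""

    network_name: str
    outcome: str
    removed_nodes: int
    remaining_mask_edges: int
    rho_whole: float
    p_whole: float
    rho_lesioned: float
    p_lesioned: float
    r_between_strengths: float
    steiger: SteigerResult | None
    n: int

    def to_row(self) -> dict:
        """Flatten into one tidy-table row (NaN for undefined fields)."""
        return {
            "network": self.network_name,
            "outcome": self.outcome,
            "removed_nodes": self.removed_nodes,
            "remaining_mask_edges": self.remaining_mask_edges,
            "rho_whole": self.rho_whole,
            "p_whole": self.p_whole,
            "rho_lesioned": self.rho_lesioned,
            "p_lesioned": self.p_lesioned,
            "r_between_strengths": self.r_between_strengths,
            "Z": self.steiger.Z if self.steiger else np.nan,
            "p_steiger": self.steiger.p if self.steiger else np.nan,
            "n": self.n,
        }


def lesion_network(
    cohort: CohortConnectomes,
    mask: EdgeMask,
    atlas: NodeAtlas,
    network_name: str,
) -> tuple[CohortConnectomes, EdgeMask, list[int]]:
    """Remove a canonical network's nodes from matrices and mask.

    Every node labeled ``network_name`` in the atlas is dropped from all
    participant matrices, and every mask edge incident to a removed node is
    deleted.  Node ordering of the survivors is preserved.  Lesioning a
    network with no member nodes among the matrix nodes is an identity
    transform (with a warning); a lesion that empties the mask succeeds, and
    downstream strength scoring is responsible for flagging the undefined
    strength.

    Returns
    -------
    (lesioned cohort, lesioned mask, removed node ids)
    """
    if network_name not in atlas.networks:
        raise ValueError(
            f"network {network_name!r} not in atlas (has {atlas.networks})"
        )
    member = set(atlas.nodes_in(network_name))
    present = [int(n) for n in cohort.node_ids]
    removed = sorted(member.intersection(present))
    if not removed:
        import warnings

        warnings.warn(
            f"network {network_name!r} has no nodes in the cohort; lesion is a no-op",
            stacklevel=2,
        )
        return cohort, mask, []
    keep = [n for n in present if n not in member]
    if not keep:
        raise ValueError(f"lesioning {network_name!r} would remove every node")
    lesioned_cohort = CohortConnectomes([m.subset(keep) for m in cohort.matrices])
    lesioned_mask = mask.restrict_to(keep)
    return lesioned_cohort, lesioned_mask, removed


def _strengths(cohort: CohortConnectomes, mask: EdgeMask) -> np.ndarray:
    return np.array([network_strength(m, mask) for m in cohort.matrices])


def lesion_analysis(
    cohort: CohortConnectomes,
    model: CPMModel,
    atlas: NodeAtlas,
    phenotypes: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    networks: Sequence[str],
    polarity: str = "high",
) -> pd.DataFrame:
    """Compare whole-brain and lesioned associations per canonical network.

    For each network: lesion matrices and the consensus mask of the chosen
    polarity, rescore strength from the surviving edges (never rescaled to
    the original edge count), and compute partial Spearman correlations of
    whole-brain and lesioned strength with the outcome given the covariates.
    Both correlations are computed on the same listwise-complete participant
    set (a dependent-correlation test requires a common sample), and
    compared with Steiger's Z using the rank (Spearman) correlation between
    the two strength scores as the predictor-predictor term.  A lesion that
    leaves the mask empty yields a row with NaN association fields rather
    than being silently dropped.

    Returns a tidy DataFrame, one row per network.
    """
    mask = model.consensus_high if polarity == "high" else model.consensus_low
    if len(mask) == 0:
        raise ValueError(f"consensus {polarity} mask is empty; nothing to lesion")
    if outcome not in phenotypes.columns:
        raise ValueError(f"unknown outcome column {outcome!r}")

    pheno = phenotypes.set_index(phenotypes["participant_id"].astype(str))
    pids = [str(p) for p in cohort.participant_ids]
    pheno = pheno.loc[pids]
    s_whole = _strengths(cohort, mask)

    results: list[LesionResult] = []
    for net in networks:
        lcohort, lmask, removed = lesion_network(cohort, mask, atlas, net)
        if len(lmask) == 0:
            results.append(
                LesionResult(
                    network_name=net, outcome=outcome,
                    removed_nodes=len(removed), remaining_mask_edges=0,
                    rho_whole=np.nan, p_whole=np.nan,
                    rho_lesioned=np.nan, p_lesioned=np.nan,
                    r_between_strengths=np.nan, steiger=None, n=0,
                )
            )
            continue
        s_les = _strengths(lcohort, lmask)

        cols = np.column_stack(
            [s_whole, s_les, pheno[outcome].to_numpy(dtype=float)]
            + [pheno[c].to_numpy(dtype=float) for c in covariates]
        )
        complete = np.isfinite(cols).all(axis=1)
        d = cols[complete]
        n = int(complete.sum())
        covs = [d[:, 3 + k] for k in range(len(covariates))]
        whole = partial_spearman(
            d[:, 0], d[:, 2], covs,
            predictor=f"{polarity}_strength", outcome=outcome,
            covariate_names=tuple(covariates),
        )
        les = partial_spearman(
            d[:, 1], d[:, 2], covs,
            predictor=f"{polarity}_strength_lesioned_{net}", outcome=outcome,
            covariate_names=tuple(covariates),
        )
        r_kh = float(sps.spearmanr(d[:, 0], d[:, 1]).statistic)
        if lmask.edges == mask.edges:
            # no mask edge touched the lesioned network: the two strength
            # scores are identical and the comparison is degenerate
            st = SteigerResult(
                Z=0.0, p=1.0, r_jk=whole.rho, r_jh=les.rho, r_kh=1.0, n=n
            )
        else:
            st = steiger_z(whole.rho, les.rho, r_kh, n)
        results.append(
            LesionResult(
                network_name=net, outcome=outcome,
                removed_nodes=len(removed), remaining_mask_edges=len(lmask),
                rho_whole=whole.rho, p_whole=whole.p,
                rho_lesioned=les.rho, p_lesioned=les.p,
                r_between_strengths=st.r_kh, steiger=st, n=n,
            )
        )
    return pd.DataFrame([r.to_row() for r in results])
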