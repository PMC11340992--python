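"""Covariate-adjusted rank associations and dependent-correlation tests.

Biomarker and cognitive outcomes in aging cohorts are typically skewed, so
associations with network strength are assessed with Spearman correlations;
head motion is a known confound of connectivity strength and is partialed
out.  Partial Spearman correlation is computed as the partial Pearson
correlation of average-ranked variables.  Whole-brain and lesioned models
yield *dependent* correlations with a shared outcome; their difference is
tested with Steiger's (1980) asymptotic Z for two correlations sharing one
variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AssociationResult",
    "SteigerResult",
    "partial_spearman",
    "steiger_z",
    "run_association_battery",
]


@dataclass(frozen=True)
class AssociationResult:
    """A (partial) Spearman association between a predictor and an outcome."""

    predictor: str
    outcome: str
    covariates: tuple[str, ...]
    rho: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError(f"rho out of range: {self.rho}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")


@dataclass(frozen=True)
class SteigerResult:
    """Steiger's Z for two dependent correlations sharing one variable.

    ``r_jk`` and ``r_jh`` are the two correlations being compared (both
    involve the shared variable j); ``r_kh`` is the correlation between the
    two non-shared variables.  ``psd_warning`` is set when the three
    correlations are not jointly realizable (the implied 3x3 correlation
    matrix is not positive semidefinite), in which case the asymptotic
    standard error is extrapolated beyond its domain.
    """

    Z: float
    p: float
    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    psd_warning: bool = False


def _rank(a: np.ndarray) -> np.ndarray:
    """Average ranks (ties share the mean rank)."""
    return sps.rankdata(a, method="average")


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Sequence[Sequence[float]] = (),
    predictor: str = "x",
    outcome: str = "y",
    covariate_names: Sequence[str] = (),
) -> AssociationResult:
    """Spearman correlation of x and y, partialing covariates out of both.

    All variables are rank-transformed (average ranks for ties) and the
    partial Pearson correlation of ranked x and y given the ranked
    covariates is computed from the inverse correlation matrix.  The
    two-tailed p-value uses ``t = rho * sqrt((n - 2 - k) / (1 - rho^2))``
    with ``n - 2 - k`` degrees of freedom, k the number of (non-degenerate)
    covariates.  Rows with any missing value are dropped listwise first;
    covariates that are constant after deletion carry no rank information
    and are dropped (with a warning), reducing k accordingly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covs = [np.asarray(c, dtype=float) for c in covariates]
    if covariate_names and len(covariate_names) != len(covs):
        raise ValueError("covariate_names length mismatch")
    names = tuple(covariate_names) if covariate_names else tuple(
        f"cov{k}" for k in range(len(covs))
    )

    cols = [x, y, *covs]
    if len({len(c) for c in cols}) != 1:
        raise ValueError("all variables must have equal length")
    data = np.column_stack(cols)
    keep = np.isfinite(data).all(axis=1)
    d = data[keep]
    n = d.shape[0]
    k_all = len(covs)
    if n < 4 + k_all:
        raise ValueError(
            f"need at least {4 + k_all} complete rows for {k_all} covariate(s), got {n}"
        )
    if np.ptp(d[:, 0]) == 0 or np.ptp(d[:, 1]) == 0:
        raise ValueError("x or y is constant after listwise deletion")

    # drop degenerate covariates: a constant has no ranks to adjust for
    keep_cov = [j for j in range(k_all) if np.ptp(d[:, 2 + j]) > 0]
    if len(keep_cov) < k_all:
        dropped = [names[j] for j in range(k_all) if j not in keep_cov]
        warnings.warn(f"constant covariate(s) dropped: {dropped}", stacklevel=2)
    d = d[:, [0, 1] + [2 + j for j in keep_cov]]
    names = tuple(names[j] for j in keep_cov)
    k = len(keep_cov)

    ranks = np.column_stack([_rank(col) for col in d.T])
    corr = np.corrcoef(ranks.T)
    if k == 0:
        rho = float(corr[0, 1])
    else:
        prec = np.linalg.pinv(corr)
        rho = float(-prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1]))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return AssociationResult(
        predictor=predictor,
        outcome=outcome,
        covariates=names,
        rho=rho,
        p=p,
        n=n,
    )


def steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> SteigerResult:
    """Steiger's (1980) Z for two dependent correlations with variable j shared.

    The two correlations are Fisher z-transformed and their difference is
    scaled by the asymptotic standard error for dependent correlations,
    evaluated at the back-transformed mean correlation rbar:

        zbar = (atanh(r_jk) + atanh(r_jh)) / 2,   rbar = tanh(zbar)
        psi  = r_kh * (1 - 2*rbar^2) - rbar^2 * (1 - 2*rbar^2 - r_kh^2) / 2
        s    = psi / (1 - rbar^2)^2
        Z    = (atanh(r_jk) - atanh(r_jh)) * sqrt((n - 3) / (2 - 2*s))

    with a two-tailed normal p-value.  ``|r| = 1`` for any input is an error
    (no clipping is applied here: a degenerate correlation signals an
    upstream problem, not a numerical nuisance).
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not np.isfinite(r) or abs(r) >= 1.0:
            raise ValueError(f"{name} must satisfy |r| < 1 and be finite, got {r}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")

    R = np.array([[1.0, r_jk, r_jh], [r_jk, 1.0, r_kh], [r_jh, r_kh, 1.0]])
    psd_warning = bool(np.linalg.eigvalsh(R)[0] < -1e-12)
    if psd_warning:
        warnings.warn(
            "correlation triple (r_jk, r_jh, r_kh) is not jointly realizable; "
            "Steiger Z is extrapolated",
            stacklevel=2,
        )

    z_jk = np.arctanh(r_jk)
    z_jh = np.arctanh(r_jh)
    rbar = np.tanh(0.5 * (z_jk + z_jh))
    psi = r_kh * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_kh**2)
    s = psi / (1 - rbar**2) ** 2
    Z = float((z_jk - z_jh) * np.sqrt((n - 3) / (2.0 - 2.0 * s)))
    p = float(2.0 * sps.norm.sf(abs(Z)))
    return SteigerResult(
        Z=Z, p=p, r_jk=float(r_jk), r_jh=float(r_jh), r_kh=float(r_kh), n=int(n),
        psd_warning=psd_warning,
    )


def run_association_battery(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    outcomes: Sequence[str],
    covariates: Sequence[str] = (),
    predictors: Sequence[str] = ("high_strength", "low_strength"),
) -> pd.DataFrame:
    """Partial Spearman of every strength score against every outcome.

    ``scores`` (participant_id + strength columns) is merged with
    ``phenotypes`` on participant_id; one association per
    (predictor, outcome) pair is computed with listwise deletion per pair,
    so ``n`` can differ across rows.  No multiple-testing adjustment is
    applied; p-values are unadjusted and two-tailed.
    """
    unknown = (set(outcomes) | set(covariates)) - set(phenotypes.columns)
    if unknown:
        raise ValueError(f"unknown phenotype columns: {sorted(unknown)}")
    missing_pred = set(predictors) - set(scores.columns)
    if missing_pred:
        raise ValueError(f"unknown score columns: {sorted(missing_pred)}")
    if len(set(outcomes)) < len(list(outcomes)):
        warnings.warn("duplicate outcomes listed; duplicate rows will be produced",
                      stacklevel=2)

    merged = scores.merge(phenotypes, on="participant_id", how="inner")
    rows = []
    for pred in predictors:
        for out in outcomes:
            res = partial_spearman(
                merged[pred],
                merged[out],
                [merged[c] for c in covariates],
                predictor=pred,
                outcome=out,
                covariate_names=tuple(covariates),
            )
            rows.append(
                {
                    "predictor": res.predictor,
                    "outcome": res.outcome,
                    "covariates": ";".join(res.covariates),
                    "rho": res.rho,
                    "p": res.p,
                    "n": res.n,
                    "p_adjustment": "none",
                }
            )
    return pd.DataFrame(rows)
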