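"""End-to-end orchestration: simulate -> build -> QC -> train -> score ->
associate -> lesion, with a manifest that makes every run reproducible.

Each stage writes plain-text outputs into the run directory; the manifest
records the seed, a hash of the full configuration, and cohort accounting,
so a rerun with the same config and seed reproduces every numeric output
exactly.  A stage failure aborts the run with the failing stage named and a
FAILED marker left beside any partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .connectome import harmonize_nodes, qc_filter
from .cpm import apply_model, save_model, train_cpm_loo
from .lesion import lesion_analysis
from .stats import run_association_battery
from .synthetic import SimConfig, generate_cohort, make_atlas, write_cohort

__all__ = ["RunConfig", "run_pipeline", "summarize_run"]

log = logging.getLogger("cpmkit")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run (all thresholds live here)."""

    sim: SimConfig
    out_dir: str = "cpm_run"
    selection_threshold: float = 0.01
    fd_threshold: float = 0.15
    min_participants_missing: int = 3
    behavior_col: str = "behavior"
    outcome_cols: tuple[str, ...] = ("biomarker", "pacc_like", "mem_like", "ef_like")
    covariate_cols: tuple[str, ...] = ("mean_fd",)
    lesion_networks: tuple[str, ...] = ("DMN", "VAN", "DAN", "FPN")
    lesion_outcomes: tuple[str, ...] = ("biomarker",)
    include_combined: bool = False

    @property
    def seed(self) -> int:
        return self.sim.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load from a flat YAML mapping; simulator keys are recognized by name."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        run_fields = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        sim_kwargs = {k: v for k, v in raw.items() if k in sim_fields}
        run_kwargs = {k: v for k, v in raw.items() if k in run_fields}
        unknown = set(raw) - sim_fields - run_fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("outcome_cols", "covariate_cols", "lesion_networks", "lesion_outcomes"):
            if key in run_kwargs:
                run_kwargs[key] = tuple(run_kwargs[key])
        return cls(sim=SimConfig(**sim_kwargs), **run_kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _setup_logging(out: Path) -> None:
    log.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in list(log.handlers):
        log.removeHandler(h)
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(fmt)
    log.addHandler(sh)
    log.addHandler(fh)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest.

    Raises on the first failing stage, naming it; partial outputs remain in
    the run directory beside a FAILED marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    stage = "setup"
    try:
        # ------------------------------------------------------------ simulate
        stage = "simulate"
        log.info("stage=simulate seed=%d", config.seed)
        cohort, phenotypes, truth = generate_cohort(config.sim)
        write_cohort(cohort, phenotypes, truth, out / "cohort", config=config.sim)
        atlas = make_atlas(cohort.node_ids)

        # ------------------------------------------------------------------ qc
        stage = "qc"
        qc = qc_filter(phenotypes, fd_threshold=config.fd_threshold)
        log.info(
            "stage=qc input=%d coverage_fail=%d fd_fail=%d retained=%d",
            qc.n_input, qc.n_coverage_fail, qc.n_fd_fail, qc.n_retained,
        )
        pd.DataFrame(
            {
                "reason": ["input", "coverage_fail", "fd_fail", "retained"],
                "n": [qc.n_input, qc.n_coverage_fail, qc.n_fd_fail, qc.n_retained],
            }
        ).to_csv(out / "exclusions.csv", index=False)
        cohort = cohort.subset_participants(qc.retained_ids)
        phenotypes = phenotypes[
            phenotypes["participant_id"].isin(qc.retained_ids)
        ].reset_index(drop=True)

        # ----------------------------------------------------------- harmonize
        stage = "harmonize"
        cohort, removed_nodes = harmonize_nodes(
            cohort, min_participants_missing=config.min_participants_missing
        )
        log.info(
            "stage=harmonize removed_nodes=%d remaining=%d",
            len(removed_nodes), len(cohort.node_ids),
        )
        # the atlas keeps its full node list; lesioning intersects network
        # membership with the surviving cohort nodes

        # --------------------------------------------------------------- train
        stage = "train"
        behavior = (
            phenotypes.set_index("participant_id")
            .loc[cohort.participant_ids, config.behavior_col]
            .to_numpy(dtype=float)
        )
        model, predictions = train_cpm_loo(
            cohort, behavior, threshold=config.selection_threshold
        )
        log.info(
            "stage=train folds=%d consensus_high=%d consensus_low=%d",
            model.n_folds, len(model.consensus_high), len(model.consensus_low),
        )
        save_model(model, out / "model")
        predictions.to_csv(out / "model" / "loo_predictions.csv", index=False,
                           float_format="%.10g")

        # --------------------------------------------------------------- score
        stage = "score"
        scores = apply_model(cohort, model, include_combined=config.include_combined)
        scores.to_csv(out / "strengths.csv", index=False, float_format="%.10g")

        # ----------------------------------------------------------- associate
        stage = "associate"
        assoc = run_association_battery(
            scores, phenotypes, config.outcome_cols, config.covariate_cols
        )
        assoc.to_csv(out / "associations.csv", index=False, float_format="%.10g")
        for _, row in assoc.iterrows():
            log.info(
                "stage=associate %s~%s rho=%.4f p=%.4g n=%d",
                row["predictor"], row["outcome"], row["rho"], row["p"], row["n"],
            )

        # -------------------------------------------------------------- lesion
        stage = "lesion"
        lesion_frames = []
        for outcome in config.lesion_outcomes:
            lf = lesion_analysis(
                cohort, model, atlas, phenotypes,
                outcome=outcome,
                covariates=config.covariate_cols,
                networks=config.lesion_networks,
            )
            lesion_frames.append(lf)
        lesions = pd.concat(lesion_frames, ignore_index=True)
        lesions.to_csv(out / "lesions.csv", index=False, float_format="%.10g")

        # ------------------------------------------------------------ manifest
        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": cio.config_hash(config.to_dict()),
            "n_input": qc.n_input,
            "n_coverage_fail": qc.n_coverage_fail,
            "n_fd_fail": qc.n_fd_fail,
            "n_retained": qc.n_retained,
            "removed_nodes": removed_nodes,
            "n_nodes_final": int(len(cohort.node_ids)),
            "consensus_high_edges": len(model.consensus_high),
            "consensus_low_edges": len(model.consensus_low),
            "outputs": [
                "cohort", "exclusions.csv", "model", "strengths.csv",
                "associations.csv", "lesions.csv",
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        failed = out / "FAILED"
        if failed.exists():
            failed.unlink()
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "undefined"
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)


def summarize_run(out_dir) -> str:
    """Human-readable summary of a completed run bundle."""
    out = Path(out_dir)
    required = ["manifest.json", "exclusions.csv", "associations.csv",
                "lesions.csv", "strengths.csv"]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run bundle, missing: {missing}")
    manifest = json.loads((out / "manifest.json").read_text())
    assoc = pd.read_csv(out / "associations.csv")
    lesions = pd.read_csv(out / "lesions.csv")
    strengths = pd.read_csv(out / "strengths.csv")

    lines = [
        f"run seed={manifest['seed']} config_hash={manifest['config_hash']}",
        (
            f"cohort: {manifest['n_input']} enrolled, "
            f"{manifest['n_coverage_fail']} coverage exclusions, "
            f"{manifest['n_fd_fail']} motion exclusions, "
            f"{manifest['n_retained']} retained"
        ),
        (
            f"nodes: {manifest['n_nodes_final']} after removing "
            f"{len(manifest['removed_nodes'])} missing-prone node(s)"
        ),
        (
            f"consensus masks: high={manifest['consensus_high_edges']} edges, "
            f"low={manifest['consensus_low_edges']} edges"
        ),
    ]
    for col in ("high_strength", "low_strength"):
        if col in strengths.columns and strengths[col].isna().all():
            lines.append(f"warning: {col} undefined for all participants "
                         "(empty consensus mask)")
    lines.append("associations (partial Spearman):")
    for _, r in assoc.iterrows():
        lines.append(
            f"  {r['predictor']} ~ {r['outcome']} | {r['covariates']}: "
            f"rho={_fmt(r['rho'])} p={_fmt(r['p'])} n={r['n']}"
        )
    lines.append("computational lesions (whole-brain vs lesioned, Steiger Z):")
    for _, r in lesions.iterrows():
        lines.append(
            f"  {r['network']} / {r['outcome']}: rho_whole={_fmt(r['rho_whole'])} "
            f"rho_lesioned={_fmt(r['rho_lesioned'])} "
            f"Z={_fmt(r['Z'])} p={_fmt(r['p_steiger'])} n={r['n']}"
        )
    return "\n".join(lines)
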