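import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy import stats as sps

from cpmkit import (
    EdgeMask,
    SimConfig,
    generate_cohort,
    harmonize_nodes,
    make_atlas,
    network_strength,
    qc_filter,
    write_cohort,
)
from cpmkit.io import read_cohort_dir, read_phenotypes


def _clean_config(**kw):
    base = dict(
        seed=11,
        n_participants=30,
        n_nodes=12,
        n_signal_pos_edges=5,
        n_signal_neg_edges=5,
        frac_missing_nodes=0.0,
        frac_fd_fail=0.0,
        frac_coverage_fail=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_participants": 0},
            {"n_nodes": -1},
            {"n_timepoints": -5},
            {"frac_fd_fail": 1.2},
            {"frac_missing_nodes": -0.1},
            {"n_signal_pos_edges": 40, "n_signal_neg_edges": 40},  # > 66 pairs
            {"target_strength_outcome_rho": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _clean_config(**kw)


class TestGenerateCohort:
    def test_matrices_symmetric_finite(self):
        cohort, _, _ = generate_cohort(_clean_config())
        for m in cohort.matrices:
            assert np.array_equal(m.z, m.z.T, equal_nan=True)
            off = m.z[~np.eye(m.n_nodes, dtype=bool)]
            assert np.all(np.isfinite(off))
            assert np.all(np.isnan(np.diag(m.z)))

    def test_clean_cohort_passes_qc_and_harmonization_unchanged(self):
        cohort, pheno, _ = generate_cohort(_clean_config())
        qc = qc_filter(pheno)
        assert qc.n_retained == cohort.n_participants
        _, removed = harmonize_nodes(cohort)
        assert removed == []

    def test_signal_edges_disjoint_and_recorded(self):
        _, _, truth = generate_cohort(_clean_config())
        assert len(truth.signal_pos_edges) == 5
        assert len(truth.signal_neg_edges) == 5
        assert not (truth.signal_pos_edges & truth.signal_neg_edges)
        assert len(truth.latent_behavior) == 30

    def test_qc_fractions_give_exact_counts(self):
        cfg = _clean_config(
            n_participants=50, frac_coverage_fail=0.1, frac_fd_fail=0.2
        )
        _, pheno, _ = generate_cohort(cfg)
        qc = qc_filter(pheno)
        assert qc.n_coverage_fail == 5
        assert qc.n_fd_fail == 10
        assert qc.n_retained == 35

    def test_missing_nodes_recorded_and_removable(self):
        cfg = _clean_config(n_participants=20, frac_missing_nodes=2 / 12)
        cohort, _, truth = generate_cohort(cfg)
        assert len(truth.missing_nodes) == 2
        for who in truth.missing_nodes.values():
            assert len(who) == 3
        harm, removed = harmonize_nodes(cohort)
        assert sorted(removed) == sorted(truth.missing_nodes)
        assert len(harm.node_ids) == 10

    def test_biomarker_positively_skewed(self):
        _, pheno, _ = generate_cohort(_clean_config(n_participants=300))
        assert sps.skew(pheno["biomarker"]) > 0.5

    def test_null_effect_consistent_with_no_association(self):
        # no planted coupling anywhere: truth-mask strength vs biomarker
        # should scatter around zero at the null sampling scale ~ 2/sqrt(3n)
        rhos = []
        for rep in range(50):
            cfg = _clean_config(
                seed=300 + rep,
                n_participants=200,
                n_nodes=16,
                n_signal_pos_edges=8,
                n_signal_neg_edges=0,
                effect_size=0.0,
                target_strength_outcome_rho=0.0,
                motion_confound_rho=0.0,
            )
            cohort, pheno, truth = generate_cohort(cfg)
            mask = EdgeMask(
                "high", truth.signal_pos_edges, tuple(int(v) for v in cohort.node_ids)
            )
            s = [network_strength(m, mask) for m in cohort.matrices]
            rhos.append(sps.spearmanr(s, pheno["biomarker"]).statistic)
        assert abs(np.mean(rhos)) < 0.03  # ~3 MC standard errors of the mean
        assert np.mean(np.abs(rhos)) < 2 / np.sqrt(3 * 200)

    def test_planted_correlation_unbiased(self):
        # marginal Spearman(truth-mask strength, biomarker) should center on
        # the target (edge-noise attenuation is compensated analytically)
        cfgs = [
            _clean_config(
                seed=700 + rep,
                n_participants=150,
                n_nodes=40,
                n_signal_pos_edges=100,
                n_signal_neg_edges=0,
            )
            for rep in range(100)
        ]
        rhos = []
        for cfg in cfgs:
            cohort, pheno, truth = generate_cohort(cfg)
            mask = EdgeMask(
                "high", truth.signal_pos_edges, tuple(int(v) for v in cohort.node_ids)
            )
            s = [network_strength(m, mask) for m in cohort.matrices]
            rhos.append(sps.spearmanr(s, pheno["biomarker"]).statistic)
        expected = cfgs[0].target_strength_outcome_rho
        se = np.std(rhos) / np.sqrt(len(rhos))
        assert abs(np.mean(rhos) - expected) < 3 * se + 0.01

    def test_motion_confound_near_planted_value(self):
        cfg = _clean_config(
            seed=5, n_participants=500, n_nodes=30,
            n_signal_pos_edges=60, n_signal_neg_edges=0,
        )
        cohort, pheno, truth = generate_cohort(cfg)
        mask = EdgeMask(
            "high", truth.signal_pos_edges, tuple(int(v) for v in cohort.node_ids)
        )
        s = [network_strength(m, mask) for m in cohort.matrices]
        r = np.corrcoef(pheno["mean_fd"], s)[0, 1]
        assert r == pytest.approx(cfg.motion_confound_rho, abs=0.12)

    def test_composites_negatively_coupled(self):
        _, pheno, truth = generate_cohort(_clean_config(n_participants=400))
        for col in ("pacc_like", "mem_like", "ef_like"):
            r = np.corrcoef(truth.latent_behavior, pheno[col])[0, 1]
            assert r < -0.15

    def test_determinism_same_seed_same_cohort(self):
        c1, p1, t1 = generate_cohort(_clean_config())
        c2, p2, t2 = generate_cohort(_clean_config())
        np.testing.assert_array_equal(c1.stack(), c2.stack())
        assert p1.equals(p2)
        assert t1.signal_pos_edges == t2.signal_pos_edges

    def test_timeseries_mode_approximates_planted_connectivity(self):
        cfg = _clean_config(n_nodes=10, n_timepoints=400, n_participants=6,
                            n_signal_pos_edges=4, n_signal_neg_edges=4)
        cohort_ts, _, _ = generate_cohort(cfg)
        cfg0 = _clean_config(n_nodes=10, n_timepoints=0, n_participants=6,
                             n_signal_pos_edges=4, n_signal_neg_edges=4)
        cohort_z, _, _ = generate_cohort(cfg0)
        iu = np.triu_indices(10, k=1)
        d = cohort_ts.stack()[:, iu[0], iu[1]] - cohort_z.stack()[:, iu[0], iu[1]]
        # empirical correlation noise ~ 1/sqrt(T) per edge, ~0 on average
        assert abs(d.mean()) < 0.05
        assert np.abs(d).mean() < 3 / np.sqrt(400)


class TestWriteCohort:
    def test_layout_roundtrip_and_manifest(self, tmp_path):
        cfg = _clean_config(n_participants=3, n_nodes=10,
                            n_signal_pos_edges=3, n_signal_neg_edges=3)
        cohort, pheno, truth = generate_cohort(cfg)
        manifest = write_cohort(cohort, pheno, truth, tmp_path, config=cfg)
        mats = sorted((tmp_path / "matrices").glob("*.tsv"))
        assert len(mats) == 3
        # header line + one row per node
        assert len(mats[0].read_text().strip().splitlines()) == 11
        assert manifest["seed"] == cfg.seed

        back = read_cohort_dir(tmp_path / "matrices")
        np.testing.assert_allclose(back.stack(), cohort.stack(), rtol=1e-9,
                                   equal_nan=True)
        pheno_back = read_phenotypes(tmp_path / "phenotypes.csv")
        assert list(pheno_back["participant_id"]) == cohort.participant_ids

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = _clean_config(n_participants=3, n_nodes=8,
                            n_signal_pos_edges=2, n_signal_neg_edges=2)
        for d in ("a", "b"):
            cohort, pheno, truth = generate_cohort(cfg)
            write_cohort(cohort, pheno, truth, tmp_path / d, config=cfg)
        files = [p.relative_to(tmp_path / "a")
                 for p in (tmp_path / "a").rglob("*") if p.is_file()]
        assert files
        for rel in files:
            assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel,
                               shallow=False), rel

    def test_empty_cohort_rejected(self, tmp_path):
        cohort, pheno, truth = generate_cohort(_clean_config())
        empty = cohort.subset_participants([])
        with pytest.raises(ValueError, match="empty"):
            write_cohort(empty, pheno, truth, tmp_path)


class TestMakeAtlas:
    def test_partition_covers_all_nodes(self):
        atlas = make_atlas(range(268))
        assert len(atlas.table) == 268
        assert set(atlas.networks) == {
            "DMN", "VAN", "DAN", "FPN", "visual", "somatomotor", "subcortical"
        }
        assert len(atlas.nodes_in("DMN")) == 35

    def test_deterministic(self):
        a1 = make_atlas(range(50))
        a2 = make_atlas(range(50))
        assert a1.table.equals(a2.table)
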