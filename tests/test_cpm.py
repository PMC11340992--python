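import numpy as np
import pandas as pd
import pytest

from cpmkit import (
    CohortConnectomes,
    EdgeMask,
    apply_model,
    load_model,
    network_strength,
    save_model,
    select_edges,
    train_cpm_loo,
)
from cpmkit.io import read_mask, write_mask

from conftest import matrix_from_values, random_cohort


def cohort_with_edge_signal(rng, n, node_ids, signal_edge, behavior,
                            noise_edges="random", sign=1.0):
    """Cohort where one edge equals sign*behavior and the rest are noise or
    constant."""
    nn = len(node_ids)
    iu, ju = np.triu_indices(nn, k=1)
    pairs = list(zip(node_ids[iu], node_ids[ju]))
    k_sig = pairs.index(signal_edge)
    mats = []
    for p in range(n):
        if noise_edges == "random":
            vals = rng.normal(0.2, 0.1, len(pairs))
        else:  # constant background: only the signal edge varies
            vals = np.full(len(pairs), 0.1)
        vals[k_sig] = sign * behavior[p]
        mats.append(matrix_from_values(vals, node_ids, pid=f"sub-{p:03d}"))
    return CohortConnectomes(mats)


class TestEdgeMask:
    def test_canonical_ordering_and_matrix_rendering(self):
        mask = EdgeMask("high", {(5, 2), (1, 3)}, node_ids=(1, 2, 3, 5))
        assert mask.edges == {(2, 5), (1, 3)}
        m = mask.to_matrix()
        assert np.array_equal(m, m.T)
        assert m.sum() == 4  # each undirected edge appears twice
        back = EdgeMask.from_matrix(m, (1, 2, 3, 5), "high")
        assert back.edges == mask.edges

    def test_self_edge_and_stray_nodes_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            EdgeMask("high", {(2, 2)}, node_ids=(1, 2))
        with pytest.raises(ValueError, match="unknown node"):
            EdgeMask("high", {(1, 9)}, node_ids=(1, 2))

    def test_roundtrip_through_both_file_renderings(self, tmp_path):
        mask = EdgeMask("low", {(0, 3), (1, 2)}, node_ids=(0, 1, 2, 3, 4))
        write_mask(mask, tmp_path / "m")
        from_edges = read_mask(tmp_path / "m.edges.csv", node_ids=mask.node_ids)
        from_matrix = read_mask(tmp_path / "m.matrix.tsv", polarity="low")
        assert from_edges.edges == mask.edges
        assert from_edges.polarity == "low"
        assert from_matrix.edges == mask.edges


class TestSelectEdges:
    def test_exact_positive_and_negative_edges(self):
        rng = np.random.default_rng(3)
        ids = np.arange(8)
        behavior = rng.standard_normal(40)
        pos = cohort_with_edge_signal(rng, 40, ids, (2, 5), behavior)
        p_sel, n_sel = select_edges(pos, behavior, threshold=0.01)
        assert (2, 5) in p_sel
        neg = cohort_with_edge_signal(rng, 40, ids, (1, 6), behavior, sign=-1.0)
        p2, n2 = select_edges(neg, behavior, threshold=0.01)
        assert (1, 6) in n2
        assert not p_sel & n_sel

    def test_constant_edges_never_selected(self):
        rng = np.random.default_rng(4)
        behavior = rng.standard_normal(30)
        cohort = cohort_with_edge_signal(
            rng, 30, np.arange(6), (0, 1), behavior, noise_edges="constant"
        )
        pos, neg = select_edges(cohort, behavior, threshold=0.05)
        assert pos == {(0, 1)}
        assert neg == frozenset()

    def test_constant_behavior_rejected(self):
        rng = np.random.default_rng(5)
        cohort = random_cohort(rng, 10, np.arange(5))
        with pytest.raises(ValueError, match="constant"):
            select_edges(cohort, np.ones(10))

    def test_selection_shrinks_with_tighter_threshold(self, planted_cohort):
        _, cohort, pheno, _ = planted_cohort
        behavior = pheno["behavior"].to_numpy()
        loose_p, loose_n = select_edges(cohort, behavior, threshold=0.05)
        tight_p, tight_n = select_edges(cohort, behavior, threshold=0.001)
        assert tight_p <= loose_p
        assert tight_n <= loose_n


class TestNetworkStrength:
    def test_single_and_two_edge_masks(self):
        m = matrix_from_values(np.arange(6) / 10, np.arange(4))
        # edges: (0,1)=0.0 (0,2)=0.1 (0,3)=0.2 (1,2)=0.3 (1,3)=0.4 (2,3)=0.5
        assert network_strength(m, EdgeMask("high", {(1, 2)}, (0, 1, 2, 3))) == 0.3
        two = EdgeMask("high", {(0, 3), (1, 3)}, (0, 1, 2, 3))
        assert network_strength(m, two) == pytest.approx(0.3)

    def test_full_mask_equals_brute_force_mean(self):
        rng = np.random.default_rng(9)
        ids = np.arange(30)
        m = matrix_from_values(rng.standard_normal(435), ids)
        iu, ju = np.triu_indices(30, k=1)
        mask = EdgeMask("high", set(zip(iu, ju)), tuple(ids))
        brute = np.nanmean(np.where(np.eye(30, dtype=bool), np.nan, m.z))
        assert network_strength(m, mask) == pytest.approx(brute, abs=1e-12)

    def test_empty_mask_and_absent_nodes_error(self):
        m = matrix_from_values(np.arange(3) / 10, np.arange(3))
        with pytest.raises(ValueError, match="undefined"):
            network_strength(m, EdgeMask("high", set(), (0, 1, 2)))
        with pytest.raises(ValueError, match=r"\[7\]"):
            network_strength(m, EdgeMask("high", {(0, 7)}, (0, 1, 2, 7)))


class TestTrainLOO:
    def test_minimal_cohort_bookkeeping(self):
        rng = np.random.default_rng(12)
        behavior = rng.standard_normal(5)
        cohort = cohort_with_edge_signal(
            rng, 5, np.arange(6), (0, 4), behavior, noise_edges="constant"
        )
        model, preds = train_cpm_loo(cohort, behavior, threshold=0.05)
        assert model.n_folds == 5
        assert len(preds) == 5
        for fold_edges in model.per_fold_pos_edges:
            assert model.consensus_high.edges <= fold_edges

    def test_noise_free_single_edge_recovered_perfectly(self):
        rng = np.random.default_rng(13)
        behavior = rng.standard_normal(20)
        cohort = cohort_with_edge_signal(
            rng, 20, np.arange(8), (2, 6), behavior, noise_edges="constant"
        )
        model, preds = train_cpm_loo(cohort, behavior, threshold=0.01)
        assert model.consensus_high.edges == {(2, 6)}
        assert len(model.consensus_low) == 0
        r = np.corrcoef(preds["pred_high"], behavior)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_all_folds_empty_raises(self):
        rng = np.random.default_rng(14)
        cohort = random_cohort(rng, 12, np.arange(5))
        behavior = rng.standard_normal(12)
        with pytest.raises(ValueError, match="no edges selected"):
            train_cpm_loo(cohort, behavior, threshold=1e-12)

    def test_consensus_shrinks_as_threshold_tightens(self, planted_cohort):
        _, cohort, pheno, _ = planted_cohort
        behavior = pheno["behavior"].to_numpy()
        loose, _ = train_cpm_loo(cohort, behavior, threshold=0.05)
        tight, _ = train_cpm_loo(cohort, behavior, threshold=0.005)
        assert tight.consensus_high.edges <= loose.consensus_high.edges
        assert tight.consensus_low.edges <= loose.consensus_low.edges

    def test_planted_edges_recovered(self, planted_cohort):
        cfg, cohort, pheno, truth = planted_cohort
        model, _ = train_cpm_loo(cohort, pheno["behavior"].to_numpy(),
                                 threshold=0.01)
        hit = len(model.consensus_high.edges & truth.signal_pos_edges)
        assert hit / len(truth.signal_pos_edges) >= 0.75
        hit_low = len(model.consensus_low.edges & truth.signal_neg_edges)
        assert hit_low / len(truth.signal_neg_edges) >= 0.75


class TestApplyModel:
    def _model(self, cohort, behavior):
        model, _ = train_cpm_loo(cohort, behavior, threshold=0.05)
        return model

    def test_identical_matrices_identical_scores(self):
        rng = np.random.default_rng(21)
        behavior = rng.standard_normal(20)
        train = cohort_with_edge_signal(rng, 20, np.arange(6), (1, 4), behavior)
        model = self._model(train, behavior)
        vals = rng.normal(0.3, 0.1, 15)
        same = CohortConnectomes(
            [matrix_from_values(vals, np.arange(6), pid=f"x{k}") for k in range(4)]
        )
        scores = apply_model(same, model)
        assert scores["high_strength"].nunique() == 1

    def test_constant_shift_moves_strength_linearly(self):
        rng = np.random.default_rng(22)
        behavior = rng.standard_normal(20)
        cohort = cohort_with_edge_signal(rng, 20, np.arange(6), (1, 4), behavior)
        model = self._model(cohort, behavior)
        base = apply_model(cohort, model)
        shifted = CohortConnectomes(
            [
                matrix_from_values(
                    m.z[np.triu_indices(6, k=1)] + 0.25, np.arange(6),
                    pid=m.participant_id,
                )
                for m in cohort.matrices
            ]
        )
        out = apply_model(shifted, model)
        np.testing.assert_allclose(
            out["high_strength"], base["high_strength"] + 0.25, atol=1e-12
        )

    def test_model_bundle_roundtrip(self, tmp_path, planted_cohort):
        _, cohort, pheno, _ = planted_cohort
        behavior = pheno["behavior"].to_numpy()
        model, _ = train_cpm_loo(cohort, behavior, threshold=0.01)
        save_model(model, tmp_path / "bundle")
        back = load_model(tmp_path / "bundle")
        assert back.consensus_high.edges == model.consensus_high.edges
        assert back.consensus_low.edges == model.consensus_low.edges
        assert back.selection_threshold == model.selection_threshold
        assert back.n_folds == model.n_folds
        s1 = apply_model(cohort, model)
        s2 = apply_model(cohort, back)
        pd.testing.assert_frame_equal(s1, s2)
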