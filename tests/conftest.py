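import numpy as np
import pytest

from cpmkit import CohortConnectomes, ConnectivityMatrix, SimConfig, generate_cohort


def matrix_from_values(values, node_ids, pid="sub-0000"):
    """Symmetric ConnectivityMatrix from an upper-triangle value vector."""
    n = len(node_ids)
    iu, ju = np.triu_indices(n, k=1)
    z = np.full((n, n), np.nan)
    z[iu, ju] = values
    z[ju, iu] = values
    return ConnectivityMatrix(pid, np.asarray(node_ids), z)


def random_cohort(rng, n_participants, node_ids):
    """Pure-noise cohort on the given nodes."""
    n_edges = len(node_ids) * (len(node_ids) - 1) // 2
    return CohortConnectomes(
        [
            matrix_from_values(
                rng.normal(0.3, 0.2, n_edges), node_ids, pid=f"sub-{k:04d}"
            )
            for k in range(n_participants)
        ]
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """A small cohort with planted signal edges and clean QC."""
    cfg = SimConfig(
        seed=42,
        n_participants=60,
        n_nodes=20,
        n_signal_pos_edges=8,
        n_signal_neg_edges=8,
        frac_missing_nodes=0.0,
        frac_fd_fail=0.0,
        frac_coverage_fail=0.0,
    )
    cohort, phenotypes, truth = generate_cohort(cfg)
    return cfg, cohort, phenotypes, truth
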