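import numpy as np
import pytest

import treedecon as td


@pytest.fixture
def tiny_ref():
    """Hand-built reference: 3 clusters x 2 subjects, 12 cells, 5 genes.

    Gene layout: g0 elevated in cluster A, g1 in B, g2 in C, g3/g4
    housekeeping.  Every cell has total count 20 so CPM is easy to
    compute by hand.
    """
    genes = np.array(["g0", "g1", "g2", "g3", "g4"], dtype=object)
    rows = []
    clusters = []
    subjects = []
    cell_ids = []
    layout = {"A": [10, 0, 0, 5, 5], "B": [0, 10, 0, 5, 5], "C": [0, 0, 10, 5, 5]}
    i = 0
    for cluster, base in layout.items():
        for subject in ("s1", "s2"):
            for _ in range(2):
                rows.append(base)
                clusters.append(cluster)
                subjects.append(subject)
                cell_ids.append(f"cell{i}")
                i += 1
    return td.SingleCellReference(
        counts=np.array(rows, dtype=float),
        gene_ids=genes,
        cell_ids=np.array(cell_ids, dtype=object),
        clusters=np.array(clusters, dtype=object),
        subjects=np.array(subjects, dtype=object),
    )


SMALL_SIM_CONFIG = td.SimulationConfig(
    n_genes=300,
    n_clusters=4,
    n_subjects=2,
    cells_per_cluster_per_subject=12,
    markers_per_cluster=6,
    marker_fold=8.0,
    seed=7,
)

SMALL_MARKER_CONFIG = td.MarkerConfig(n_b=2, n_bs=20, n_min=4, n_max=8, seed=7)


@pytest.fixture(scope="session")
def small_marker_config():
    return SMALL_MARKER_CONFIG


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated reference with its planted-marker ledger."""
    return td.simulate_reference(SMALL_SIM_CONFIG)


@pytest.fixture(scope="session")
def small_markers(small_sim):
    ref, _ = small_sim
    return td.select_all_markers(ref, SMALL_MARKER_CONFIG)


@pytest.fixture(scope="session")
def small_signature(small_sim, small_markers):
    ref, _ = small_sim
    return td.build_signature(ref, small_markers)
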