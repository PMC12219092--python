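import numpy as np
import pandas as pd
import pytest

from xtalkflow.io import ExpressionData, LRRecord


def make_expression(matrix, clusters, gene_ids=None, cell_ids=None,
                    normalized=None):
    """Build an ExpressionData with explicit layers for formula tests."""
    matrix = np.asarray(matrix, dtype=float)
    n_genes, n_cells = matrix.shape
    gene_ids = gene_ids or [f"g{i+1}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{j+1}" for j in range(n_cells)]
    data = ExpressionData(
        matrix=matrix, gene_ids=gene_ids, cell_ids=cell_ids,
        cluster_of=dict(zip(cell_ids, clusters)), state="raw")
    if normalized is not None:
        data.normalized = np.asarray(normalized, dtype=float)
        data.state = "normalized"
    return data


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_cluster_expr():
    """Ligand expressed only in the sender cluster, receptor everywhere."""
    # genes: LIG, REC, OTHER; 4 sender + 4 receiver cells
    mat = np.array([
        [5, 5, 5, 5, 0, 0, 0, 0],    # LIG high in sender
        [1, 1, 1, 1, 1, 1, 1, 1],    # REC uniform
        [1, 2, 1, 2, 1, 2, 1, 2],    # OTHER
    ], dtype=float)
    data = make_expression(
        mat, clusters=["S"] * 4 + ["Rcv"] * 4,
        gene_ids=["LIG", "REC", "OTHER"], normalized=mat)
    return data


@pytest.fixture
def prs_table():
    """Hand-built PRS table exercising both module normalizations."""
    return pd.DataFrame({
        "Signal": ["S1", "S2", "S1", "S1"],
        "SSC":    ["C1", "C1", "C1", "C2"],
        "Target": ["T1", "T1", "T2", "T2"],
        "PRS":    [9.0, 1.0, 60.0, 21.0],
    })


@pytest.fixture
def lr_simple():
    return LRRecord(ligand_subunits=["LIG"], receptor_subunits=["REC"])


def synthetic_pipeline_model(seed=0, n_genes=60, n_cells=240, config=None):
    """Full-pipeline model over simulator output with emulated ligands."""
    from xtalkflow import simulate as sim
    from xtalkflow.config import RunConfig
    from xtalkflow.io import LRDatabase, PriorNetworks
    from xtalkflow.model import CrosstalkModel

    grn = sim.generate_grn(n_genes, seed=seed)
    ds = sim.simulate_expression(grn, n_cells=n_cells, seed=seed + 1,
                                 with_ligands=True)
    lrdb = LRDatabase([LRRecord([ds.ligand_of[r]], [r])
                       for r in grn.receptors])
    priors = PriorNetworks(grn.receptor_tf_edges.copy(),
                           grn.tf_target_edges.copy())
    cfg = config or RunConfig(seed=seed, epochs=40, patience=10,
                              n_permutations=50)
    return CrosstalkModel(
        expr=ds.to_expression_data(), lr_db=lrdb, priors=priors,
        receiver="C1", user_targets=list(grn.targets), config=cfg)
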