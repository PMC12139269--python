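import numpy as np
import pytest

from mutgraph.cohort_io import CohortLabels, GeneCatalog, MutationMatrix, PPINetwork
from mutgraph.features import compute_feature_matrix, compute_rf_table
from mutgraph.gat_model import GATConfig, train_gat
from mutgraph.hetero_graph import EdgeConfig, assemble_graph
from mutgraph.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture
def small_catalog() -> GeneCatalog:
    genes = ("BRCA1", "KRAS", "TP53")
    return GeneCatalog(genes, {g: f"PR_{g}" for g in genes})


@pytest.fixture
def small_ppi(small_catalog) -> PPINetwork:
    prots = small_catalog.proteins
    edges = {frozenset((prots[0], prots[1])), frozenset((prots[1], prots[2]))}
    return PPINetwork(
        proteins=prots,
        edges=edges,
        score={e: 900 for e in edges},
        gene_of={small_catalog.protein_of[g]: g for g in small_catalog.genes},
    )


@pytest.fixture(scope="session")
def tiny_bundle():
    """40-patient planted cohort small enough for per-test training."""
    return generate_cohort(
        SyntheticSpec(n_case=20, n_control=20, n_genes=60, n_planted=10, seed=11)
    )


@pytest.fixture(scope="session")
def tiny_graph(tiny_bundle):
    b = tiny_bundle
    y = b.labels.vector(b.matrix.patients)
    rf = compute_rf_table(b.matrix, b.labels)
    feats = compute_feature_matrix(b.matrix, rf, dict(b.labels.label))
    n = len(y)
    rng = np.random.default_rng(0)
    order = rng.permutation(n)
    masks = {k: np.zeros(n, dtype=bool) for k in ("train", "val", "test")}
    masks["train"][order[:28]] = True
    masks["val"][order[28:34]] = True
    masks["test"][order[34:]] = True
    return assemble_graph(feats, y, b.ppi, b.catalog, EdgeConfig(k_edges=20), masks)


@pytest.fixture(scope="session")
def tiny_model(tiny_graph):
    return train_gat(
        tiny_graph, GATConfig(hidden_units=8, heads=2, max_epochs=200, patience=200, seed=5)
    )
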