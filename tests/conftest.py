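import numpy as np
import pytest

from morphrank import ClusteringSolution, Configuration, ExpressionMatrix


def make_matrix(values, dataset_id="ds", platform="microarray", gene_ids=None,
                sample_ids=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    return ExpressionMatrix(
        dataset_id=dataset_id,
        gene_ids=gene_ids or [f"g{i:03d}" for i in range(n_genes)],
        sample_ids=sample_ids or [f"s{j:02d}" for j in range(n_samples)],
        values=values,
        platform=platform,
    )


def make_config(values, assignment, dataset_id="ds", clustering_id="c",
                gene_ids=None, unclustered=None):
    m = make_matrix(values, dataset_id=dataset_id, gene_ids=gene_ids)
    unclustered = set(unclustered or (set(m.gene_ids) - set(assignment)))
    sol = ClusteringSolution(
        clustering_id=clustering_id, dataset_id=dataset_id,
        assignment=assignment, unclustered=unclustered,
    )
    return Configuration(matrix=m, clustering=sol)


def random_config(rng, n_genes=30, n_samples=10, n_modules=3, dataset_id="ds",
                  clustering_id="c"):
    """Random matrix with a random full partition into n_modules."""
    values = rng.standard_normal((n_genes, n_samples))
    gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    labels = rng.integers(0, n_modules, size=n_genes)
    # guarantee every module >= 2 members
    for mod in range(n_modules):
        while np.count_nonzero(labels == mod) < 2:
            labels[rng.integers(0, n_genes)] = mod
    assignment = {g: int(m) for g, m in zip(gene_ids, labels)}
    return make_config(values, assignment, dataset_id=dataset_id,
                       clustering_id=clustering_id, gene_ids=gene_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
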