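import numpy as np
import pytest

from phenotrace.preprocess import assemble
from phenotrace.synthetic import (
    SIX_PHENOTYPES,
    GeneratorConfig,
    generate_dataset,
    make_phenotype_library,
)
from phenotrace.vae import TrainConfig, train


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """200-cell six-phenotype synthetic sample with impact coverage."""
    cfg = GeneratorConfig(n_cells=200, phenotype_names=SIX_PHENOTYPES, seed=0)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return assemble(small_dataset.traces, labels=small_dataset.labels)


@pytest.fixture(scope="session")
def two_phenotype_vae():
    """VAE trained on two well-separated viable phenotypes.

    Low-calcium (cluster_01) vs high-calcium/high-mito (cluster_06): both
    spatially unbiased, so the classes stay balanced. Session-scoped:
    training takes a few seconds and several tests probe the same model.
    Returns (trained, matrix, dataset).
    """
    cfg = GeneratorConfig(
        n_cells=240, phenotype_names=("cluster_01", "cluster_06"), seed=7
    )
    ds = generate_dataset(cfg)
    matrix = assemble(ds.traces, labels=ds.labels)
    trained = train(matrix.data, config=TrainConfig(epochs=30, seed=7))
    return trained, matrix, ds


@pytest.fixture(scope="session")
def phenotype_library():
    return make_phenotype_library()
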