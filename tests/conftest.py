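import numpy as np
import pytest

from gsclassify import MarkerMatrix, PhenotypeVector, SimConfig, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n=120, p=200, coding="01", n_qtl=12, epistasis_pairs=3, h2=0.6, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    X = simulate_genotypes(small_cfg)
    pv, truth = simulate_phenotypes(X, small_cfg)
    return X, pv, truth


@pytest.fixture
def tiny_markers():
    vals = np.array([[0, 1], [2, 0], [1, 2]])
    return MarkerMatrix(["a", "b", "c"], ["m1", "m2"], vals, coding="012")


@pytest.fixture
def tiny_phenotype():
    return PhenotypeVector(["a", "b", "c"], np.array([1.0, 2.0, 3.0]), "gy", "E1")
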