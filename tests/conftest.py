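import numpy as np
import pytest

from clonalgp import GenotypeMatrix, SimConfig, build_kernel_set, compute_blues_all, simulate_dataset


@pytest.fixture
def toy_geno():
    """Three individuals, one SNP at p=0.5: AA, AB, BB."""
    return GenotypeMatrix(["i1", "i2", "i3"], ["s1"], np.array([[0.0], [1.0], [2.0]]))


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated clonal trial reused across tests."""
    cfg = SimConfig(
        n_parents=10, n_families=8, family_size=10, n_snps=400, seed=42,
        n_grandparents=5,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def study_sim():
    """A study-scale simulated trial (25 parents, 17 families, 2828 SNPs)."""
    return simulate_dataset(SimConfig(seed=42))


@pytest.fixture(scope="session")
def small_sim_blues(small_sim):
    return compute_blues_all(small_sim.phenotypes)


@pytest.fixture(scope="session")
def small_sim_kernels(small_sim):
    return build_kernel_set(small_sim.offspring)


def random_genotypes(rng: np.random.Generator, n: int, m: int, maf_floor: float = 0.1) -> GenotypeMatrix:
    p = rng.uniform(maf_floor, 1 - maf_floor, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    return GenotypeMatrix([f"i{k}" for k in range(n)], [f"s{j}" for j in range(m)], dos)
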