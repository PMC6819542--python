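import numpy as np
import pytest

from pavomics import SimConfig, simulate_panel, simulate_phenotypes, simulate_populations


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        n_genes=120,
        n_snps_array=150,
        n_sv=150,
        library_size_reads=200_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_panel(small_cfg)


@pytest.fixture(scope="session")
def small_pops(small_panel, small_cfg):
    _, _, truth = small_panel
    return simulate_populations(truth, small_cfg)


@pytest.fixture(scope="session")
def small_pheno(small_panel, small_cfg):
    _, _, truth = small_panel
    return simulate_phenotypes(truth, small_cfg)


def gamete_drop_missing_fraction(
    n_individuals: int, selfing_generations: int, seed: int
) -> float:
    """Brute-force gamete-dropping oracle: fraction of selfed descendants of
    a (null, allele) F1 that carry at least one null copy — the progeny
    whose array call fails at a SNP inside the deletion."""
    rng = np.random.default_rng(seed)
    # genotype state per individual: number of null alleles (F1 = 1)
    null_count = np.ones(n_individuals, dtype=int)
    for _ in range(selfing_generations):
        het = null_count == 1
        # from a heterozygote, each gamete carries null w.p. 1/2
        gametes = rng.integers(0, 2, size=(2, n_individuals))
        offspring = gametes.sum(axis=0)
        null_count = np.where(het, offspring, null_count)
    return float((null_count >= 1).mean())
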