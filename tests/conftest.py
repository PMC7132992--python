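import numpy as np
import pytest

import hybridpeel as hp


@pytest.fixture(scope="session")
def trio_pedigree() -> hp.Pedigree:
    return hp.Pedigree(["sire", "dam", "child"],
                       np.array([-1, -1, 0]), np.array([-1, -1, 1]))


@pytest.fixture(scope="session")
def small_config() -> hp.RunConfig:
    """Tiny study configuration for fast end-to-end tests."""
    return hp.RunConfig(n_chromosomes=1, variants_per_chromosome=400,
                        hd_per_chromosome=40, ld_per_chromosome=10,
                        n_founders=12, n_generations=5, population_size=180,
                        seed=123)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> hp.Dataset:
    return hp.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_run(small_dataset):
    """Hybrid-peeling dosages for the tiny study, on a variant subsample."""
    rng = np.random.default_rng(7)
    sub = np.sort(rng.choice(small_dataset.gmap.n_variants, 200, replace=False))
    dosages, _ = hp.hybrid_peel(small_dataset.pedigree, small_dataset.genotypes,
                                small_dataset.reads, small_dataset.gmap,
                                small_dataset.panels, variants=sub)
    report = hp.population_accuracy(small_dataset, dosages.values, sub)
    return small_dataset, sub, dosages, report
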