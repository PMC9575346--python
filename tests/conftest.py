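import numpy as np
import pytest

from snpdiffnet import JdinacConfig, SimConfig, compute_gene_scores, simulate_cohort
from snpdiffnet.simulate import PlantedEdge


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with one strong differential edge (a-b)."""
    cfg = SimConfig(
        n_case=80,
        n_control=80,
        genes=["a", "b", "c", "d"],
        snps_per_gene=3,
        maf=0.3,
        planted_edges=[PlantedEdge("a", "b", 0.6, 0.0)],
        seed=7,
    )
    genotypes, truth = simulate_cohort(cfg)
    scores = compute_gene_scores(genotypes, cfg.snp_gene_map())
    return cfg, genotypes, truth, scores


@pytest.fixture()
def fast_jdinac():
    """Cheap JDINAC settings for structural (non-power) tests."""
    return JdinacConfig(T=2, cv_folds=3, n_lambdas=6, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
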