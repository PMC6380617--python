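import numpy as np
import pytest

from ethacc.panel import GenotypePanel, TrainTestSplit, center_design
from ethacc.simulate import SimConfig, simulate_genotypes, simulate_phenotype


@pytest.fixture
def small_panel():
    """Unstructured 40-sample, 60-marker inbred panel."""
    cfg = SimConfig(n_samples=40, n_markers=60, n_clusters=1, fst=0.2,
                    inbred=True, seed=42)
    return simulate_genotypes(cfg)


@pytest.fixture
def sim_case():
    """A mid-size panel with a 5-QTL h2=0.5 trait and an 80/20 split."""
    cfg = SimConfig(n_samples=150, n_markers=200, n_clusters=1, fst=0.2,
                    inbred=True, n_qtl=5, h2=0.5, seed=7)
    panel = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotype(panel, n_qtl=5, h2=0.5, seed=8)
    perm = np.random.default_rng(9).permutation(panel.n_samples)
    split = TrainTestSplit(np.sort(perm[30:]), np.sort(perm[:30]))
    return panel, pheno, truth, split


def random_split(n: int, n_test: int, seed: int) -> TrainTestSplit:
    perm = np.random.default_rng(seed).permutation(n)
    return TrainTestSplit(np.sort(perm[n_test:]), np.sort(perm[:n_test]))


def random_design(seed: int, T: int = 30, n_test: int = 10, M: int = 50):
    """A centered design plus phenotype from a seeded random panel."""
    cfg = SimConfig(n_samples=T + n_test, n_markers=M, n_clusters=1, fst=0.2,
                    inbred=False, seed=seed)
    panel = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotype(panel, n_qtl=max(1, M // 10), h2=0.5,
                                      seed=seed + 1)
    split = random_split(T + n_test, n_test, seed + 2)
    return panel, pheno, truth, split, center_design(panel, split)
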