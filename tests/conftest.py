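import numpy as np
import pytest

from autogs.genotype_io import impute_missing
from autogs.simulate import SimConfig, simulate_genotypes, simulate_trait


@pytest.fixture(scope="session")
def small_panel():
    """60 samples x 40 loci, complete genotypes, additive trait h2=0.8."""
    cfg = SimConfig(n=60, L=40, n_qtl=8, h2=0.8, seed=42)
    gm, vt = simulate_genotypes(cfg)
    pt, truth = simulate_trait(gm, cfg)
    return gm, vt, pt, truth


@pytest.fixture(scope="session")
def medium_panel():
    """300 samples x 120 loci for model-level checks."""
    cfg = SimConfig(n=300, L=120, n_qtl=20, h2=0.9, seed=7)
    gm, vt = simulate_genotypes(cfg)
    pt, truth = simulate_trait(gm, cfg)
    return gm, vt, pt, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
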