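import pytest

from embai import (
    PriorConfig,
    compute_grm,
    make_scenario_one_qtn,
    simulate_genotypes,
    simulate_phenotype,
)


@pytest.fixture(scope="session")
def tight_prior():
    """Strict stopping rule for fixed-point / oracle comparisons."""
    return PriorConfig(tol=1e-10, max_iter=5000)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest one-QTN dataset with its GRM (n=300, q=600)."""
    g = simulate_genotypes(300, 600, seed=42)
    K = compute_grm(g)
    scen = make_scenario_one_qtn(g, background_multiplier=2.0, seed=43)
    ds = simulate_phenotype(g, scen, K)
    return ds, K
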