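import numpy as np
import pytest

from splicestr import SimConfig, simulate_genotypes, simulate_psi


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared across tests (read-only)."""
    cfg = SimConfig(n_samples=300, n_events=12, snps_per_locus=10, seed=11,
                    snp_causal_fraction=0.5)
    genotypes, truth, extras = simulate_genotypes(cfg)
    events, covariates = simulate_psi(genotypes, truth, cfg, extras)
    return {"config": cfg, "genotypes": genotypes, "truth": truth,
            "extras": extras, "events": events, "covariates": covariates}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
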