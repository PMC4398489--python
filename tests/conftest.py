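import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from feednet.gwas import default_trait_fixed_effects, run_gwas
from feednet.phenotypes import derive_phenotypes
from feednet.simulate import SimulationConfig, simulate_study
from feednet.traits import ANALYSIS_TRAITS


@pytest.fixture(scope="session")
def small_study():
    """Small synthetic F2 study reused across modules."""
    config = SimulationConfig(seed=11, n_f2=150, n_snps=400, n_genes=200)
    return simulate_study(config)


@pytest.fixture(scope="session")
def derived_phenotypes(small_study):
    pheno, fit = derive_phenotypes(small_study.phenotypes)
    return pheno, fit


@pytest.fixture(scope="session")
def study_gwas(small_study, derived_phenotypes):
    """Full 14-trait scan on the small study (shared, read-only)."""
    pheno, _ = derived_phenotypes
    return run_gwas(
        pheno,
        small_study.f2_genotypes(),
        default_trait_fixed_effects(ANALYSIS_TRAITS),
        small_study.relationship,
        traits=ANALYSIS_TRAITS,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_correlation_matrix(rng, n, p=8):
    """Sample correlation matrix of n rows of p-variate noise."""
    X = rng.standard_normal((n, p))
    return np.corrcoef(X)
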