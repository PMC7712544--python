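import numpy as np
import pytest

from epiforest import SimulationSpec, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """1000 subjects x 50 noise variants, balanced-ish classes."""
    spec = SimulationSpec(n_subjects=1000, n_variants=50,
                          maf_range=(0.05, 0.5), case_fraction=0.4, seed=7)
    gm, pheno, truth = simulate(spec)
    return gm, pheno


@pytest.fixture(scope="session")
def planted_cohort():
    """2000 subjects, one strong main effect at index 3 among 40 variants."""
    spec = SimulationSpec(n_subjects=2000, n_variants=40,
                          maf_range=(0.05, 0.5), case_fraction=0.35,
                          main_effects=[(3, 0.8)],
                          maf_overrides=[(3, 0.3)], seed=11)
    gm, pheno, truth = simulate(spec)
    return gm, pheno


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
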