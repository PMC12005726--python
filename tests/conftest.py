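import warnings

import pytest
from hypothesis import HealthCheck, settings

import combiscreen as cs
from combiscreen.simulate import recovery_benchmark_config

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_design() -> cs.LibraryDesign:
    """3 genes × 2 sgRNAs + 2 controls = 8 guides, 64 ordered pairs."""
    return cs.make_design(n_genes=3, n_sgrna_per_gene=2, n_controls=2, seed=11)


@pytest.fixture(scope="session")
def sim_screen():
    """Default-noise 12-gene screen with ten planted interactions."""
    return cs.simulate_counts(recovery_benchmark_config(42))


@pytest.fixture(scope="session")
def scored_screen(sim_screen):
    matrix, truth = sim_screen
    pheno = cs.score_phenotypes(matrix, truth.design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k clamped at gene level by design
        gi = cs.score_interactions(
            pheno, truth.design, cs.InteractionConfig(seed=7, n_perm=999)
        )
    return pheno, gi, truth
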