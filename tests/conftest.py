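import pytest

from tadfscreen import (
    EvolutionConfig,
    MutationSpec,
    enumerate_da_library,
    fixture_fragments,
    run_evolution,
)

SMALL_RUN_CONFIG = dict(
    mutation_label="Sub3",
    library_cap=300,
    max_generations=2,
    seed=7,
)


def small_config() -> EvolutionConfig:
    return EvolutionConfig(
        mutation=MutationSpec.from_label(SMALL_RUN_CONFIG["mutation_label"]),
        library_cap=SMALL_RUN_CONFIG["library_cap"],
        max_generations=SMALL_RUN_CONFIG["max_generations"],
        seed=SMALL_RUN_CONFIG["seed"],
    )


@pytest.fixture(scope="session")
def small_fragments():
    # 20 x 20 couplings exceed the cap of 300, and the library stays large
    # enough that the 10% training draw clears the surrogate's 20-sample minimum
    return fixture_fragments(20, 20, seed=3)


@pytest.fixture(scope="session")
def small_evolution(small_fragments):
    """A quick seeded end-to-end run shared across tests (library cap 200,
    two mutation generations, synthetic oracle)."""
    return run_evolution(small_config(), small_fragments)


@pytest.fixture(scope="session")
def g0_smiles():
    """Generation-0 library (seed 1, full fixture pools) as canonical SMILES."""
    lib = enumerate_da_library(fixture_fragments(30, 43, seed=1), cap=1000, seed=1)
    return lib.smiles()
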