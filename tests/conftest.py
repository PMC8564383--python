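import pytest

from figmark import forge
from figmark.primers import default_primer_pairs, pair_by_name

SEED = 1


@pytest.fixture(scope="session")
def ag_models():
    return forge.build_ag_models(SEED)


@pytest.fixture(scope="session")
def ran1():
    return forge.build_ran1_model(SEED)


@pytest.fixture(scope="session")
def cultivar_panel():
    return forge.build_cultivar_panel(seed=SEED)


@pytest.fixture(scope="session")
def pop1():
    return forge.build_f1_population(seed=SEED, fixed_counts=(110, 132), population="pop1")


@pytest.fixture(scope="session")
def pop2():
    return forge.build_f1_population(seed=SEED, fixed_counts=(49, 36), population="pop2")


@pytest.fixture(scope="session")
def primer_pairs():
    return {p.name: p for p in default_primer_pairs()}
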