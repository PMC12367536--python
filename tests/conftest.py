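import pandas as pd
import pytest

from nsurplus import synth


@pytest.fixture(scope="session")
def mini():
    """12-region miniature dataset (3 per archetype) with truth labels."""
    return synth.make_fixture("mini")


@pytest.fixture(scope="session")
def mini_records(mini) -> pd.DataFrame:
    return mini[0]


@pytest.fixture(scope="session")
def mini_truth(mini) -> pd.Series:
    return mini[1]


@pytest.fixture(scope="session")
def mini_clean():
    """Same layout with noise and heterogeneity off (closed-form curves)."""
    return synth.make_fixture("mini-clean")


@pytest.fixture(scope="session")
def recovery():
    """Default-noise dataset large enough for typology recovery (120 regions)."""
    cfg = synth.GeneratorConfig(n_regions=120, seed=1)
    return synth.generate(cfg)
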