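import numpy as np
import pytest

from gfblup.validate import PanelContext, prepare_panel


@pytest.fixture(scope="session")
def panel_ctx() -> PanelContext:
    """Small factorized synthetic panel shared across test modules."""
    return prepare_panel(150, 400, seed=11)


@pytest.fixture(scope="session")
def medium_ctx() -> PanelContext:
    """Medium panel for REML parameter-recovery checks."""
    return prepare_panel(300, 1200, seed=13)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
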