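import numpy as np
import pytest

from aavsorb.synthetic_data import (
    PanelSpec,
    ToyCapsidSpec,
    generate_toy_capsid,
    simulate_panel,
)


@pytest.fixture(scope="session")
def default_panel():
    """Study-shaped panel: 4 serotypes × 3 surfaces × 2 ionic strengths."""
    return simulate_panel(PanelSpec(seed=11))


@pytest.fixture(scope="session")
def noiseless_panel():
    return simulate_panel(PanelSpec(seed=7, noise_sd=0.0))


@pytest.fixture(scope="session")
def toy_capsid():
    """12-copy shell, 20 pseudo-atoms/copy, zero mutual occlusion."""
    return generate_toy_capsid(ToyCapsidSpec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
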