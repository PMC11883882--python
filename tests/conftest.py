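import numpy as np
import pytest

from gamcast.preprocessing import build_tables
from gamcast.synthetic import (
    PanelSpec,
    default_variable_defs,
    generate_panel,
    inject_missingness,
)


@pytest.fixture(scope="session")
def default_spec() -> PanelSpec:
    return PanelSpec(seed=0)


@pytest.fixture(scope="session")
def default_panel(default_spec):
    """Complete 74-district panel plus ground truth (no missingness)."""
    return generate_panel(default_spec)


@pytest.fixture(scope="session")
def missing_panel(default_spec):
    """Panel after seeded district-wise missingness; truth flags updated."""
    panel, truth = generate_panel(default_spec)
    panel = inject_missingness(panel, default_spec, truth)
    return panel, truth


@pytest.fixture(scope="session")
def analysis_tables(missing_panel):
    panel, _ = missing_panel
    return build_tables(panel)


def null_variable_defs():
    """Generator covariates with every covariate→GAM link switched off."""
    defs = []
    for v in default_variable_defs():
        v.link = "none"
        v.effect_size = 0.0
        defs.append(v)
    return defs


def strong_signal_variable_defs():
    """Covariates in a regime where environmental drivers dominate noise."""
    defs = []
    for v in default_variable_defs():
        if v.link != "none":
            v.effect_size *= 2.0
        defs.append(v)
    return defs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
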