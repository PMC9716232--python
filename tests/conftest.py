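import pytest
from hypothesis import HealthCheck, settings

from fhces import PanelDesign, default_truths, simulate_variant_panel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_design():
    return PanelDesign().noiseless()


@pytest.fixture(scope="session")
def noiseless_panel(noiseless_design):
    """Zero-noise default 21-variant panel (shared; treat as read-only)."""
    truths = default_truths(noiseless_design)
    return simulate_variant_panel(truths, noiseless_design, seed=11)


@pytest.fixture(scope="session")
def noisy_panel():
    """Default panel under the study's stated noise levels."""
    design = PanelDesign()
    return simulate_variant_panel(default_truths(design), design, seed=11)
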