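import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ihcspatial import PatternSpec, PointPattern, Window, generate_pattern

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def unit_window():
    return Window(1.0, 1.0)


@pytest.fixture
def px_window():
    return Window(1000.0, 1000.0)


@pytest.fixture
def csr_pattern(px_window):
    return generate_pattern(PatternSpec("csr", 150, seed=42), px_window)


def make_pattern(regime: str, n: int, window: Window, seed: int,
                 **kwargs) -> PointPattern:
    """Convenience constructor used across test modules."""
    if regime == "thomas_cluster":
        kwargs.setdefault("parent_intensity", 8.0 / window.area)
        kwargs.setdefault("offspring_spread", 0.03 * window.shorter_side)
    if regime == "jittered_lattice":
        kwargs.setdefault("jitter", 0.1)
    return generate_pattern(PatternSpec(regime, n, seed=seed, **kwargs), window)
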