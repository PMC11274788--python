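import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from fcakit.context import FormalContext
from fcakit.datasets import demo_context, demo_labels

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def demo_ctx() -> FormalContext:
    return demo_context()


@pytest.fixture
def demo_y() -> dict:
    return demo_labels()


@st.composite
def contexts(draw, max_objects: int = 10, max_attributes: int = 6):
    """Random small formal contexts for property tests."""
    n = draw(st.integers(1, max_objects))
    m = draw(st.integers(1, max_attributes))
    bits = draw(
        st.lists(st.lists(st.integers(0, 1), min_size=m, max_size=m),
                 min_size=n, max_size=n)
    )
    objects = [f"o{i}" for i in range(n)]
    attributes = [f"m{j}" for j in range(m)]
    return FormalContext(objects, attributes, np.array(bits))


def random_context(rng: np.random.Generator, max_objects: int, max_attributes: int,
                   density: float | None = None) -> FormalContext:
    """Seeded random context (used where many trials are needed)."""
    n = int(rng.integers(1, max_objects + 1))
    m = int(rng.integers(1, max_attributes + 1))
    p = density if density is not None else float(rng.uniform(0.2, 0.8))
    inc = (rng.random((n, m)) < p).astype(int)
    return FormalContext([f"o{i}" for i in range(n)],
                         [f"m{j}" for j in range(m)], inc)
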