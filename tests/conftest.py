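import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from shapely.geometry import Polygon

from granuflux.synthetic_em import Circle, SectionModel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def square_cell(half_nm: float = 3000.0) -> Polygon:
    h = half_nm
    return Polygon([(-h, -h), (h, -h), (h, h), (-h, h)])


@pytest.fixture
def toy_section() -> SectionModel:
    """A hand-built section: one granule, one SLMV, one mitochondrion
    placed at known coordinates inside a square cell profile, so that
    assignment distances can be asserted exactly."""
    return SectionModel(
        cell_type="beta",
        condition="rat",
        boundary=square_cell(3000.0),
        granules=[Circle(0.0, 0.0, 150.0)],
        slmvs=[Circle(1500.0, 0.0, 20.0)],
        mitochondria=[Circle(-1500.0, -1500.0, 300.0)],
    )
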