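import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ecointegrity import GridSpec, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def grid():
    return GridSpec(origin_x=0.0, origin_y=0.0, pixel_size=500.0, ncols=40, nrows=40)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_features(rng, grid, registry, n, threat=None):
    """Random mixed-geometry features; optionally restricted to one threat."""
    from shapely.geometry import LineString, Point, box

    from ecointegrity.threats import ThreatFeature

    specs = [s for s in registry if threat is None or s.threat == threat]
    features = []
    for _ in range(n):
        spec = specs[rng.integers(len(specs))]
        kind = rng.integers(3)
        cx = rng.uniform(grid.origin_x, grid.xmax)
        cy = rng.uniform(grid.origin_y, grid.ymax)
        if kind == 0:
            geom = Point(cx, cy)
        elif kind == 1:
            ang = rng.uniform(0, np.pi)
            h = rng.uniform(500, 5000)
            geom = LineString(
                [(cx - h * np.cos(ang), cy - h * np.sin(ang)),
                 (cx + h * np.cos(ang), cy + h * np.sin(ang))]
            )
        else:
            geom = box(cx - rng.uniform(300, 2000), cy - rng.uniform(300, 2000),
                       cx + rng.uniform(300, 2000), cy + rng.uniform(300, 2000))
        attr = (
            float(rng.uniform(10, 1000))
            if spec.magnitude_rule == "attribute_scaled"
            else None
        )
        features.append(
            ThreatFeature(geometry=geom, threat=spec.threat, category=spec.category,
                          attribute=attr)
        )
    return features
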