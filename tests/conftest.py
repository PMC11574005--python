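import logging

import numpy as np
import pytest

from shapestage.mesh import build_atlas, build_icosphere, mesh_edges

logging.getLogger("shapestage").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def ico2():
    """162-vertex icosphere with its edge list."""
    mesh = build_icosphere(2)
    return mesh, mesh_edges(mesh.faces)


@pytest.fixture(scope="session")
def toy_atlas():
    """Two small bilateral structures (uv spheres), no random rotation."""
    config = [
        {"name": "putamen", "hemisphere": h, "kind": "uv", "rings": 6, "cols": 8,
         "axes": [8.0, 4.0, 3.0], "center": [s * 20.0, 0.0, 0.0], "rotate": False}
        for h, s in [("left", -1), ("right", 1)]
    ] + [
        {"name": "pallidum", "hemisphere": h, "kind": "uv", "rings": 5, "cols": 8,
         "axes": [5.0, 4.0, 3.0], "center": [s * 10.0, 5.0, 0.0], "rotate": False}
        for h, s in [("left", -1), ("right", 1)]
    ]
    return build_atlas(config, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
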