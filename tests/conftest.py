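import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from solvshell import make_static_geometry


@pytest.fixture(scope="session")
def octahedron():
    """Static octahedron: solute + 6 solvent sites at 2.8 A, 3 frames."""
    return make_static_geometry("octahedron", 2.8, n_frames=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_sites(rng, n, radius=6.0, min_r=1.0):
    """n random sites around the origin, radii in [min_r, radius]."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(min_r, radius, size=(n, 1))
    return v * r
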