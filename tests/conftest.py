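import numpy as np
import pytest

from ppiipred import structgeom as sg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_angle_list(rng, n, omega_range=(150.0, 180.0)):
    """Random phi/psi anywhere, omega near trans (avoids degenerate
    near-collinear geometry in the builder)."""
    return [
        {
            "phi": float(rng.uniform(-179.0, 180.0)),
            "psi": float(rng.uniform(-179.0, 180.0)),
            "omega": float(rng.uniform(*omega_range)),
        }
        for _ in range(n)
    ]


def wrapped_diff(a, b):
    return abs((a - b + 180.0) % 360.0 - 180.0)


@pytest.fixture
def ppii_chain():
    """Ideal 6-residue PPII chain flanked by alpha helix."""
    angles = (
        [{"phi": -60.0, "psi": -45.0, "omega": 180.0}] * 8
        + [{"phi": -75.0, "psi": 145.0, "omega": 180.0}] * 6
        + [{"phi": -60.0, "psi": -45.0, "omega": 180.0}] * 8
    )
    return sg.build_backbone(angles)
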