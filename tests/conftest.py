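import numpy as np
import pytest

from shellfract import ShellParams, TriangleMesh, generate_shell

# Faces of an axis-aligned cube on 8 shared vertices.
_CUBE_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],  # z = lo
        [4, 5, 6], [4, 6, 7],  # z = hi
        [0, 1, 5], [0, 5, 4],  # y = lo
        [2, 3, 7], [2, 7, 6],  # y = hi
        [1, 2, 6], [1, 6, 5],  # x = hi
        [3, 0, 4], [3, 4, 7],  # x = lo
    ]
)


def cube_mesh(lo: float = 0.0, hi: float = 1.0, unit: str = "cm") -> TriangleMesh:
    v = np.array(
        [
            [lo, lo, lo], [hi, lo, lo], [hi, hi, lo], [lo, hi, lo],
            [lo, lo, hi], [hi, lo, hi], [hi, hi, hi], [lo, hi, hi],
        ],
        dtype=float,
    )
    return TriangleMesh(v, _CUBE_FACES, unit=unit, id="cube")


@pytest.fixture
def unit_cube() -> TriangleMesh:
    return cube_mesh(0.0, 1.0)


@pytest.fixture
def inset_cube() -> TriangleMesh:
    """Cube [0.05, 0.95]^3 — inscribed in a 10-cell grid it fills the 488 boundary cells."""
    return cube_mesh(0.05, 0.95)


@pytest.fixture(scope="session")
def small_shell() -> TriangleMesh:
    """A light keeled shell (no lirae/increments) shared across modules."""
    params = ShellParams(
        theta_steps=256, phi_steps=96, keel_count=3, keel_amp=0.06,
        lirae_count=0, lirae_amp=0.0, increment_amp=0.0,
    )
    return generate_shell(params, specimen_id="small_shell")
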