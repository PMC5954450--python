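import numpy as np
import pytest

from trabec.phantoms import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def ball_phantom():
    """Ball of radius 12 voxels on an odd grid (centre on a voxel centre)."""
    return generate_phantom(PhantomSpec("ball", (33, 33, 33), 0.01, {"radius": 12}))


@pytest.fixture(scope="session")
def cylinder_phantom():
    """z-axis cylinder, radius 5 voxels, odd grid."""
    return generate_phantom(PhantomSpec("cylinder", (49, 49, 49), 0.01, {"radius": 5}))


@pytest.fixture(scope="session")
def plate_phantom():
    """Plates normal to z: thickness 7, gap 9 voxels."""
    return generate_phantom(
        PhantomSpec("plate_stack", (64, 64, 64), 0.02, {"thickness": 7, "gap": 9})
    )


@pytest.fixture(scope="session")
def lattice_phantom():
    """4x4x4-node rod lattice: spacing 16, rod radius 2."""
    return generate_phantom(
        PhantomSpec("rod_lattice", (49, 49, 49), 0.01, {"spacing": 16, "rod_radius": 2})
    )
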