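import numpy as np
import pytest

from saflex.synthetic import build_backbone, make_ideal_backbone


@pytest.fixture(scope="session")
def helix20():
    """Ideal 20-residue α-helix backbone."""
    return build_backbone(np.full(20, -57.0), np.full(20, -47.0))


@pytest.fixture(scope="session")
def strand20():
    """Ideal 20-residue extended (β) backbone with no H-bond partners."""
    return build_backbone(np.full(20, -119.0), np.full(20, 113.0))


@pytest.fixture(scope="session")
def mixed_structure():
    """Helix–coil–strand backbone used across encoding tests."""
    return make_ideal_backbone("HHHHHHHHCCCCCEEEEEEECCHHHHHH", seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def apply_rigid_transform(structure, rng):
    """Random proper rotation + translation applied to every backbone atom."""
    from scipy.spatial.transform import Rotation

    import copy

    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(scale=20.0, size=3)
    out = copy.deepcopy(structure)
    for name in ("coords_n", "coords_ca", "coords_c", "coords_o"):
        setattr(out, name, getattr(out, name) @ rot.T + shift)
    return out
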