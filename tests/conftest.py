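import numpy as np
import pytest

from isodyn.structure import build_ideal_helix
from isodyn.synthetic import MotionSpec, generate_trajectory, two_chain_fixture


@pytest.fixture(scope="session")
def fixture_complex():
    """The shipped two-chain complex fixture at a small frame count."""
    return two_chain_fixture(n_frames=120)


@pytest.fixture(scope="session")
def small_gaussian_trajectory():
    """60-residue helix with isotropic 0.4 Å displacements, 2000 frames."""
    base = build_ideal_helix(60)
    spec = MotionSpec(sigmas=np.full(60, 0.4), correlation=np.eye(60),
                      n_frames=2000, seed=5)
    return generate_trajectory(base, spec, name="gauss60")
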