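import numpy as np
import pytest

import dimerscan as ds


@pytest.fixture(scope="session")
def monomer():
    """Default idealized 7-TM monomer."""
    return ds.build_ideal_tm_bundle()


@pytest.fixture(scope="session")
def decorated(monomer):
    """Monomer with the complementary TM4/TM5 face decoration."""
    return ds.plant_interface_patch(monomer, ds.PatchSpec())


@pytest.fixture(scope="session")
def contact_poses(decorated):
    """Coarse starting-pose grid on the decorated monomer (6x6)."""
    return ds.enumerate_dimer_poses(decorated, steps_a=6, steps_b=6)


@pytest.fixture(scope="session")
def matched_pose(decorated):
    """The symmetric pose that presents both decorated faces (45_45)."""
    poses = ds.enumerate_dimer_poses(decorated, steps_a=2, steps_b=2)
    return poses[2]  # grid (1, 0): A rotated 180deg, B at 0


@pytest.fixture(scope="session")
def far_dimer(monomer):
    """Two protomers 100 A apart: no contact at all."""
    from dimerscan.structure import concat_chains
    b = monomer.transformed(translation=np.array([100.0, 0.0, 0.0]))
    return concat_chains([("A", monomer), ("B", b)])
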