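import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lipidgate.geometry import AtomRecord, FrameCoordinates, Trajectory
from lipidgate.synthetic import GeneratorConfig, generate_trajectory

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


def make_atoms(specs):
    """Build a topology from (name, resname, resid, chain, element, mass)."""
    return [
        AtomRecord(serial=i + 1, name=s[0], residue_name=s[1], residue_id=s[2],
                   chain_id=s[3], element=s[4], mass=s[5])
        for i, s in enumerate(specs)
    ]


def point_topology(n, chain="A", resid_start=1, mass=12.011):
    """n single-atom residues named CA, one per residue."""
    return make_atoms(
        [("CA", "GLY", resid_start + i, chain, "C", mass) for i in range(n)]
    )


def single_frame_trajectory(topology, positions, time=1.0, interval=0.01):
    return Trajectory(
        topology, [FrameCoordinates(time, np.asarray(positions, float))], interval
    )


def random_rigid_transform(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.normal(scale=10.0, size=3)
    return R, t


@pytest.fixture(scope="session")
def synthetic_3k():
    """A 3000-frame synthetic trajectory with ground truth (fixed seed)."""
    cfg = GeneratorConfig(seed=11, n_frames=3000)
    traj, truth = generate_trajectory(cfg)
    return cfg, traj, truth
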