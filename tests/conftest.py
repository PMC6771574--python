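import numpy as np
import pytest

import littplan as lp


@pytest.fixture(scope="session")
def phantom_default():
    """One open-corridor phantom shared by read-only tests."""
    return lp.generate_phantom(lp.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def scene_default(phantom_default):
    vol, role_map, _ = phantom_default
    return lp.build_scene(vol, role_map)


@pytest.fixture(scope="session")
def plans_default(scene_default):
    """Ranked plans for all three methods on the shared phantom."""
    constraints = lp.PlanningConstraints()
    return {
        method: lp.plan(scene_default, constraints, lp.TargetSpec(method), k=50)
        for method in ("centroid_T2", "expert_T3", "ml_T4")
    }


def identity_affine(offset=0.0):
    a = np.eye(4)
    a[:3, 3] = offset
    return a


def straight_vessel_field(offset_mm=0.0, shape=(64, 64, 64)):
    """Distance field of a straight vessel along y at world x=z=0."""
    affine = identity_affine(-np.floor(np.array(shape) / 2.0))
    vessel = np.zeros(shape, dtype=bool)
    cx, cz = shape[0] // 2, shape[2] // 2
    vessel[cx, 4 : shape[1] - 4, cz] = True
    return lp.distance_field(lp.BinaryMask(vessel, affine))
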