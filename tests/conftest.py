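"""Shared fixtures: bundled demo model and a reduced-resolution avatar stack.

Heavy objects (mesh, weights, collision shapes) are session-scoped; tests must
not mutate them.
"""
import numpy as np
import pytest

from skelsynth import (
    MorphologyParams,
    build_armature,
    build_collision_shapes,
    compute_weights,
    demo_model,
    generate_avatar,
    rest_transforms,
)
from skelsynth.skeletal_model import (
    BodySegment,
    Coordinate,
    Dof,
    Joint,
    SkeletalModel,
)


@pytest.fixture(scope="session")
def model():
    return demo_model()


@pytest.fixture(scope="session")
def rest(model):
    return rest_transforms(model)


@pytest.fixture(scope="session")
def small_avatar(model, rest):
    """Reduced-resolution avatar (fast); full 7,500-vertex meshes are built
    only where the check is about the default resolution itself."""
    return generate_avatar(model, MorphologyParams(mesh_resolution=2000), rest)


@pytest.fixture(scope="session")
def armature(model, rest):
    return build_armature(model, rest)


@pytest.fixture(scope="session")
def weights(small_avatar, armature):
    return compute_weights(small_avatar, armature)


@pytest.fixture(scope="session")
def shapes(small_avatar, weights, rest):
    return build_collision_shapes(small_avatar, weights.vertex_bodies(), rest)


def make_hinge_chain(n_links=2, link_length=0.4, axis=(0, 0, 1)):
    """A serial chain of `n_links` bodies under 1-DOF hinges (first joint is a
    6-DOF-free-less root: translation-free hinge to ground)."""
    bodies = [BodySegment(f"link{i}") for i in range(n_links)]
    coords = [Coordinate(f"q{i}", -np.pi, np.pi) for i in range(n_links)]
    joints = [
        Joint("j0", "ground", "link0", location_in_parent=(0.0, 1.0, 0.0),
              location_in_child=(0.0, 0.0, 0.0),
              dofs=[Dof("q0", "rotation", axis)])
    ]
    for i in range(1, n_links):
        joints.append(Joint(f"j{i}", f"link{i-1}", f"link{i}",
                            location_in_parent=(0.0, -link_length, 0.0),
                            location_in_child=(0.0, 0.0, 0.0),
                            dofs=[Dof(f"q{i}", "rotation", axis)]))
    return SkeletalModel(name=f"chain{n_links}", bodies=bodies, joints=joints,
                         coordinates=coords, markers=[])


@pytest.fixture
def toy_model():
    """Two-body toy model: pelvis + femur under a 1-DOF hinge."""
    return SkeletalModel(
        name="toy",
        bodies=[BodySegment("pelvis"), BodySegment("femur")],
        joints=[
            Joint("ground_pelvis", "ground", "pelvis",
                  location_in_parent=(0.0, 1.0, 0.0), location_in_child=(0.0, 0.0, 0.0),
                  dofs=[]),
            Joint("hip", "pelvis", "femur",
                  location_in_parent=(0.1, -0.05, 0.0), location_in_child=(0.0, 0.0, 0.0),
                  dofs=[Dof("hip_flexion", "rotation", (0, 0, 1))]),
        ],
        coordinates=[Coordinate("hip_flexion", -np.pi, np.pi)],
        markers=[],
    )
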