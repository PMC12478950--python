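"""Reflection transforms: point/mesh/orientation/inertia/joint/muscle and the
bilateral merge, checked against matrix-conjugation and forward-kinematics
oracles plus the involution property."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bimanum.fk import ModelKinematics, euler_xyz_to_matrix
from bimanum.mirroring import (
    MirrorConvention,
    build_bilateral,
    mirror_body,
    mirror_inertia,
    mirror_joint,
    mirror_mesh,
    mirror_model,
    mirror_muscle,
    mirror_orientation,
    mirror_point,
)
from bimanum.model import Mesh

CONV = MirrorConvention()
M = np.diag([1.0, 1.0, -1.0])

finite_coord = st.floats(-10, 10, allow_nan=False)
angles = st.floats(-3.0, 3.0, allow_nan=False)


def test_mirror_point_examples():
    np.testing.assert_array_equal(mirror_point([0, 0, 0]), [0, 0, 0])
    np.testing.assert_array_equal(mirror_point([0.1, 0.2, 0.05]), [0.1, 0.2, -0.05])


@given(st.tuples(finite_coord, finite_coord, finite_coord))
@settings(max_examples=50, deadline=None)
def test_mirror_point_involution(p):
    np.testing.assert_array_equal(mirror_point(mirror_point(p)), np.asarray(p))


def test_mirror_mesh_preserves_signed_volume():
    tet = Mesh(
        vertices=[[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]],
        faces=[[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]],
    )
    mirrored = mirror_mesh(tet)
    # winding reversal keeps outward orientation: signed volume sign preserved
    assert np.isclose(mirrored.signed_volume(), tet.signed_volume())
    back = mirror_mesh(mirrored)
    np.testing.assert_array_equal(back.vertices, tet.vertices)
    np.testing.assert_array_equal(back.faces, tet.faces)


def test_sagittal_plane_triangle_vertices_fixed():
    tri = Mesh(vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]], faces=[[0, 1, 2]])
    m = mirror_mesh(tri)
    np.testing.assert_array_equal(m.vertices, tri.vertices)
    np.testing.assert_array_equal(m.faces, [[2, 1, 0]])


def test_mirror_orientation_against_conjugation_oracle():
    for e in ([0.0, 0.0, 0.0], [0.3, -0.1, 0.5], [1.2, 0.7, -2.0], [-0.4, 1.5, 0.1]):
        out = mirror_orientation(e)
        R_out = euler_xyz_to_matrix(out)
        R_oracle = M @ euler_xyz_to_matrix(e) @ M
        np.testing.assert_allclose(R_out, R_oracle, atol=1e-12)
        assert np.isclose(np.linalg.det(R_out), 1.0)
    # z-normal convention: x- and y-rotations negate, z preserved
    np.testing.assert_allclose(mirror_orientation([0.3, -0.1, 0.5]), [-0.3, 0.1, 0.5],
                               atol=1e-12)


def test_pure_z_rotation_preserved():
    for theta in (0.4, -1.1, 2.9):
        np.testing.assert_allclose(mirror_orientation([0, 0, theta]), [0, 0, theta], atol=1e-12)


@given(st.tuples(angles, angles, angles))
@settings(max_examples=50, deadline=None)
def test_mirror_orientation_involution_as_rotation(e):
    twice = mirror_orientation(mirror_orientation(e))
    np.testing.assert_allclose(
        euler_xyz_to_matrix(twice), euler_xyz_to_matrix(e), atol=1e-9
    )


def test_gimbal_lock_branch_is_consistent():
    e = np.array([0.3, np.pi / 2, 0.5])
    out = mirror_orientation(e)
    np.testing.assert_allclose(
        euler_xyz_to_matrix(out), M @ euler_xyz_to_matrix(e) @ M, atol=1e-9
    )


def test_mirror_inertia():
    diag = [1.0, 2.0, 3.0, 0.0, 0.0, 0.0]
    np.testing.assert_array_equal(mirror_inertia(diag), diag)
    with_products = np.array([1.0, 2.0, 3.0, 0.04, 0.01, -0.02])
    out = mirror_inertia(with_products)
    np.testing.assert_array_equal(out, [1.0, 2.0, 3.0, 0.04, -0.01, 0.02])

    def eig(i6):
        xx, yy, zz, xy, xz, yz = i6
        return np.sort(np.linalg.eigvalsh([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]]))

    np.testing.assert_allclose(eig(out), eig(with_products), atol=1e-12)
    np.testing.assert_array_equal(mirror_inertia(out), with_products)


def test_mirror_body(model):
    hum = model.body("humerus_r")
    out = mirror_body(hum)
    assert out.name == "humerus_l"
    assert out.mass == hum.mass
    np.testing.assert_array_equal(out.com, hum.com * [1, 1, -1])
    assert out.mesh_refs[0].file == "humerus_mirrored.vtp"
    back = mirror_body(out)
    assert back.name == hum.name
    assert back.mesh_refs[0].file == "humerus.vtp"
    np.testing.assert_array_equal(back.com, hum.com)


def test_mirror_joint_roundtrip_and_axes(model):
    shoulder = model.joint("shoulder_r")
    left = mirror_joint(shoulder)
    assert left.name == "shoulder_l"
    assert left.parent == "thorax" and left.child == "humerus_l"
    np.testing.assert_array_equal(
        left.location_in_parent, shoulder.location_in_parent * [1, 1, -1]
    )
    # rotation axes flip as a -> -M a; ranges/defaults unchanged
    for ax_r, ax_l in zip(shoulder.spatial_transform, left.spatial_transform):
        np.testing.assert_allclose(ax_l.axis, -(M @ ax_r.axis), atol=1e-15)
    for c_r, c_l in zip(shoulder.coordinates, left.coordinates):
        assert c_l.range == c_r.range and c_l.default == c_r.default
    back = mirror_joint(left)
    np.testing.assert_allclose(back.location_in_parent, shoulder.location_in_parent, atol=1e-12)
    for ax_b, ax_r in zip(back.spatial_transform, shoulder.spatial_transform):
        np.testing.assert_allclose(ax_b.axis, ax_r.axis, atol=1e-12)


def test_unsupported_joint_class_rejected(model):
    j = model.joint("shoulder_r")
    import copy

    bad = copy.deepcopy(j)
    bad.joint_class = "EllipsoidJoint"
    with pytest.raises(ValueError, match="EllipsoidJoint"):
        mirror_joint(bad)


def test_mirror_muscle_preserves_fmax_and_is_involutive(model):
    supra = model.muscle("supraspinatus_r")
    left = mirror_muscle(supra)
    assert left.name == "supraspinatus_l"
    assert left.max_isometric_force == supra.max_isometric_force
    back = mirror_muscle(left)
    for p1, p2 in zip(back.path, supra.path):
        assert p1.body == p2.body
        np.testing.assert_array_equal(p1.location, p2.location)


def test_full_model_mirror_involution(model):
    twice = mirror_model(mirror_model(model))
    assert twice.equals(model, rtol=1e-12)


def test_build_bilateral_counts_and_mass(model, bilateral):
    assert len(bilateral.muscles) == 2 * len(model.muscles)
    assert len(list(bilateral.coordinates())) == 2 * len(list(model.coordinates()))
    # thorax appears once; total mass = trunk + 2 x limb
    limb = model.body("humerus_r").mass + model.body("forearm_hand_r").mass
    assert np.isclose(bilateral.total_mass(), model.body("thorax").mass + 2 * limb)


def test_build_bilateral_name_collision_rejected(model):
    m = model.copy()
    m.bodies.append(mirror_body(m.body("humerus_r")))
    with pytest.raises(ValueError, match="collide"):
        build_bilateral(m)


def _symmetric_pose(names, rng):
    q = {}
    for n in names:
        if n.endswith("_r"):
            v = rng.uniform(0.05, 0.8)
            q[n] = v
            q[n[:-2] + "_l"] = v
    return q


def test_fk_mirror_symmetry_oracle(bilateral, rng):
    """Equal coordinate values on both sides place every right-side station
    at the mirror image of its left-side twin."""
    kin = ModelKinematics(bilateral)
    for _ in range(5):
        q = _symmetric_pose(kin.free_coords, rng)
        X = kin.body_transforms(q)
        for body_r, local in [
            ("humerus_r", np.array([0.0, -0.3, 0.0])),
            ("forearm_hand_r", np.array([0.0, -0.3, 0.0])),
            ("forearm_hand_r", np.array([0.02, -0.15, 0.01])),
        ]:
            p_r = kin.station(X, body_r, local)
            p_l = kin.station(X, body_r[:-2] + "_l", local * [1, 1, -1])
            assert np.abs(p_r - p_l * [1, 1, -1]).max() < 1e-9


def test_muscle_length_symmetry(bilateral, rng):
    kin = ModelKinematics(bilateral)
    names = [m.name for m in bilateral.muscles]
    for _ in range(5):
        q = _symmetric_pose(kin.free_coords, rng)
        L = kin.muscle_lengths(kin.body_transforms(q))
        for i, n in enumerate(names):
            if n.endswith("_r"):
                assert abs(L[i] - L[names.index(n[:-2] + "_l")]) < 1e-9


def test_proper_rotations_throughout(bilateral):
    kin = ModelKinematics(bilateral)
    X = kin.body_transforms({})
    for Xb in X:
        assert np.isclose(np.linalg.det(Xb[:3, :3]), 1.0, atol=1e-12)
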