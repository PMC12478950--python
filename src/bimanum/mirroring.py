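"""Mid-sagittal mirroring: build a bilateral model from a unilateral one.

Reflection across the plane through the ground origin with normal along the
medial/lateral axis (z by default) is applied consistently to meshes, body
mass properties, joint frames, spatial-transform axes and muscle paths, and
the mirrored components are merged with the originals into one model.

Sign policy for coordinates: conjugating a rotation by the reflection M
gives M R(a, q) M = R(M a, -q) = R(-M a, q), so every rotation axis is
mapped a -> -M a and the coordinate value keeps its sign. Equal coordinate
values on the two sides then produce mirror-symmetric postures, which is what
lets one mirrored kinematics file drive both limbs.
"""
from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fk import euler_xyz_to_matrix, matrix_to_euler_xyz
from .model import (
    BodyDef,
    ConstraintDef,
    JointDef,
    Mesh,
    MeshRef,
    ModelDef,
    MuscleDef,
    PathPoint,
)

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class MirrorConvention:
    """How to reflect: which ground axis is medial/lateral, and how
    side-suffixed names map to their contralateral twins."""

    sagittal_normal_axis: str = "z"
    suffix_pairs: list[tuple[str, str]] = field(default_factory=lambda: [("_r", "_l")])

    def __post_init__(self) -> None:
        if self.sagittal_normal_axis not in _AXIS_INDEX:
            raise ValueError(f"axis must be one of x, y, z; got {self.sagittal_normal_axis!r}")

    @property
    def axis_index(self) -> int:
        return _AXIS_INDEX[self.sagittal_normal_axis]

    def reflection(self) -> np.ndarray:
        M = np.eye(3)
        M[self.axis_index, self.axis_index] = -1.0
        return M

    def map_name(self, name: str) -> str:
        """Swap the side suffix; names without one are returned unchanged.

        The map is an involution: applying it twice is the identity.
        """
        for a, b in self.suffix_pairs:
            if name.endswith(a):
                return name[: -len(a)] + b
            if name.endswith(b):
                return name[: -len(b)] + a
        return name

    def is_sided(self, name: str) -> bool:
        return self.map_name(name) != name

    @classmethod
    def from_suffix_spec(cls, spec: str, axis: str = "z") -> "MirrorConvention":
        """Parse e.g. ``"_r:_l"`` (comma-separated pairs) from the CLI."""
        pairs = []
        for chunk in spec.split(","):
            a, b = chunk.split(":")
            pairs.append((a, b))
        return cls(sagittal_normal_axis=axis, suffix_pairs=pairs)


_DEFAULT = MirrorConvention()


def mirror_point(p, convention: MirrorConvention = _DEFAULT) -> np.ndarray:
    """Reflect a point/vector: negate the component along the mirror normal."""
    out = np.asarray(p, float).copy()
    out[convention.axis_index] = -out[convention.axis_index]
    return out


def mirror_mesh(mesh: Mesh, convention: MirrorConvention = _DEFAULT) -> Mesh:
    """Reflect every vertex and reverse triangle winding so outward normals
    stay outward (a reflection alone turns the surface inside out)."""
    verts = mesh.vertices.copy()
    verts[:, convention.axis_index] = -verts[:, convention.axis_index]
    faces = mesh.faces[:, ::-1].copy()
    return Mesh(vertices=verts, faces=faces)


def mirror_orientation(euler_xyz, convention: MirrorConvention = _DEFAULT) -> np.ndarray:
    """Euler angles (body-fixed XYZ) of the reflection-conjugated rotation
    M R M. The result is always a proper rotation (det +1): with the z-normal
    convention, x- and y-rotations negate and z-rotations are preserved."""
    M = convention.reflection()
    R = euler_xyz_to_matrix(euler_xyz)
    return matrix_to_euler_xyz(M @ R @ M)


def mirror_inertia(inertia6, convention: MirrorConvention = _DEFAULT) -> np.ndarray:
    """Mirror an inertia 6-vector (Ixx,Iyy,Izz,Ixy,Ixz,Iyz): M I M^T negates
    the two products involving the mirror axis; eigenvalues are preserved."""
    xx, yy, zz, xy, xz, yz = np.asarray(inertia6, float)
    k = convention.axis_index
    if k == 0:
        xy, xz = -xy, -xz
    elif k == 1:
        xy, yz = -xy, -yz
    else:
        xz, yz = -xz, -yz
    return np.array([xx, yy, zz, xy, xz, yz])


def mirror_mesh_filename(file: str) -> str:
    """Toggle the ``_mirrored`` marker on a mesh file name (involution)."""
    p = Path(file)
    stem = p.stem
    if stem.endswith("_mirrored"):
        return stem[: -len("_mirrored")] + p.suffix
    return stem + "_mirrored" + p.suffix


def mirror_body(b: BodyDef, convention: MirrorConvention = _DEFAULT) -> BodyDef:
    return BodyDef(
        name=convention.map_name(b.name),
        mass=b.mass,
        com=mirror_point(b.com, convention),
        inertia=mirror_inertia(b.inertia, convention),
        mesh_refs=[MeshRef(file=mirror_mesh_filename(m.file), scale=m.scale.copy())
                   for m in b.mesh_refs],
        extra_xml=[copy.deepcopy(e) for e in b.extra_xml],
    )


def mirror_joint(j: JointDef, convention: MirrorConvention = _DEFAULT) -> JointDef:
    """Mirror a joint: frames reflected, rotation axes a -> -M a (coordinate
    sign kept), translation axes a -> M a, names side-swapped. Ranges and
    defaults carry over unchanged because the coordinate sign is preserved."""
    if j.joint_class not in ("CustomJoint", "WeldJoint", "PinJoint"):
        raise ValueError(f"cannot mirror joint class {j.joint_class!r}")
    M = convention.reflection()
    out = JointDef(
        name=convention.map_name(j.name),
        joint_class=j.joint_class,
        parent=convention.map_name(j.parent),
        child=convention.map_name(j.child),
        location_in_parent=mirror_point(j.location_in_parent, convention),
        orientation_in_parent=mirror_orientation(j.orientation_in_parent, convention),
        location_in_child=mirror_point(j.location_in_child, convention),
        orientation_in_child=mirror_orientation(j.orientation_in_child, convention),
    )
    for c in j.coordinates:
        cc = copy.deepcopy(c)
        cc.name = convention.map_name(c.name)
        out.coordinates.append(cc)
    for ax in j.spatial_transform:
        new_axis = (-M @ ax.axis) if ax.kind == "rotation" else (M @ ax.axis)
        out.spatial_transform.append(
            type(ax)(
                name=ax.name,
                kind=ax.kind,
                axis=new_axis,
                coordinate=convention.map_name(ax.coordinate) if ax.coordinate else None,
            )
        )
    return out


def mirror_muscle(m: MuscleDef, convention: MirrorConvention = _DEFAULT) -> MuscleDef:
    return MuscleDef(
        name=convention.map_name(m.name),
        max_isometric_force=m.max_isometric_force,
        path=[
            PathPoint(body=convention.map_name(p.body), location=mirror_point(p.location, convention))
            for p in m.path
        ],
        optimal_fiber_length=m.optimal_fiber_length,
        tendon_slack_length=m.tendon_slack_length,
        class_name=m.class_name,
        extra_xml=[copy.deepcopy(e) for e in m.extra_xml],
    )


def mirror_constraint(c: ConstraintDef, convention: MirrorConvention = _DEFAULT) -> ConstraintDef:
    return ConstraintDef(
        name=convention.map_name(c.name),
        body_1=convention.map_name(c.body_1),
        body_2=convention.map_name(c.body_2),
        location_body_1=mirror_point(c.location_body_1, convention),
        orientation_body_1=mirror_orientation(c.orientation_body_1, convention),
        location_body_2=mirror_point(c.location_body_2, convention),
        orientation_body_2=mirror_orientation(c.orientation_body_2, convention),
        kind=c.kind,
    )


def build_bilateral(
    model: ModelDef,
    convention: MirrorConvention = _DEFAULT,
    meshes: dict[str, Mesh] | None = None,
) -> tuple[ModelDef, dict[str, Mesh]]:
    """Merge a one-sided model with its mirror image.

    Side-suffixed components (per the convention's name map) gain a mirrored
    twin; shared trunk/ground components appear once. Returns the bilateral
    model and a dict of newly mirrored meshes keyed by file name (empty if no
    meshes were supplied).

    Raises ``ValueError`` if a mirrored name collides with an existing one.
    """
    out = model.copy()
    new_names: list[str] = []

    sided_bodies = [b for b in model.bodies if convention.is_sided(b.name)]
    for b in sided_bodies:
        out.bodies.append(mirror_body(b, convention))
        new_names.append(out.bodies[-1].name)
    for j in model.joints:
        if convention.is_sided(j.child):
            out.joints.append(mirror_joint(j, convention))
            new_names.append(out.joints[-1].name)
    for m in model.muscles:
        if convention.is_sided(m.name) or any(convention.is_sided(p.body) for p in m.path):
            out.muscles.append(mirror_muscle(m, convention))
            new_names.append(out.muscles[-1].name)
    for c in model.constraints:
        if convention.is_sided(c.body_1) or convention.is_sided(c.body_2):
            out.constraints.append(mirror_constraint(c, convention))
            new_names.append(out.constraints[-1].name)

    collisions = sorted(
        set(new_names)
        & (
            {b.name for b in model.bodies}
            | {j.name for j in model.joints}
            | {m.name for m in model.muscles}
            | {c.name for c in model.constraints}
        )
    )
    if collisions:
        raise ValueError(f"mirrored names collide with existing components: {collisions}")

    mirrored_meshes: dict[str, Mesh] = {}
    if meshes:
        for b in sided_bodies:
            for mref in b.mesh_refs:
                if mref.file in meshes:
                    mirrored_meshes[mirror_mesh_filename(mref.file)] = mirror_mesh(
                        meshes[mref.file], convention
                    )

    out.validate()
    return out, mirrored_meshes


def mirror_model(model: ModelDef, convention: MirrorConvention = _DEFAULT) -> ModelDef:
    """Mirror every component of a model (no merging). Applying this twice
    returns the original model — the involution property."""
    out = ModelDef(
        name=model.name,
        gravity=model.gravity.copy(),
        bodies=[mirror_body(b, convention) for b in model.bodies],
        joints=[mirror_joint(j, convention) for j in model.joints],
        muscles=[mirror_muscle(m, convention) for m in model.muscles],
        constraints=[mirror_constraint(c, convention) for c in model.constraints],
        extra_xml=[copy.deepcopy(e) for e in model.extra_xml],
    )
    return out
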