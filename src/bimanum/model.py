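"""In-memory containers for the subset of musculoskeletal-model content the
toolkit manipulates.

The containers mirror the OpenSim 3.3 ``.osim`` dialect closely enough for a
lossless round trip of the elements we transform (bodies, custom/weld joints,
coordinates, muscle actuators with path points, weld constraints); everything
else read from a file is carried as opaque XML and re-emitted verbatim.

Internal units are SI throughout: metres, kilograms, newtons, radians.
Degree-valued motion files are converted at the I/O boundary.
"""
from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

GRAVITY_DEFAULT = (0.0, -9.80665, 0.0)
STANDARD_GRAVITY = 9.80665  # m/s^2


class ModelValidationError(ValueError):
    """A model violates a structural invariant (dangling reference, bad range...)."""


def _vec3(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).reshape(3)
    return a


@dataclass
class PathPoint:
    """A via/attachment point of a muscle path, fixed in a body frame."""

    body: str
    location: np.ndarray

    def __post_init__(self) -> None:
        self.location = _vec3(self.location)
        if not np.all(np.isfinite(self.location)):
            raise ModelValidationError(f"path point on {self.body!r} has non-finite location")


@dataclass
class MuscleDef:
    """A muscle actuator: a geometric path plus a peak isometric force.

    The reduced solver treats muscles as rigid-tendon, activation-linear force
    generators, so only ``max_isometric_force`` and the path enter mechanics;
    fiber/tendon lengths are carried through for file fidelity.
    """

    name: str
    max_isometric_force: float
    path: list[PathPoint]
    optimal_fiber_length: float = 0.1
    tendon_slack_length: float = 0.05
    class_name: str = "Thelen2003Muscle"
    extra_xml: list = field(default_factory=list)

    def validate(self) -> None:
        if len(self.path) < 2:
            raise ModelValidationError(f"muscle {self.name!r} needs >= 2 path points")
        if self.max_isometric_force < 0:
            raise ModelValidationError(f"muscle {self.name!r} has negative Fmax")


@dataclass
class CoordinateDef:
    name: str
    kind: str = "rotational"  # or "translational"
    range: tuple[float, float] = (-np.pi, np.pi)
    default: float = 0.0
    locked: bool = False

    def validate(self) -> None:
        lo, hi = self.range
        if not (lo <= self.default <= hi):
            raise ModelValidationError(
                f"coordinate {self.name!r}: default {self.default} outside range [{lo}, {hi}]"
            )


@dataclass
class TransformAxis:
    """One axis of a custom joint's spatial transform.

    ``kind`` is "rotation" or "translation"; ``coordinate`` names the model
    coordinate driving the axis, or None for a constant-zero axis.
    """

    name: str
    kind: str
    axis: np.ndarray
    coordinate: str | None = None

    def __post_init__(self) -> None:
        self.axis = _vec3(self.axis)

    def validate(self) -> None:
        n = float(np.linalg.norm(self.axis))
        if abs(n - 1.0) > 1e-8:
            raise ModelValidationError(f"transform axis {self.name!r} not unit norm (|a|={n})")


@dataclass
class JointDef:
    """A joint owned by its child body, connecting a frame in the parent to a
    frame in the child. ``spatial_transform`` is ordered rotation1..3 then
    translation1..3 as in the 3.3 dialect; weld joints have none.
    """

    name: str
    joint_class: str  # "CustomJoint" | "WeldJoint"
    parent: str
    child: str
    location_in_parent: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation_in_parent: np.ndarray = field(default_factory=lambda: np.zeros(3))
    location_in_child: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation_in_child: np.ndarray = field(default_factory=lambda: np.zeros(3))
    coordinates: list[CoordinateDef] = field(default_factory=list)
    spatial_transform: list[TransformAxis] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.location_in_parent = _vec3(self.location_in_parent)
        self.orientation_in_parent = _vec3(self.orientation_in_parent)
        self.location_in_child = _vec3(self.location_in_child)
        self.orientation_in_child = _vec3(self.orientation_in_child)

    def validate(self) -> None:
        for c in self.coordinates:
            c.validate()
        for ax in self.spatial_transform:
            ax.validate()
            if ax.coordinate is not None and ax.coordinate not in {c.name for c in self.coordinates}:
                raise ModelValidationError(
                    f"joint {self.name!r}: transform axis {ax.name!r} cites unknown "
                    f"coordinate {ax.coordinate!r}"
                )


@dataclass
class MeshRef:
    file: str
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.scale = _vec3(self.scale)


@dataclass
class BodyDef:
    """A rigid segment: mass properties plus display-mesh references.

    ``inertia`` is the 6-vector (Ixx, Iyy, Izz, Ixy, Ixz, Iyz) about the body
    COM in the body frame, kg*m^2.
    """

    name: str
    mass: float
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))
    inertia: np.ndarray = field(default_factory=lambda: np.zeros(6))
    mesh_refs: list[MeshRef] = field(default_factory=list)
    extra_xml: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.com = _vec3(self.com)
        self.inertia = np.asarray(self.inertia, dtype=float).reshape(6)

    def inertia_matrix(self) -> np.ndarray:
        xx, yy, zz, xy, xz, yz = self.inertia
        return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])

    def validate(self) -> None:
        if self.mass < 0:
            raise ModelValidationError(f"body {self.name!r} has negative mass")
        eig = np.linalg.eigvalsh(self.inertia_matrix())
        if eig.min() < -1e-9 * max(1.0, eig.max()):
            raise ModelValidationError(f"body {self.name!r} inertia not positive semidefinite")


@dataclass
class ConstraintDef:
    """A weld constraint closing a kinematic loop between two bodies."""

    name: str
    body_1: str
    body_2: str
    location_body_1: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation_body_1: np.ndarray = field(default_factory=lambda: np.zeros(3))
    location_body_2: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation_body_2: np.ndarray = field(default_factory=lambda: np.zeros(3))
    kind: str = "weld"

    def __post_init__(self) -> None:
        self.location_body_1 = _vec3(self.location_body_1)
        self.orientation_body_1 = _vec3(self.orientation_body_1)
        self.location_body_2 = _vec3(self.location_body_2)
        self.orientation_body_2 = _vec3(self.orientation_body_2)


GROUND = "ground"


@dataclass
class ModelDef:
    """A musculoskeletal model: bodies, joints, muscle actuators, constraints."""

    name: str = "model"
    gravity: np.ndarray = field(default_factory=lambda: np.asarray(GRAVITY_DEFAULT))
    bodies: list[BodyDef] = field(default_factory=list)
    joints: list[JointDef] = field(default_factory=list)
    muscles: list[MuscleDef] = field(default_factory=list)
    constraints: list[ConstraintDef] = field(default_factory=list)
    extra_xml: list = field(default_factory=list)
    # Snapshot of pristine peak isometric forces, populated the first time a
    # tear severity is applied so severities scale absolute baselines and
    # never compound. In-memory only; not serialized.
    fmax_baseline: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.gravity = _vec3(self.gravity)

    # -- lookups ------------------------------------------------------------
    def body_names(self) -> set[str]:
        return {b.name for b in self.bodies}

    def body(self, name: str) -> BodyDef:
        for b in self.bodies:
            if b.name == name:
                return b
        raise KeyError(f"no body named {name!r}")

    def joint(self, name: str) -> JointDef:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(f"no joint named {name!r}")

    def muscle(self, name: str) -> MuscleDef:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(f"no muscle named {name!r}")

    def coordinates(self) -> Iterator[CoordinateDef]:
        for j in self.joints:
            yield from j.coordinates

    def coordinate(self, name: str) -> CoordinateDef:
        for c in self.coordinates():
            if c.name == name:
                return c
        raise KeyError(f"no coordinate named {name!r}")

    def free_coordinate_names(self) -> list[str]:
        return [c.name for c in self.coordinates() if not c.locked]

    def default_pose(self) -> dict[str, float]:
        return {c.name: c.default for c in self.coordinates()}

    def total_mass(self) -> float:
        return float(sum(b.mass for b in self.bodies))

    def copy(self) -> "ModelDef":
        return _copy.deepcopy(self)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        names = [b.name for b in self.bodies]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ModelValidationError(f"duplicate body names: {dupes}")
        known = set(names) | {GROUND}
        for b in self.bodies:
            b.validate()
        coord_names: list[str] = []
        for j in self.joints:
            if j.parent not in known:
                raise ModelValidationError(f"joint {j.name!r} cites unknown parent body {j.parent!r}")
            if j.child not in known:
                raise ModelValidationError(f"joint {j.name!r} cites unknown child body {j.child!r}")
            j.validate()
            coord_names.extend(c.name for c in j.coordinates)
        if len(coord_names) != len(set(coord_names)):
            dupes = sorted({n for n in coord_names if coord_names.count(n) > 1})
            raise ModelValidationError(f"duplicate coordinate names: {dupes}")
        for m in self.muscles:
            m.validate()
            for p in m.path:
                if p.body not in known:
                    raise ModelValidationError(
                        f"muscle {m.name!r} path point cites unknown body {p.body!r}"
                    )
        for c in self.constraints:
            for ref in (c.body_1, c.body_2):
                if ref not in known:
                    raise ModelValidationError(f"constraint {c.name!r} cites unknown body {ref!r}")

    # -- structural equality (float-tolerant) -------------------------------
    def equals(self, other: "ModelDef", rtol: float = 1e-9) -> bool:
        return models_equal(self, other, rtol=rtol)


def _close(a, b, rtol) -> bool:
    return np.allclose(np.asarray(a, float), np.asarray(b, float), rtol=rtol, atol=rtol)


def models_equal(a: ModelDef, b: ModelDef, rtol: float = 1e-9) -> bool:
    """Field-wise structural equality of two models, floats to ``rtol``."""
    if a.name != b.name or not _close(a.gravity, b.gravity, rtol):
        return False
    if len(a.bodies) != len(b.bodies) or len(a.joints) != len(b.joints):
        return False
    if len(a.muscles) != len(b.muscles) or len(a.constraints) != len(b.constraints):
        return False
    for x, y in zip(a.bodies, b.bodies):
        if x.name != y.name or not _close(x.mass, y.mass, rtol):
            return False
        if not (_close(x.com, y.com, rtol) and _close(x.inertia, y.inertia, rtol)):
            return False
        if [(m.file, tuple(m.scale)) for m in x.mesh_refs] != [
            (m.file, tuple(m.scale)) for m in y.mesh_refs
        ]:
            return False
    for x, y in zip(a.joints, b.joints):
        if (x.name, x.joint_class, x.parent, x.child) != (y.name, y.joint_class, y.parent, y.child):
            return False
        for fx, fy in (
            (x.location_in_parent, y.location_in_parent),
            (x.orientation_in_parent, y.orientation_in_parent),
            (x.location_in_child, y.location_in_child),
            (x.orientation_in_child, y.orientation_in_child),
        ):
            if not _close(fx, fy, rtol):
                return False
        if len(x.coordinates) != len(y.coordinates) or len(x.spatial_transform) != len(
            y.spatial_transform
        ):
            return False
        for cx, cy in zip(x.coordinates, y.coordinates):
            if cx.name != cy.name or cx.kind != cy.kind or cx.locked != cy.locked:
                return False
            if not (_close(cx.range, cy.range, rtol) and _close(cx.default, cy.default, rtol)):
                return False
        for tx, ty in zip(x.spatial_transform, y.spatial_transform):
            if (tx.name, tx.kind, tx.coordinate) != (ty.name, ty.kind, ty.coordinate):
                return False
            if not _close(tx.axis, ty.axis, rtol):
                return False
    for mx, my in zip(a.muscles, b.muscles):
        if mx.name != my.name or not _close(mx.max_isometric_force, my.max_isometric_force, rtol):
            return False
        if len(mx.path) != len(my.path):
            return False
        for px, py in zip(mx.path, my.path):
            if px.body != py.body or not _close(px.location, py.location, rtol):
                return False
    for cx, cy in zip(a.constraints, b.constraints):
        if (cx.name, cx.body_1, cx.body_2, cx.kind) != (cy.name, cy.body_1, cy.body_2, cy.kind):
            return False
        for fx, fy in (
            (cx.location_body_1, cy.location_body_1),
            (cx.location_body_2, cy.location_body_2),
        ):
            if not _close(fx, fy, rtol):
                return False
    return True


@dataclass
class MotionTable:
    """A named time series of coordinate values or force components.

    Backed by the ``.mot``/``.sto`` storage dialect. ``values`` has one row
    per time step and one column per name in ``column_names`` (time excluded).
    """

    time: np.ndarray
    column_names: list[str]
    values: np.ndarray
    in_degrees: bool = False
    name: str = "motion"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float).reshape(-1)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.values.shape != (self.time.size, len(self.column_names)):
            raise ValueError(
                f"motion table shape {self.values.shape} does not match "
                f"{self.time.size} times x {len(self.column_names)} columns"
            )
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("motion table time must be strictly increasing")

    @property
    def n_rows(self) -> int:
        return int(self.time.size)

    def column(self, name: str) -> np.ndarray:
        try:
            i = self.column_names.index(name)
        except ValueError:
            raise KeyError(f"no column named {name!r}") from None
        return self.values[:, i]

    def rate(self) -> float:
        dt = np.diff(self.time)
        if dt.size == 0:
            raise ValueError("single-row table has no sampling rate")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("table is not uniformly sampled")
        return 1.0 / float(dt[0])

    def in_radians(self) -> "MotionTable":
        """Return a copy with angle values in radians (no-op if already)."""
        if not self.in_degrees:
            return MotionTable(self.time.copy(), list(self.column_names), self.values.copy(),
                               in_degrees=False, name=self.name)
        return MotionTable(self.time.copy(), list(self.column_names),
                           np.deg2rad(self.values), in_degrees=False, name=self.name)

    def copy(self) -> "MotionTable":
        return MotionTable(self.time.copy(), list(self.column_names), self.values.copy(),
                           in_degrees=self.in_degrees, name=self.name)


@dataclass
class Mesh:
    """A triangle surface mesh (bone display geometry)."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray     # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertices.shape[0] == 0:
            raise ValueError("mesh has no vertices")

    def signed_volume(self) -> float:
        """Signed volume via the divergence theorem; sign encodes winding."""
        v = self.vertices
        t = v[self.faces]
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)
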