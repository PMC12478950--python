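"""Forward kinematics over a :class:`~bimanum.model.ModelDef` joint tree.

The engine evaluates body poses from a coordinate vector, musculotendon path
lengths, body-COM positions, station (point) Jacobians and gravity demand
torques. Derivative quantities are computed by central finite differences of
the kinematics, which is the tendon-excursion definition of a moment arm
(r = -dL/dq) realized numerically.
"""
from __future__ import annotations

import numpy as np

from .model import GROUND, JointDef, ModelDef

FD_STEP = 1e-5  # rad (or m) — central-difference step for excursion derivatives


def euler_xyz_to_matrix(e) -> np.ndarray:
    """Rotation matrix of body-fixed (intrinsic) XYZ Euler angles."""
    a, b, c = np.asarray(e, float)
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rx @ ry @ rz


def matrix_to_euler_xyz(R: np.ndarray, gimbal_tol: float = 1e-9) -> np.ndarray:
    """Body-fixed XYZ Euler angles of a rotation matrix.

    At gimbal lock (|pitch| = pi/2) the decomposition is one-parameter
    degenerate; the branch taken here sets the third angle to 0 and folds the
    free parameter into the first angle, which makes the round trip
    deterministic.
    """
    R = np.asarray(R, float)
    sb = np.clip(R[0, 2], -1.0, 1.0)
    b = np.arcsin(sb)
    if abs(np.cos(b)) > gimbal_tol:
        a = np.arctan2(-R[1, 2], R[2, 2])
        c = np.arctan2(-R[0, 1], R[0, 0])
    else:
        c = 0.0
        a = np.arctan2(R[1, 0], R[1, 1]) if sb > 0 else np.arctan2(-R[1, 0], R[1, 1])
    return np.array([a, b, c])


def axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _homog(R: np.ndarray, p: np.ndarray) -> np.ndarray:
    X = np.eye(4)
    X[:3, :3] = R
    X[:3, 3] = p
    return X


def joint_transform(joint: JointDef, qmap: dict[str, float]) -> np.ndarray:
    """Parent-frame -> child-frame transform of one joint at coordinate values.

    Custom joints compose their rotation axes intrinsically in listed order;
    translations accumulate along their axes in the parent joint frame.
    """
    Xp = _homog(euler_xyz_to_matrix(joint.orientation_in_parent), joint.location_in_parent)
    Xc = _homog(euler_xyz_to_matrix(joint.orientation_in_child), joint.location_in_child)
    R = np.eye(3)
    p = np.zeros(3)
    for ax in joint.spatial_transform:
        q = qmap.get(ax.coordinate, 0.0) if ax.coordinate else 0.0
        if ax.kind == "rotation":
            R = R @ axis_angle_matrix(ax.axis, q)
        else:
            p = p + ax.axis * q
    return Xp @ _homog(R, p) @ np.linalg.inv(Xc)


class ModelKinematics:
    """Cached forward-kinematics evaluator for one model.

    Joints are sorted topologically from ground once; repeated evaluations
    reuse the ordering and the flattened muscle-path arrays.
    """

    def __init__(self, model: ModelDef, massless: set[str] | frozenset[str] = frozenset()):
        self.model = model
        self._massless = set(massless)
        self._order = self._topological_joints(model)
        self._body_index = {GROUND: 0}
        for j in self._order:
            self._body_index[j.child] = len(self._body_index)
        missing = model.body_names() - set(self._body_index)
        if missing:
            raise ValueError(f"bodies unreachable from ground: {sorted(missing)}")
        self.coord_names = [c.name for j in self._order for c in j.coordinates]
        self.free_coords = [
            c.name for j in self._order for c in j.coordinates if not c.locked
        ]
        self._defaults = {c.name: c.default for j in self._order for c in j.coordinates}
        # flattened muscle paths: per muscle, body indices + local homogeneous points
        self._paths = []
        for m in model.muscles:
            idx = np.array([self._body_index[p.body] for p in m.path])
            pts = np.hstack([[*p.location, 1.0] for p in m.path]).reshape(-1, 4)
            self._paths.append((idx, pts))
        self._masses = np.array(
            [0.0 if b.name in self._massless else b.mass for b in model.bodies]
        )
        self._coms = np.hstack([[*b.com, 1.0] for b in model.bodies]).reshape(-1, 4) \
            if model.bodies else np.empty((0, 4))
        self._body_rows = np.array([self._body_index[b.name] for b in model.bodies], dtype=int)

    @staticmethod
    def _topological_joints(model: ModelDef) -> list[JointDef]:
        pending = list(model.joints)
        placed = {GROUND}
        ordered: list[JointDef] = []
        while pending:
            progress = False
            for j in list(pending):
                if j.parent in placed:
                    ordered.append(j)
                    placed.add(j.child)
                    pending.remove(j)
                    progress = True
            if not progress:
                names = [j.name for j in pending]
                raise ValueError(f"joint tree has a cycle or floating subtree: {names}")
        return ordered

    # -- pose handling ------------------------------------------------------
    def full_pose(self, q: dict[str, float] | None) -> dict[str, float]:
        """Defaults (with locked values) overlaid with the provided values."""
        pose = dict(self._defaults)
        if q:
            for k, v in q.items():
                if k not in pose:
                    raise KeyError(f"unknown coordinate {k!r}")
                pose[k] = float(v)
        return pose

    def vector_to_pose(self, qv: np.ndarray) -> dict[str, float]:
        return dict(zip(self.free_coords, np.asarray(qv, float)))

    def pose_to_vector(self, q: dict[str, float] | None) -> np.ndarray:
        pose = self.full_pose(q)
        return np.array([pose[n] for n in self.free_coords])

    # -- core evaluation ----------------------------------------------------
    def body_transforms(self, q: dict[str, float] | None = None) -> np.ndarray:
        """(n_bodies+1, 4, 4) ground-frame poses; index 0 is ground."""
        pose = self.full_pose(q)
        X = np.empty((len(self._body_index), 4, 4))
        X[0] = np.eye(4)
        for j in self._order:
            X[self._body_index[j.child]] = (
                X[self._body_index[j.parent]] @ joint_transform(j, pose)
            )
        return X

    def station(self, transforms: np.ndarray, body: str, local: np.ndarray) -> np.ndarray:
        """Ground position of a point fixed in a body frame."""
        Xb = transforms[self._body_index[body]]
        return (Xb @ np.array([*local, 1.0]))[:3]

    def body_rotation(self, transforms: np.ndarray, body: str) -> np.ndarray:
        return transforms[self._body_index[body]][:3, :3]

    def muscle_lengths(self, transforms: np.ndarray) -> np.ndarray:
        out = np.empty(len(self._paths))
        for i, (idx, pts) in enumerate(self._paths):
            g = np.einsum("nij,nj->ni", transforms[idx], pts)[:, :3]
            out[i] = np.linalg.norm(np.diff(g, axis=0), axis=1).sum()
        return out

    def com_positions(self, transforms: np.ndarray) -> np.ndarray:
        if self._coms.shape[0] == 0:
            return np.empty((0, 3))
        return np.einsum("nij,nj->ni", transforms[self._body_rows], self._coms)[:, :3]

    def potential_energy(self, transforms: np.ndarray) -> float:
        """Gravitational potential of all bodies, V = -sum m_b g . p_b."""
        p = self.com_positions(transforms)
        return float(-(self._masses[:, None] * self.model.gravity).ravel()
                     @ p.ravel()) if p.size else 0.0

    # -- finite-difference sweep -------------------------------------------
    def sweep(self, q: dict[str, float] | None = None, h: float = FD_STEP) -> "FKSweep":
        """Evaluate the pose and all +/-h coordinate perturbations at once."""
        return FKSweep(self, self.pose_to_vector(q), h)


class FKSweep:
    """One central-difference sweep: nominal pose plus 2*n_dof perturbed poses.

    All excursion-based derivatives (moment arms, COM/station Jacobians,
    gravity demand) are read from the same sweep, so a solver step costs
    2*n_dof + 1 forward-kinematics evaluations.
    """

    def __init__(self, kin: ModelKinematics, qv: np.ndarray, h: float):
        self.kin = kin
        self.qv = np.asarray(qv, float)
        self.h = h
        n = len(kin.free_coords)
        self.X0 = kin.body_transforms(kin.vector_to_pose(qv))
        self.Xp = []
        self.Xm = []
        for j in range(n):
            qp = self.qv.copy()
            qp[j] += h
            qm = self.qv.copy()
            qm[j] -= h
            self.Xp.append(kin.body_transforms(kin.vector_to_pose(qp)))
            self.Xm.append(kin.body_transforms(kin.vector_to_pose(qm)))

    @property
    def n_dof(self) -> int:
        return len(self.kin.free_coords)

    def moment_arms(self) -> np.ndarray:
        """(n_muscles, n_dof) tendon-excursion moment arms, r = -dL/dq."""
        n = self.n_dof
        out = np.empty((len(self.kin._paths), n))
        for j in range(n):
            lp = self.kin.muscle_lengths(self.Xp[j])
            lm = self.kin.muscle_lengths(self.Xm[j])
            out[:, j] = -(lp - lm) / (2 * self.h)
        return out

    def gravity_demand(self) -> np.ndarray:
        """Generalized torque the actuators must produce to hold the pose,
        tau_j = dV/dq_j = -sum_b m_b g^T dcom_b/dq_j."""
        g = self.kin.model.gravity
        m = self.kin._masses
        out = np.empty(self.n_dof)
        for j in range(self.n_dof):
            dp = (self.kin.com_positions(self.Xp[j]) - self.kin.com_positions(self.Xm[j])) / (
                2 * self.h
            )
            out[j] = -float(m @ (dp @ g))
        return out

    def station_jacobian(self, body: str, local: np.ndarray) -> np.ndarray:
        """(3, n_dof) Jacobian of a body-fixed point's ground position."""
        out = np.empty((3, self.n_dof))
        for j in range(self.n_dof):
            out[:, j] = (
                self.kin.station(self.Xp[j], body, local)
                - self.kin.station(self.Xm[j], body, local)
            ) / (2 * self.h)
        return out

    def angular_jacobian(self, body: str) -> np.ndarray:
        """(3, n_dof) Jacobian of the body's angular velocity (ground frame)."""
        R0 = self.kin.body_rotation(self.X0, body)
        out = np.empty((3, self.n_dof))
        for j in range(self.n_dof):
            dR = (
                self.kin.body_rotation(self.Xp[j], body)
                - self.kin.body_rotation(self.Xm[j], body)
            ) / (2 * self.h)
            W = dR @ R0.T
            out[:, j] = [W[2, 1], W[0, 2], W[1, 0]]
        return out
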