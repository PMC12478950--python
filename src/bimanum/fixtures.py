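"""Self-contained synthetic inputs: a miniature unilateral shoulder model.

The canonical fixture is a right-side-only model — thorax (welded to
ground), humerus and a combined forearm+hand segment — with the four
shoulder/elbow degrees of freedom of interest (elevation plane, shoulder
elevation, axial shoulder rotation, elbow flexion; wrist coordinates present
but locked at 0) and the 14 shoulder-crossing muscle paths whose forces the
analysis reports: the three deltoid compartments, the four rotator-cuff
muscles, teres major, and three compartments each of pectoralis major and
latissimus dorsi.

Geometry, masses and peak isometric forces are order-of-magnitude upper-limb
values chosen so that every muscle has a usable moment arm about at least
one shoulder degree of freedom; they deliberately are NOT the values of any
published cadaver-derived model, so solver outputs on the fixture support
property-based checks only, never numeric comparison with published
simulations.

Frame conventions (ground): x anterior, y superior, z toward the model's
right. The mirror plane is the x-y plane (normal z). Shoulder rotations:
elevation_angle about +y (0 = coronal/abduction plane, ~80-90 = forward),
shoulder_elevation about -x after the plane rotation (positive elevates the
hanging arm), shoulder_rotation axially about +y of the humerus.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    BodyDef,
    CoordinateDef,
    JointDef,
    Mesh,
    MeshRef,
    ModelDef,
    MotionTable,
    MuscleDef,
    PathPoint,
    TransformAxis,
)
from .tasks import TaskDefinition

DEG = np.pi / 180.0

# peak isometric forces (N): plausible literature-class magnitudes
DEFAULT_FMAX = {
    "supraspinatus": 487.0,
    "infraspinatus": 1210.0,
    "subscapularis": 1378.0,
    "teres_minor": 354.0,
    "teres_major": 425.0,
    "deltoid_ant": 1100.0,
    "deltoid_mid": 1100.0,
    "deltoid_post": 950.0,
    "pec_major_clav": 444.0,
    "pec_major_stern": 658.0,
    "pec_major_ribs": 498.0,
    "lat_dorsi_thor": 433.0,
    "lat_dorsi_lumb": 433.0,
    "lat_dorsi_iliac": 433.0,
}

# muscle paths: (origin on thorax, insertion on humerus), thorax/humerus frames (m).
# The shoulder centre sits at (0, 0.45, 0.17) in the thorax frame.
_PATHS = {
    "supraspinatus":   ((0.00, 0.480, 0.100), (0.000, -0.010, 0.030)),
    "infraspinatus":   ((-0.060, 0.440, 0.100), (-0.020, -0.020, 0.020)),
    "subscapularis":   ((0.050, 0.430, 0.100), (0.020, -0.020, 0.015)),
    "teres_minor":     ((-0.050, 0.400, 0.110), (-0.015, -0.040, 0.015)),
    "teres_major":     ((-0.050, 0.360, 0.100), (0.010, -0.080, 0.005)),
    "deltoid_ant":     ((0.050, 0.460, 0.140), (0.005, -0.120, 0.012)),
    "deltoid_mid":     ((0.000, 0.460, 0.200), (0.000, -0.120, 0.015)),
    "deltoid_post":    ((-0.050, 0.460, 0.140), (-0.005, -0.120, 0.012)),
    "pec_major_clav":  ((0.060, 0.440, 0.020), (0.012, -0.050, 0.008)),
    "pec_major_stern": ((0.060, 0.380, 0.010), (0.012, -0.060, 0.008)),
    "pec_major_ribs":  ((0.050, 0.300, 0.020), (0.012, -0.070, 0.008)),
    "lat_dorsi_thor":  ((-0.060, 0.350, 0.020), (0.010, -0.045, 0.002)),
    "lat_dorsi_lumb":  ((-0.060, 0.280, 0.010), (0.010, -0.050, 0.002)),
    "lat_dorsi_iliac": ((-0.050, 0.200, 0.020), (0.010, -0.055, 0.002)),
}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic unilateral model."""

    seed: int = 0
    humerus_length: float = 0.30       # m
    humerus_mass: float = 2.0          # kg
    forearm_length: float = 0.30       # m (forearm + hand, one segment)
    forearm_mass: float = 1.5          # kg
    thorax_mass: float = 20.0          # kg
    shoulder_offset: tuple[float, float, float] = (0.0, 0.45, 0.17)
    fmax: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FMAX))


def _rod_inertia(mass: float, length: float) -> np.ndarray:
    i = mass * length**2 / 12.0
    return np.array([i, 0.1 * i + 1e-4, i, 0.0, 0.0, 0.0])


def _box_mesh(dx: float, dy: float, dz: float, center=(0.0, 0.0, 0.0)) -> Mesh:
    cx, cy, cz = center
    hx, hy, hz = dx / 2, dy / 2, dz / 2
    verts = np.array(
        [
            [cx + sx * hx, cy + sy * hy, cz + sz * hz]
            for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)
        ]
    )
    # 12 triangles, outward winding
    faces = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # -x
            [4, 6, 7], [4, 7, 5],  # +x
            [0, 4, 5], [0, 5, 1],  # -y
            [2, 3, 7], [2, 7, 6],  # +y
            [0, 2, 6], [0, 6, 4],  # -z
            [1, 5, 7], [1, 7, 3],  # +z
        ]
    )
    return Mesh(vertices=verts, faces=faces)


def make_unilateral_fixture(spec: FixtureSpec | None = None) -> tuple[ModelDef, dict[str, Mesh]]:
    """Build the canonical right-side-only model and its display meshes.

    Deterministic: the same spec (seed included) always yields an identical
    model and identical mesh files.
    """
    spec = spec or FixtureSpec()
    s = np.asarray(spec.shoulder_offset)

    thorax = BodyDef(
        name="thorax",
        mass=spec.thorax_mass,
        com=(0.0, 0.25, 0.0),
        inertia=(1.3, 0.6, 1.3, 0.0, 0.0, 0.0),
        mesh_refs=[MeshRef(file="thorax.vtp")],
    )
    humerus = BodyDef(
        name="humerus_r",
        mass=spec.humerus_mass,
        com=(0.0, -spec.humerus_length / 2, 0.0),
        inertia=_rod_inertia(spec.humerus_mass, spec.humerus_length),
        mesh_refs=[MeshRef(file="humerus.vtp")],
    )
    forearm = BodyDef(
        name="forearm_hand_r",
        mass=spec.forearm_mass,
        com=(0.0, -spec.forearm_length / 2, 0.0),
        inertia=_rod_inertia(spec.forearm_mass, spec.forearm_length),
        mesh_refs=[MeshRef(file="forearm_hand.vtp")],
    )

    ground_joint = JointDef(
        name="ground_thorax", joint_class="WeldJoint", parent="ground", child="thorax"
    )
    shoulder = JointDef(
        name="shoulder_r",
        joint_class="CustomJoint",
        parent="thorax",
        child="humerus_r",
        location_in_parent=s,
        coordinates=[
            CoordinateDef("elevation_angle_r", range=(-95 * DEG, 130 * DEG)),
            CoordinateDef("shoulder_elevation_r", range=(0.0, 180 * DEG)),
            CoordinateDef("shoulder_rotation_r", range=(-90 * DEG, 90 * DEG)),
        ],
        spatial_transform=[
            TransformAxis("rotation1", "rotation", (0.0, 1.0, 0.0), "elevation_angle_r"),
            TransformAxis("rotation2", "rotation", (-1.0, 0.0, 0.0), "shoulder_elevation_r"),
            TransformAxis("rotation3", "rotation", (0.0, 1.0, 0.0), "shoulder_rotation_r"),
        ],
    )
    elbow = JointDef(
        name="elbow_r",
        joint_class="CustomJoint",
        parent="humerus_r",
        child="forearm_hand_r",
        location_in_parent=(0.0, -spec.humerus_length, 0.0),
        coordinates=[
            CoordinateDef("elbow_flexion_r", range=(0.0, 150 * DEG)),
            CoordinateDef("pro_sup_r", range=(-90 * DEG, 90 * DEG), locked=True),
            CoordinateDef("wrist_flex_r", range=(-70 * DEG, 70 * DEG), locked=True),
        ],
        spatial_transform=[
            TransformAxis("rotation1", "rotation", (0.0, 0.0, 1.0), "elbow_flexion_r"),
            TransformAxis("rotation2", "rotation", (0.0, 1.0, 0.0), "pro_sup_r"),
            TransformAxis("rotation3", "rotation", (1.0, 0.0, 0.0), "wrist_flex_r"),
        ],
    )

    muscles = [
        MuscleDef(
            name=f"{name}_r",
            max_isometric_force=spec.fmax[name],
            path=[
                PathPoint(body="thorax", location=origin),
                PathPoint(body="humerus_r", location=insertion),
            ],
        )
        for name, (origin, insertion) in _PATHS.items()
    ]

    model = ModelDef(
        name="bimanum_fixture",
        bodies=[thorax, humerus, forearm],
        joints=[ground_joint, shoulder, elbow],
        muscles=muscles,
    )
    model.validate()

    meshes = {
        "thorax.vtp": _box_mesh(0.2, 0.5, 0.3, center=(0.0, 0.25, 0.0)),
        "humerus.vtp": _box_mesh(0.05, spec.humerus_length, 0.05,
                                 center=(0.0, -spec.humerus_length / 2, 0.01)),
        "forearm_hand.vtp": _box_mesh(0.04, spec.forearm_length, 0.04,
                                      center=(0.0, -spec.forearm_length / 2, 0.0)),
    }
    return model, meshes


def make_symmetric_kinematics(
    task: TaskDefinition,
    noise_sd_deg: float = 0.0,
    seed: int = 0,
) -> tuple[MotionTable, MotionTable]:
    """Left/right joint-angle tables for a bilateral task, exactly mirrored
    (identical coordinate values, per the coordinate-sign-preserving mirror
    policy), with optional additive Gaussian noise on the left side to probe
    RMSE sensitivity."""
    full = task.table(bilateral=True)
    r_cols = [i for i, n in enumerate(full.column_names) if n.endswith("_r")]
    l_cols = [i for i, n in enumerate(full.column_names) if n.endswith("_l")]
    right = MotionTable(
        time=full.time.copy(),
        column_names=[full.column_names[i] for i in r_cols],
        values=full.values[:, r_cols].copy(),
        in_degrees=True,
        name=f"{task.name}_right",
    )
    lvals = full.values[:, l_cols].copy()
    if noise_sd_deg > 0:
        rng = np.random.default_rng(seed)
        lvals = lvals + rng.normal(0.0, noise_sd_deg, size=lvals.shape)
    left = MotionTable(
        time=full.time.copy(),
        column_names=[full.column_names[i] for i in l_cols],
        values=lvals,
        in_degrees=True,
        name=f"{task.name}_left",
    )
    return left, right
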