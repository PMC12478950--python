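"""Graded unilateral rotator-cuff-tear severities and the bimanual shared load.

Tear severity is modelled by scaling the peak isometric force of the affected
side's cuff actuators, under the assumption that muscle force capacity is
linearly related to the fraction of intact tendon:

========  ============================================================
none      all cuff muscles at 100% of baseline
partial   supraspinatus at 50%
full      supraspinatus at 0%, infraspinatus at 75%
massive   supraspinatus at 0%, infraspinatus at 25%, subscapularis at 50%
========  ============================================================

Teres minor is never scaled. Severities always scale the pristine baseline
(snapshotted on first application), never the current value, so applying
severities in sequence does not compound.

The shared load is a rigid box body of mass W/g welded to the left hand with
a weld constraint closing the loop to the right hand; its COM sits at the
midpoint of the two hand COMs in the model's default (arms extended, thumbs
up) posture.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fk import ModelKinematics, matrix_to_euler_xyz
from .model import STANDARD_GRAVITY, BodyDef, ConstraintDef, JointDef, ModelDef

CUFF_ROLES = ("supraspinatus", "infraspinatus", "subscapularis")

SEVERITY_SCALES: dict[str, dict[str, float]] = {
    "none": {},
    "partial": {"supraspinatus": 0.5},
    "full": {"supraspinatus": 0.0, "infraspinatus": 0.75},
    "massive": {"supraspinatus": 0.0, "infraspinatus": 0.25, "subscapularis": 0.5},
}

SEVERITY_ORDER = ("none", "partial", "full", "massive")

# Shared-load presets: newtons of weight for the household / occupational objects.
LOAD_PRESETS_N = (13.3, 44.5)


@dataclass
class RCTSeverity:
    """One tear severity: per-muscle-role fractions of baseline peak force."""

    label: str
    scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role, frac in self.scale.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"severity {self.label!r}: fraction for {role} not in [0,1]")

    def fraction(self, role: str) -> float:
        return self.scale.get(role, 1.0)

    @classmethod
    def from_label(cls, label: str) -> "RCTSeverity":
        try:
            return cls(label=label, scale=dict(SEVERITY_SCALES[label]))
        except KeyError:
            raise ValueError(
                f"unknown severity {label!r}; expected one of {SEVERITY_ORDER}"
            ) from None


def _side_suffix(side: str) -> str:
    if side in ("right", "r", "_r"):
        return "_r"
    if side in ("left", "l", "_l"):
        return "_l"
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def find_cuff_muscle(model: ModelDef, role: str, side: str) -> str:
    """Name of the actuator implementing a cuff role on one side."""
    suffix = _side_suffix(side)
    matches = [
        m.name
        for m in model.muscles
        if role.lower() in m.name.lower() and m.name.endswith(suffix)
    ]
    if not matches:
        raise KeyError(f"no {role} actuator with suffix {suffix!r} in model {model.name!r}")
    if len(matches) > 1:
        raise KeyError(f"ambiguous {role} actuators on side {side}: {matches}")
    return matches[0]


def apply_rct(
    model: ModelDef,
    severity: RCTSeverity | str,
    side: str = "right",
) -> ModelDef:
    """Return a copy of the model with the severity's force scaling applied
    to the affected side's cuff actuators.

    Only the muscles named in the severity's scale map are touched; the
    contralateral side and every other muscle keep their baseline values
    bit-for-bit. Scaling is absolute against the pristine baseline, so the
    operation is idempotent and severities never compound.
    """
    if isinstance(severity, str):
        severity = RCTSeverity.from_label(severity)
    out = model.copy()
    if out.fmax_baseline is None:
        out.fmax_baseline = {m.name: m.max_isometric_force for m in out.muscles}
    # restore every muscle to baseline, then scale the named ones
    for m in out.muscles:
        m.max_isometric_force = out.fmax_baseline.get(m.name, m.max_isometric_force)
    for role, frac in severity.scale.items():
        name = find_cuff_muscle(out, role, side)
        out.muscle(name).max_isometric_force = out.fmax_baseline[name] * frac
    return out


@dataclass
class SharedLoad:
    """A bimanual shared load: a weight held between the hands."""

    weight_n: float
    g: float = STANDARD_GRAVITY
    # box dimensions (m) used for the load body's inertia; x (anteroposterior)
    # by y (vertical) by z (mediolateral, the hand-spacing direction)
    box_dims: tuple[float, float, float] = (0.2, 0.2, 0.4)

    def __post_init__(self) -> None:
        if self.weight_n < 0:
            raise ValueError(f"load weight must be >= 0, got {self.weight_n}")

    @property
    def mass_kg(self) -> float:
        return self.weight_n / self.g

    def box_inertia(self) -> np.ndarray:
        """Uniform-box inertia 6-vector about the COM."""
        m = self.mass_kg
        dx, dy, dz = self.box_dims
        return np.array(
            [m / 12 * (dy**2 + dz**2), m / 12 * (dx**2 + dz**2), m / 12 * (dx**2 + dy**2),
             0.0, 0.0, 0.0]
        )


LOAD_BODY_NAME = "shared_load"


def find_hand_bodies(model: ModelDef) -> tuple[str, str]:
    """(left, right) hand body names, located by the 'hand' token + side suffix."""
    left = [b.name for b in model.bodies if "hand" in b.name.lower() and b.name.endswith("_l")]
    right = [b.name for b in model.bodies if "hand" in b.name.lower() and b.name.endswith("_r")]
    if len(left) != 1 or len(right) != 1:
        raise KeyError(
            f"could not identify one hand body per side (left={left}, right={right})"
        )
    return left[0], right[0]


def make_shared_load(
    model: ModelDef,
    weight_n: float | SharedLoad,
    hand_bodies: tuple[str, str] | None = None,
    hand_stations: tuple[np.ndarray, np.ndarray] | None = None,
) -> ModelDef:
    """Return a copy of the bilateral model with the shared load attached.

    The load body (mass W/g, uniform-box inertia) is added with its COM at the
    midpoint of the two hand COMs in the default posture, joined to the left
    hand by a weld joint and to the right hand by a weld constraint. The load
    body frame is aligned with ground at the default posture.
    """
    load = weight_n if isinstance(weight_n, SharedLoad) else SharedLoad(weight_n=float(weight_n))
    out = model.copy()
    if any(b.name == LOAD_BODY_NAME for b in out.bodies):
        raise ValueError(f"model already contains a body named {LOAD_BODY_NAME!r}")
    left, right = hand_bodies or find_hand_bodies(out)
    st_l = np.asarray(hand_stations[0], float) if hand_stations else out.body(left).com
    st_r = np.asarray(hand_stations[1], float) if hand_stations else out.body(right).com

    kin = ModelKinematics(out)
    X = kin.body_transforms()  # default posture
    p_l = kin.station(X, left, st_l)
    p_r = kin.station(X, right, st_r)
    midpoint = 0.5 * (p_l + p_r)
    R_l = kin.body_rotation(X, left)
    R_r = kin.body_rotation(X, right)

    body = BodyDef(
        name=LOAD_BODY_NAME,
        mass=load.mass_kg,
        com=midpoint - p_l,  # load frame = ground axes anchored at the left-hand station
        inertia=load.box_inertia(),
    )
    joint = JointDef(
        name="load_weld",
        joint_class="WeldJoint",
        parent=left,
        child=LOAD_BODY_NAME,
        location_in_parent=st_l,
        orientation_in_parent=matrix_to_euler_xyz(R_l.T),
    )
    constraint = ConstraintDef(
        name="load_weld_constraint",
        body_1=LOAD_BODY_NAME,
        body_2=right,
        location_body_1=p_r - p_l,
        location_body_2=st_r,
        orientation_body_2=matrix_to_euler_xyz(R_r.T),
    )
    out.bodies.append(body)
    out.joints.append(joint)
    out.constraints.append(constraint)
    out.validate()
    return out
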