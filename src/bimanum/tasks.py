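"""The simulated task battery as coordinate-space motion tables.

Three loaded bimanual tasks: a low static hold (shoulder elevation 80 deg,
elevation-plane angle 80 deg — a box held with extended arms at waist
height), a high static hold (elevation 130 deg, plane 80 deg — a box held
above eye height), and a dynamic forward reach (arms start at the side with
the elbows flexed 90 deg, the humerus elevates to ~75 deg in the sagittal
plane and returns). Plus the two unloaded verification tasks used to check
bilateral kinematic symmetry.

All tables are generated bilaterally with identical left/right coordinate
values, which produces mirror-symmetric postures on a model built with the
coordinate-sign-preserving mirroring policy. Wrist degrees of freedom are
locked at 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import ModelDef, MotionTable

Profile = Callable[[np.ndarray], np.ndarray]

# Default elevation-plane value (deg) placing the elevation in a forward,
# near-sagittal plane, consistent with the static box-holding tasks.
SAGITTAL_PLANE_DEG = 80.0

LOW_STATIC_ELEVATION_DEG = 80.0
HIGH_STATIC_ELEVATION_DEG = 130.0
STATIC_PLANE_DEG = 80.0


def constant(value: float) -> Profile:
    return lambda t: np.full_like(np.asarray(t, float), float(value))


def min_jerk_out_and_back(peak: float, duration: float, start: float = 0.0) -> Profile:
    """Smooth out-and-back profile: minimum-jerk rise from ``start`` to
    ``peak`` at duration/2, then the time-reversed return. Start equals end,
    and the maximum over time is exactly ``peak``."""

    def sigma(u: np.ndarray) -> np.ndarray:
        u = np.clip(u, 0.0, 1.0)
        return 10 * u**3 - 15 * u**4 + 6 * u**5

    half = duration / 2.0

    def profile(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        u = np.where(t <= half, t / half, (duration - t) / half)
        return start + (peak - start) * sigma(u)

    return profile


@dataclass
class TaskDefinition:
    """A named task: per-coordinate time profiles over [0, duration]."""

    name: str
    duration: float = 7.0
    rate: float = 100.0
    profiles: dict[str, Profile] = field(default_factory=dict)
    locked: dict[str, float] = field(default_factory=dict)

    def times(self) -> np.ndarray:
        n = int(round(self.duration * self.rate)) + 1
        return np.linspace(0.0, self.duration, n)

    def table(
        self,
        bilateral: bool = True,
        suffixes: tuple[str, ...] = ("_r", "_l"),
        model: ModelDef | None = None,
    ) -> MotionTable:
        """Sample the profiles into a degree-valued motion table.

        With ``bilateral=True`` each coordinate appears once per side suffix
        with identical values. If a model is given, targets are checked
        against its coordinate ranges.
        """
        t = self.times()
        cols: list[str] = []
        vals: list[np.ndarray] = []
        sides = suffixes if bilateral else (suffixes[0],)
        for base, prof in {**self.profiles, **{k: constant(v) for k, v in self.locked.items()}}.items():
            series = np.asarray(prof(t), float)
            for suf in sides:
                cols.append(base + suf)
                vals.append(series)
        table = MotionTable(
            time=t, column_names=cols, values=np.column_stack(vals),
            in_degrees=True, name=self.name,
        )
        if model is not None:
            check_against_ranges(table, model)
        return table


def check_against_ranges(table: MotionTable, model: ModelDef) -> None:
    """Raise if any column exceeds its model coordinate's range."""
    coords = {c.name: c for c in model.coordinates()}
    vals = np.deg2rad(table.values) if table.in_degrees else table.values
    for i, name in enumerate(table.column_names):
        c = coords.get(name)
        if c is None or c.kind != "rotational":
            continue
        lo, hi = c.range
        v = vals[:, i]
        if v.min() < lo - 1e-9 or v.max() > hi + 1e-9:
            raise ValueError(
                f"task {table.name!r}: column {name} range [{v.min():.3f}, {v.max():.3f}] rad "
                f"exceeds coordinate range [{lo:.3f}, {hi:.3f}]"
            )


_WRIST_LOCKED = {"pro_sup": 0.0, "wrist_flex": 0.0}


def make_static_task(kind: str, duration: float = 7.0, rate: float = 100.0) -> TaskDefinition:
    """The low (elevation 80/plane 80) or high (elevation 130/plane 80)
    static box-holding posture, arms extended (elbow 0), wrist locked."""
    if kind == "low":
        elevation = LOW_STATIC_ELEVATION_DEG
    elif kind == "high":
        elevation = HIGH_STATIC_ELEVATION_DEG
    else:
        raise ValueError(f"static task kind must be 'low' or 'high', got {kind!r}")
    return TaskDefinition(
        name=f"{kind}_static",
        duration=duration,
        rate=rate,
        profiles={
            "elevation_angle": constant(STATIC_PLANE_DEG),
            "shoulder_elevation": constant(elevation),
            "shoulder_rotation": constant(0.0),
            "elbow_flexion": constant(0.0),
        },
        locked=dict(_WRIST_LOCKED),
    )


def make_dynamic_reach(
    peak_elevation_deg: float = 75.0,
    start_elbow_flexion_deg: float = 90.0,
    end_elbow_flexion_deg: float = 20.0,
    duration: float = 7.0,
    rate: float = 100.0,
    model: ModelDef | None = None,
) -> TaskDefinition:
    """The dynamic forward reach: from arms-by-the-side with 90 deg elbow
    flexion, the humerus elevates along a minimum-jerk profile to the peak
    elevation at mid-task and returns; the elbow extends in proportion.
    """
    if model is not None:
        for side in ("_r", "_l"):
            c = model.coordinate("shoulder_elevation" + side)
            if not (c.range[0] <= np.deg2rad(peak_elevation_deg) <= c.range[1]):
                raise ValueError(
                    f"peak elevation {peak_elevation_deg} deg outside range of {c.name}"
                )
    elev = min_jerk_out_and_back(peak_elevation_deg, duration)

    def elbow(t: np.ndarray) -> np.ndarray:
        frac = elev(t) / peak_elevation_deg if peak_elevation_deg else np.zeros_like(t)
        return start_elbow_flexion_deg + (end_elbow_flexion_deg - start_elbow_flexion_deg) * frac

    return TaskDefinition(
        name="dynamic_reach",
        duration=duration,
        rate=rate,
        profiles={
            "elevation_angle": constant(SAGITTAL_PLANE_DEG),
            "shoulder_elevation": elev,
            "shoulder_rotation": constant(0.0),
            "elbow_flexion": elbow,
        },
        locked=dict(_WRIST_LOCKED),
    )


def make_verification_tasks(
    duration: float = 7.0, rate: float = 100.0
) -> tuple[TaskDefinition, TaskDefinition]:
    """The two unloaded symmetry-verification tasks.

    Static: arm at the side (0 deg elevation, 0 deg elbow), palm toward the
    midline at -25 deg shoulder rotation, held for the full duration.
    Dynamic: palm away from the midline at -45 deg rotation; shoulder
    elevation rises 0 -> 90 -> 0 deg over the task.
    """
    static = TaskDefinition(
        name="verification_static",
        duration=duration,
        rate=rate,
        profiles={
            "elevation_angle": constant(0.0),
            "shoulder_elevation": constant(0.0),
            "shoulder_rotation": constant(-25.0),
            "elbow_flexion": constant(0.0),
        },
        locked=dict(_WRIST_LOCKED),
    )
    dynamic = TaskDefinition(
        name="verification_dynamic",
        duration=duration,
        rate=rate,
        profiles={
            "elevation_angle": constant(0.0),
            "shoulder_elevation": min_jerk_out_and_back(90.0, duration),
            "shoulder_rotation": constant(-45.0),
            "elbow_flexion": constant(0.0),
        },
        locked=dict(_WRIST_LOCKED),
    )
    return static, dynamic
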