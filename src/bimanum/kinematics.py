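"""Joint-angle and marker time-series processing: low-pass filtering,
mirroring, and bilateral symmetry verification by per-DOF RMSE.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .mirroring import MirrorConvention
from .model import MotionTable

# The RMSE envelope (degrees) below which a bilateral model's left/right
# kinematics are considered symmetric for verification purposes.
SYMMETRY_RMSE_THRESHOLD_DEG = 1.5


@dataclass
class FilterSpec:
    """Zero-phase low-pass Butterworth.

    ``order`` is the effective order after the forward-backward (dual) pass;
    the underlying design uses order/2, the biomechanics convention for an
    'Nth-order zero-lag' filter. The cutoff is passed raw to the design, so
    the dual-pass amplitude response at the cutoff frequency is exactly 0.5.
    """

    cutoff_hz: float = 6.0
    order: int = 4

    def __post_init__(self) -> None:
        if self.order < 2 or self.order % 2:
            raise ValueError("filter order must be an even integer >= 2")


def butterworth_lowpass(table: MotionTable, spec: FilterSpec = FilterSpec()) -> MotionTable:
    """Column-wise zero-phase low-pass filter; the time column is untouched.

    Requires uniform sampling and a cutoff below the Nyquist frequency.
    """
    fs = table.rate()
    nyq = fs / 2.0
    if spec.cutoff_hz >= nyq:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyq} Hz")
    if table.n_rows < 3 * spec.order:
        raise ValueError(f"need >= {3 * spec.order} samples to filter, got {table.n_rows}")
    sos = signal.butter(spec.order // 2, spec.cutoff_hz, btype="low", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, table.values, axis=0)
    return MotionTable(
        time=table.time.copy(),
        column_names=list(table.column_names),
        values=filtered,
        in_degrees=table.in_degrees,
        name=table.name,
    )


def filter_gain_at(spec: FilterSpec, freq_hz: float, fs: float) -> float:
    """Amplitude gain of the dual-pass filter at one frequency (|H|^2)."""
    sos = signal.butter(spec.order // 2, spec.cutoff_hz, btype="low", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


def mirror_markers(markers: MotionTable, lab_axis: str = "x") -> MotionTable:
    """Mirror marker trajectories across the lab plane normal to ``lab_axis``
    by negating that coordinate of every marker (columns ``<marker>_<axis>``)."""
    lab_axis = lab_axis.lower()
    if lab_axis not in ("x", "y", "z"):
        raise ValueError(f"lab_axis must be x, y or z; got {lab_axis!r}")
    values = markers.values.copy()
    for i, name in enumerate(markers.column_names):
        if name.lower().endswith(f"_{lab_axis}"):
            values[:, i] = -values[:, i]
    return MotionTable(
        time=markers.time.copy(), column_names=list(markers.column_names),
        values=values, in_degrees=markers.in_degrees, name=markers.name,
    )


def mirror_joint_angles(
    table: MotionTable,
    sign_map: dict[str, float] | None = None,
    convention: MirrorConvention | None = None,
) -> MotionTable:
    """Map one side's joint-angle columns to the contralateral side.

    Columns are renamed via the side-suffix map and scaled by ``sign_map``
    (keyed by the original column name; default +1 for every coordinate,
    matching a model mirrored with the coordinate-sign-preserving axis-flip
    policy). Supply -1 entries for coordinates whose model does not follow
    that convention.
    """
    convention = convention or MirrorConvention()
    sign_map = sign_map or {}
    names = [convention.map_name(n) for n in table.column_names]
    values = table.values.copy()
    for i, original in enumerate(table.column_names):
        values[:, i] *= sign_map.get(original, 1.0)
    return MotionTable(
        time=table.time.copy(), column_names=names, values=values,
        in_degrees=table.in_degrees, name=table.name,
    )


def rmse(a, b) -> float:
    """Root-mean-squared error between two equal-length series."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"series lengths differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def verify_bilateral_symmetry(
    left: MotionTable,
    right: MotionTable,
    convention: MirrorConvention | None = None,
    threshold_deg: float = SYMMETRY_RMSE_THRESHOLD_DEG,
) -> pd.DataFrame:
    """Per-DOF RMSE between left- and right-side joint-angle series.

    Columns are paired by stripping the side suffix. Returns a DataFrame with
    one row per DOF (``coordinate``, ``rmse``, ``pass``); the report passes
    when every RMSE is below the threshold (degrees by convention).
    """
    convention = convention or MirrorConvention()

    def base(name: str) -> str:
        for a, b in convention.suffix_pairs:
            for suf in (a, b):
                if name.endswith(suf):
                    return name[: -len(suf)]
        return name

    lmap = {base(n): n for n in left.column_names}
    rmap = {base(n): n for n in right.column_names}
    if set(lmap) != set(rmap):
        only_l = sorted(set(lmap) - set(rmap))
        only_r = sorted(set(rmap) - set(lmap))
        raise ValueError(f"mismatched column sets: left-only {only_l}, right-only {only_r}")
    if left.n_rows != right.n_rows:
        raise ValueError(f"row counts differ: {left.n_rows} vs {right.n_rows}")

    rows = []
    for b in sorted(lmap):
        e = rmse(left.column(lmap[b]), right.column(rmap[b]))
        rows.append({"coordinate": b, "rmse": e, "pass": bool(e < threshold_deg)})
    return pd.DataFrame(rows)
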