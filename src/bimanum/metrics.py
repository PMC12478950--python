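"""Outcome measures computed from solver results.

* normalized muscle force (% of model-specific peak isometric force) and its
  time average over a task;
* percentage-point contrasts of the averages between model permutations
  (reference = no tear);
* shared-load deviation summaries: per-direction maximum deviation from the
  start position (static tasks) and per-direction RMSE against the
  input-kinematics trajectory (dynamic task).

Direction conventions (ground frame): y vertical, superior positive;
z mediolateral, affected/right side positive — "toward the unaffected side"
is a negative-z displacement reported as a positive magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinematics import rmse
from .solver import SolverResult


def normalized_force(
    result: SolverResult,
    pre_injury_fmax: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-muscle normalized force series, 100 * F(t) / Fmax.

    The denominator is the post-injury (model-specific) peak isometric force;
    pass ``pre_injury_fmax`` to normalize by pristine baselines instead.
    Muscles torn to zero capacity have identically zero force and are
    reported as 0% (flagged in ``df.attrs['zero_capacity']``).
    """
    forces = result.forces
    if pre_injury_fmax is not None:
        denom = np.array([pre_injury_fmax[n] for n in result.muscle_names])
    else:
        denom = result.fmax
    zero = denom <= 0.0
    pct = np.zeros_like(forces)
    pct[:, ~zero] = 100.0 * forces[:, ~zero] / denom[~zero]
    df = pd.DataFrame(pct, index=result.time, columns=result.muscle_names)
    df.attrs["zero_capacity"] = [n for n, z in zip(result.muscle_names, zero) if z]
    return df


def average_contribution(series) -> float | pd.Series:
    """Time-mean of a normalized-force series (scalar for one muscle,
    per-muscle Series for a whole table)."""
    if isinstance(series, pd.DataFrame):
        return series.mean(axis=0)
    return float(np.mean(np.asarray(series, float)))


def contrast(reference, comparison) -> pd.Series | float:
    """Percentage-point change in average contribution between two model
    permutations: comparison minus reference (reference = no tear).

    Antisymmetric: contrast(a, b) == -contrast(b, a).
    """
    if isinstance(reference, pd.DataFrame):
        reference = average_contribution(reference)
    if isinstance(comparison, pd.DataFrame):
        comparison = average_contribution(comparison)
    return comparison - reference


def compensation_table(
    results: dict[str, SolverResult],
    reference: str = "none",
) -> pd.DataFrame:
    """Average contribution (% maximum) per severity, with percentage-point
    contrasts against the reference severity, one row per muscle."""
    means = {label: average_contribution(normalized_force(r)) for label, r in results.items()}
    df = pd.DataFrame(means)
    for label in df.columns:
        if label != reference:
            df[f"{label}_vs_{reference}_pp"] = df[label] - df[reference]
    return df


@dataclass
class DeviationSummary:
    """Shared-load deviation outcome for one task permutation (mm)."""

    task_kind: str                       # "static" | "dynamic"
    inferior_mm: float = 0.0
    superior_mm: float = 0.0
    toward_unaffected_mm: float = 0.0
    toward_affected_mm: float = 0.0
    rmse_vertical_mm: float | None = None       # dynamic only
    rmse_mediolateral_mm: float | None = None   # dynamic only


def deviation_summary(
    load_com: np.ndarray,
    reference: np.ndarray | None = None,
    task_kind: str = "static",
    affected_axis_sign: float = 1.0,
) -> DeviationSummary:
    """Summarize a load-COM trajectory.

    Static: maximum deviation from the start position (or a given reference
    point), decomposed into inferior/superior and toward-affected/unaffected
    components. Dynamic: per-direction RMSE against the reference trajectory
    from the input kinematics.

    ``affected_axis_sign`` is +1 when the affected side lies on +z.
    """
    traj = np.atleast_2d(np.asarray(load_com, float))
    if task_kind == "static":
        # the reference is the starting position (first row if a trajectory)
        ref = traj[0] if reference is None else np.atleast_2d(np.asarray(reference, float))[0]
        d = traj - ref[None, :]
        dy = d[:, 1]
        dz = d[:, 2] * affected_axis_sign
        return DeviationSummary(
            task_kind="static",
            inferior_mm=1000.0 * max(0.0, float(-dy.min(initial=0.0))),
            superior_mm=1000.0 * max(0.0, float(dy.max(initial=0.0))),
            toward_unaffected_mm=1000.0 * max(0.0, float(-dz.min(initial=0.0))),
            toward_affected_mm=1000.0 * max(0.0, float(dz.max(initial=0.0))),
        )
    if task_kind == "dynamic":
        if reference is None:
            raise ValueError("dynamic summary needs the input-kinematics reference trajectory")
        ref = np.atleast_2d(np.asarray(reference, float))
        if ref.shape != traj.shape:
            raise ValueError(f"trajectory shapes differ: {traj.shape} vs {ref.shape}")
        d = traj - ref
        dy = d[:, 1]
        dz = d[:, 2] * affected_axis_sign
        return DeviationSummary(
            task_kind="dynamic",
            inferior_mm=1000.0 * max(0.0, float(-dy.min(initial=0.0))),
            superior_mm=1000.0 * max(0.0, float(dy.max(initial=0.0))),
            toward_unaffected_mm=1000.0 * max(0.0, float(-dz.min(initial=0.0))),
            toward_affected_mm=1000.0 * max(0.0, float(dz.max(initial=0.0))),
            rmse_vertical_mm=1000.0 * rmse(traj[:, 1], ref[:, 1]),
            rmse_mediolateral_mm=1000.0 * rmse(traj[:, 2], ref[:, 2]),
        )
    raise ValueError(f"task_kind must be 'static' or 'dynamic', got {task_kind!r}")
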