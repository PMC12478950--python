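"""Reduced-order muscle-redundancy resolution by bounded static optimization.

The tracking controller used for the original simulations (a closed-loop
algorithm with activation and contraction dynamics) is replaced here by a
per-time-step static optimization: at each prescribed posture the gravity
demand of all segments plus the shared load must be balanced by muscle
torques (moment arm x peak force x activation), a bounded torque slack, and
the interaction forces the two hands exert on the load. The program

    minimize  sum_i a_i^2  +  w * ||tau_s||^2  +  lambda * ||omega||^2
    s.t.      A a + tau_s + B^T omega = tau_demand,   0 <= a_i <= 1

is strictly convex (the tiny regularization lambda makes the load-sharing
variable unique) and is solved exactly as a bounded least-squares problem
after eliminating the slack. Muscles are rigid-tendon and activation-linear
(F = a * Fmax); force-length/velocity scaling is omitted.

Load sharing. Because the solver prescribes the joint kinematics instead of
enforcing the weld loop closure dynamically, the shared load is reduced to a
rigid massless connector carrying the load mass at the midpoint of the two
hand attachment stations. Each hand applies a force and a grip moment
through its weld; the load's full static equilibrium (force and moment) is
enforced exactly, with the residual freedom parameterized symmetrically as
the deviation phi of the right-hand force from the equal half-share and the
antisymmetric grip-moment component mu. Shifting vertical share to one hand
therefore requires real stabilizing wrist moments on both sides — the
mechanical pathway for bilateral compensation — and a mirror-symmetric task
produces exactly mirror-symmetric recruitment.

The dynamic reach is treated quasi-statically (inertial torques neglected),
the main declared fidelity gap versus a full tracking simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .fk import ModelKinematics
from .kinematics import FilterSpec, butterworth_lowpass
from .model import ModelDef, MotionTable
from .pathology_load import LOAD_BODY_NAME, RCTSeverity, SharedLoad, apply_rct, make_shared_load
from .tasks import TaskDefinition

SLACK_WEIGHT = 1e6     # (N m)^-2 — penalty enforcing torque balance when feasible
WRENCH_REG = 1e-8      # regularization on the load-sharing variable (uniqueness)
SLACK_TOL = 1e-4       # N m — residual below which a step counts as feasible
COMPLIANCE = 0.01      # rad/(N m) — joint compliance of the deviation surrogate


@dataclass
class StepSolution:
    activations: np.ndarray          # (n_muscles,) in [0, 1]
    slack: np.ndarray                # (n_dof,) N m
    wrench: np.ndarray | None        # sharing variable omega (load steps only)
    feasible: bool


def resolve_redundancy(
    A: np.ndarray,
    tau: np.ndarray,
    B: np.ndarray | None = None,
    slack_weight: float = SLACK_WEIGHT,
    wrench_reg: float = WRENCH_REG,
    slack_tol: float = SLACK_TOL,
) -> StepSolution:
    """Solve one static-optimization step.

    A is the (n_dof, n_muscles) torque-generation matrix r_ij * Fmax_i; tau
    the (n_dof,) demand; B, if given, a (k, n_dof) matrix whose transpose
    maps k free interaction variables to generalized torques. The slack is
    defined as the balance residual, so ``A a + slack + B.T w - tau = 0``
    holds to machine precision.
    """
    A = np.atleast_2d(np.asarray(A, float))
    tau = np.asarray(tau, float).ravel()
    n_dof, n_m = A.shape
    n_w = 0 if B is None else B.shape[0]
    sw = np.sqrt(slack_weight)

    design = np.zeros((n_dof + n_m + n_w, n_m + n_w))
    target = np.zeros(n_dof + n_m + n_w)
    design[:n_dof, :n_m] = sw * A
    target[:n_dof] = sw * tau
    design[n_dof:n_dof + n_m, :n_m] = np.eye(n_m)
    if n_w:
        design[:n_dof, n_m:] = sw * B.T
        design[n_dof + n_m:, n_m:] = np.sqrt(wrench_reg) * np.eye(n_w)

    lb = np.concatenate([np.zeros(n_m), np.full(n_w, -np.inf)])
    ub = np.concatenate([np.ones(n_m), np.full(n_w, np.inf)])
    try:
        res = lsq_linear(design, target, bounds=(lb, ub), method="bvls", tol=1e-14)
    except ValueError:
        res = lsq_linear(design, target, bounds=(lb, ub), method="trf", tol=1e-14)
    x = res.x
    a = np.clip(x[:n_m], 0.0, 1.0)
    w = x[n_m:] if n_w else None
    slack = tau - A @ a - (B.T @ w if n_w else 0.0)
    return StepSolution(
        activations=a,
        slack=slack,
        wrench=w,
        feasible=bool(np.max(np.abs(slack), initial=0.0) < slack_tol),
    )


@dataclass
class SolverResult:
    """Per-time-step solver output for one task simulation."""

    time: np.ndarray                     # (n_t,)
    muscle_names: list[str]
    dof_names: list[str]
    fmax: np.ndarray                     # (n_muscles,)
    activations: np.ndarray              # (n_t, n_muscles)
    slack: np.ndarray                    # (n_t, n_dof)
    feasible: np.ndarray                 # (n_t,) bool
    load_com: np.ndarray | None = None   # (n_t, 3) midpoint of the hand stations
    load_jac: np.ndarray | None = None   # (n_t, 3, n_dof) load-COM point Jacobian
    hand_force_left: np.ndarray | None = None   # (n_t, 3) force by left hand on load
    hand_force_right: np.ndarray | None = None  # (n_t, 3)
    load_mass: float = 0.0
    gravity: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def forces(self) -> np.ndarray:
        """Muscle forces F = a * Fmax (rigid tendon, activation-linear)."""
        return self.activations * self.fmax[None, :]


def moment_arms(
    model: ModelDef, q: dict[str, float] | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """(n_muscles, n_dof) tendon-excursion moment arms at a pose, with the
    muscle and free-coordinate name orderings."""
    kin = ModelKinematics(model)
    r = kin.sweep(q).moment_arms()
    return r, [m.name for m in model.muscles], list(kin.free_coords)


def static_torques(model: ModelDef, q: dict[str, float] | None = None) -> np.ndarray:
    """Gravity demand per free DOF: the generalized torque actuators must
    produce to hold the pose, tau_j = dV/dq_j (virtual work of all bodies,
    including any load body present in the model)."""
    kin = ModelKinematics(model)
    return kin.sweep(q).gravity_demand()


class _LoadHookup:
    """Resolved attachment data for the shared load, if present: the left
    hand carries the weld joint, the right hand the weld constraint."""

    def __init__(self, model: ModelDef):
        self.present = any(b.name == LOAD_BODY_NAME for b in model.bodies)
        if not self.present:
            return
        self.mass = model.body(LOAD_BODY_NAME).mass
        if self.mass <= 0.0:
            # a zero-weight load is inert: no interaction forces, so the
            # statics reduce exactly to the unloaded model
            self.present = False
            return
        joint = next(j for j in model.joints if j.child == LOAD_BODY_NAME)
        self.left_hand = joint.parent
        self.left_station = joint.location_in_parent
        con = next(c for c in model.constraints if LOAD_BODY_NAME in (c.body_1, c.body_2))
        if con.body_1 == LOAD_BODY_NAME:
            self.right_hand, self.right_station = con.body_2, con.location_body_2
        else:
            self.right_hand, self.right_station = con.body_1, con.location_body_1


class _StepEngine:
    """Shared per-pose assembly used by ``solve_step`` and ``simulate_task``."""

    def __init__(self, model: ModelDef):
        self.model = model
        self.hookup = _LoadHookup(model)
        massless = {LOAD_BODY_NAME} if self.hookup.present else set()
        # the load's gravity enters through the hand interaction forces, so
        # its body mass is excluded from the tree's gravity demand
        self.kin = ModelKinematics(model, massless=massless)
        self.fmax = np.array([m.max_isometric_force for m in model.muscles])

    def assemble(self, q: dict[str, float] | None):
        sweep = self.kin.sweep(q)
        A = (sweep.moment_arms() * self.fmax[:, None]).T
        tau = sweep.gravity_demand()
        if not self.hookup.present:
            return sweep, A, tau, None, None
        h = self.hookup
        J_l = sweep.station_jacobian(h.left_hand, h.left_station)
        J_r = sweep.station_jacobian(h.right_hand, h.right_station)
        Jw_l = sweep.angular_jacobian(h.left_hand)
        Jw_r = sweep.angular_jacobian(h.right_hand)
        p_l = self.kin.station(sweep.X0, h.left_hand, h.left_station)
        p_r = self.kin.station(sweep.X0, h.right_hand, h.right_station)
        f_half = -0.5 * h.mass * self.model.gravity  # upward equal half-share
        # demand with the symmetric reference interaction (equal forces, no
        # grip moments — the load COM is the station midpoint, so the
        # reference moment balance is exact)
        tau = tau + (J_l + J_r).T @ f_half
        # variable part: force-share deviation phi couples into the required
        # grip moments via the load's moment equilibrium about its COM
        d = p_r - p_l
        Dx = np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
        B_phi = (J_l - J_r) - 0.5 * Dx @ (Jw_l + Jw_r)
        B_mu = Jw_l - Jw_r
        B = np.vstack([B_phi, B_mu])
        return sweep, A, tau, B, (J_l, J_r, f_half, Dx)

    def solve(self, q: dict[str, float] | None) -> tuple:
        sweep, A, tau, B, aux = self.assemble(q)
        sol = resolve_redundancy(A, tau, B)
        return sweep, sol, aux


def solve_step(
    model: ModelDef,
    q: dict[str, float] | None = None,
    tau: np.ndarray | None = None,
) -> StepSolution:
    """Resolve muscle redundancy at one pose. If ``tau`` is omitted it is the
    model's gravity demand at ``q`` (including any shared load)."""
    engine = _StepEngine(model)
    if tau is not None:
        sweep, A, _, B, _ = engine.assemble(q)
        return resolve_redundancy(A, np.asarray(tau, float), B)
    _, sol, _ = engine.solve(q)
    return sol


def simulate_task(
    model: ModelDef,
    task: TaskDefinition | MotionTable,
    load: SharedLoad | float | None = None,
    severity: RCTSeverity | str | None = None,
    side: str = "right",
    filter_spec: FilterSpec | None = FilterSpec(),
) -> SolverResult:
    """Simulate a task: per-step static optimization over the (6 Hz filtered)
    task kinematics, with optional tear severity and shared load applied to a
    copy of the model first. Deterministic given its inputs.

    Consecutive identical postures (static holds) reuse the previous step's
    solution, so static tasks cost a single optimization.
    """
    prepared = model
    if severity is not None:
        prepared = apply_rct(prepared, severity, side=side)
    if load is not None:
        prepared = make_shared_load(prepared, load)

    table = task.table() if isinstance(task, TaskDefinition) else task
    if filter_spec is not None and table.n_rows >= 3 * filter_spec.order:
        table = butterworth_lowpass(table, filter_spec)
    table = table.in_radians()

    engine = _StepEngine(prepared)
    kin = engine.kin
    hookup = engine.hookup
    known = set(kin.coord_names)
    col_idx = [i for i, n in enumerate(table.column_names) if n in known]
    col_names = [table.column_names[i] for i in col_idx]

    n_t = table.n_rows
    n_m, n_dof = len(prepared.muscles), len(kin.free_coords)
    activations = np.empty((n_t, n_m))
    slack = np.empty((n_t, n_dof))
    feasible = np.empty(n_t, dtype=bool)
    with_load = hookup.present
    load_com = np.empty((n_t, 3)) if with_load else None
    load_jac = np.empty((n_t, 3, n_dof)) if with_load else None
    f_left = np.empty((n_t, 3)) if with_load else None
    f_right = np.empty((n_t, 3)) if with_load else None

    prev_q: np.ndarray | None = None
    for t in range(n_t):
        qmap = dict(zip(col_names, table.values[t, col_idx]))
        qv = kin.pose_to_vector(qmap)
        if prev_q is not None and np.allclose(qv, prev_q, rtol=0.0, atol=1e-10):
            activations[t] = activations[t - 1]
            slack[t] = slack[t - 1]
            feasible[t] = feasible[t - 1]
            if with_load:
                load_com[t] = load_com[t - 1]
                load_jac[t] = load_jac[t - 1]
                f_left[t] = f_left[t - 1]
                f_right[t] = f_right[t - 1]
            continue
        prev_q = qv
        sweep, sol, aux = engine.solve(kin.vector_to_pose(qv))
        activations[t] = sol.activations
        slack[t] = sol.slack
        feasible[t] = sol.feasible
        if with_load:
            J_l, J_r, f_half, _ = aux
            p_l = kin.station(sweep.X0, hookup.left_hand, hookup.left_station)
            p_r = kin.station(sweep.X0, hookup.right_hand, hookup.right_station)
            load_com[t] = 0.5 * (p_l + p_r)
            load_jac[t] = 0.5 * (J_l + J_r)
            phi = sol.wrench[:3]
            f_left[t] = f_half - phi
            f_right[t] = f_half + phi

    return SolverResult(
        time=table.time.copy(),
        muscle_names=[m.name for m in prepared.muscles],
        dof_names=list(kin.free_coords),
        fmax=engine.fmax,
        activations=activations,
        slack=slack,
        feasible=feasible,
        load_com=load_com,
        load_jac=load_jac,
        hand_force_left=f_left,
        hand_force_right=f_right,
        load_mass=hookup.mass if with_load else 0.0,
        gravity=prepared.gravity.copy(),
    )


def load_deviation(
    result: SolverResult,
    compliance: float = COMPLIANCE,
    slack_tol: float = SLACK_TOL,
) -> np.ndarray:
    """(n_t, 3) load-COM displacement implied by unmet torque.

    Surrogate mapping: unmet demand relaxes the posture along the slack with
    a uniform joint compliance c, dq = -c * tau_s, and the load COM moves
    with the posture through its point Jacobian, delta = J dq. Feasible steps
    (slack below tolerance) map to exactly zero deviation. Components follow
    the ground frame: y vertical (negative = inferior), z mediolateral
    (negative = toward the unaffected/left side when the right is affected).
    """
    if result.load_jac is None:
        raise ValueError("result has no load trajectory; simulate with a shared load")
    dev = np.zeros((result.time.size, 3))
    for t in range(result.time.size):
        s = result.slack[t]
        if np.max(np.abs(s), initial=0.0) < slack_tol:
            continue
        dev[t] = result.load_jac[t] @ (-compliance * s)
    return dev
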