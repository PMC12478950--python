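"""Moment arms, gravity demand, and the static-optimization redundancy solver,
checked against pulley-geometry, potential-energy and grid-search oracles."""
import numpy as np
import pytest

from bimanum.fk import ModelKinematics
from bimanum.model import BodyDef, CoordinateDef, JointDef, ModelDef, MuscleDef, PathPoint, TransformAxis
from bimanum.pathology_load import make_shared_load
from bimanum.solver import (
    load_deviation,
    moment_arms,
    resolve_redundancy,
    simulate_task,
    solve_step,
    static_torques,
)
from bimanum.tasks import make_static_task


def hinge_model(com=(0.2, 0.0, 0.0), mass=1.0, muscle_points=None, fmax=1000.0):
    """Ground + one body on a z-axis hinge at the origin."""
    model = ModelDef(
        name="hinge",
        bodies=[BodyDef(name="arm", mass=mass, com=com, inertia=(0.01,) * 3 + (0.0,) * 3)],
        joints=[
            JointDef(
                name="hinge",
                joint_class="CustomJoint",
                parent="ground",
                child="arm",
                coordinates=[CoordinateDef("q", range=(-np.pi, np.pi))],
                spatial_transform=[TransformAxis("rotation1", "rotation", (0, 0, 1), "q")],
            )
        ],
    )
    if muscle_points is not None:
        origin, insertion = muscle_points
        model.muscles.append(
            MuscleDef(
                name="m1",
                max_isometric_force=fmax,
                path=[PathPoint("ground", origin), PathPoint("arm", insertion)],
            )
        )
    return model


# -- moment arms ------------------------------------------------------------

def test_moment_arm_matches_pulley_geometry():
    """A straight line passing the hinge at perpendicular distance 0.03 m
    has a 0.03 m moment arm."""
    m = hinge_model(muscle_points=((-0.5, 0.03, 0.0), (0.2, 0.03, 0.0)))
    r, names, dofs = moment_arms(m, {"q": 0.0})
    assert names == ["m1"] and dofs == ["q"]
    assert abs(abs(r[0, 0]) - 0.03) < 1e-5


def test_moment_arm_zero_through_joint_center():
    m = hinge_model(muscle_points=((-0.4, 0.0, 0.0), (0.25, 0.0, 0.0)))
    r, _, _ = moment_arms(m, {"q": 0.0})
    assert abs(r[0, 0]) < 1e-9


def test_left_right_twin_moment_arms_equal(bilateral):
    q = {}
    for n in ModelKinematics(bilateral).free_coords:
        if n.endswith("_r"):
            q[n] = 0.4 if "elevation" in n else -0.2
            q[n[:-2] + "_l"] = q[n]
    r, names, dofs = moment_arms(bilateral, q)
    for i, n in enumerate(names):
        if not n.endswith("_r"):
            continue
        j = names.index(n[:-2] + "_l")
        for k, d in enumerate(dofs):
            if not d.endswith("_r"):
                continue
            kl = dofs.index(d[:-2] + "_l")
            assert abs(abs(r[i, k]) - abs(r[j, kl])) < 1e-9


# -- gravity demand ---------------------------------------------------------

def test_hanging_arm_has_no_elevation_torque():
    m = hinge_model(com=(0.0, -0.2, 0.0), mass=2.0)
    tau = static_torques(m, {"q": 0.0})
    assert abs(tau[0]) < 1e-9


def test_point_mass_closed_form():
    """Horizontal point mass at distance d demands tau = m g d."""
    m = hinge_model(com=(0.3, 0.0, 0.0), mass=2.0)
    tau = static_torques(m, {"q": 0.0})
    assert tau[0] == pytest.approx(2.0 * 9.80665 * 0.3, rel=1e-9)


def test_gravity_demand_matches_potential_energy_oracle(bilateral):
    """Virtual-work demand equals the finite-difference gradient of the
    total gravitational potential."""
    kin = ModelKinematics(bilateral)
    q = {n: v for n, v in zip(kin.free_coords, [0.5, 1.0, -0.3, 0.7, 0.5, 1.0, -0.3, 0.7])}
    tau = static_torques(bilateral, q)
    h = 1e-6
    qv = kin.pose_to_vector(q)
    oracle = np.empty_like(tau)
    for j in range(len(qv)):
        qp, qm = qv.copy(), qv.copy()
        qp[j] += h
        qm[j] -= h
        vp = kin.potential_energy(kin.body_transforms(kin.vector_to_pose(qp)))
        vm = kin.potential_energy(kin.body_transforms(kin.vector_to_pose(qm)))
        oracle[j] = (vp - vm) / (2 * h)
    np.testing.assert_allclose(tau, oracle, atol=1e-8)


# -- the QP -----------------------------------------------------------------

def test_zero_demand_gives_zero_activation():
    sol = resolve_redundancy(np.array([[20.0, 15.0]]), np.array([0.0]))
    np.testing.assert_allclose(sol.activations, 0.0, atol=1e-12)
    np.testing.assert_allclose(sol.slack, 0.0, atol=1e-12)
    assert sol.feasible


def test_single_muscle_activation():
    # r = 0.02 m, Fmax = 1000 N, tau = 10 N m -> a = tau/(r Fmax) = 0.5
    sol = resolve_redundancy(np.array([[0.02 * 1000.0]]), np.array([10.0]))
    assert sol.activations[0] == pytest.approx(0.5, abs=1e-6)


def test_two_identical_muscles_split_equally():
    sol = resolve_redundancy(np.array([[20.0, 20.0]]), np.array([10.0]))
    np.testing.assert_allclose(sol.activations, 0.25, atol=1e-3)


def test_saturation_limit():
    # capacity 20 N m, demand 30 -> a = 1, slack = 10
    sol = resolve_redundancy(np.array([[20.0]]), np.array([30.0]))
    assert sol.activations[0] == pytest.approx(1.0)
    assert sol.slack[0] == pytest.approx(10.0, abs=1e-6)
    assert not sol.feasible


def _grid_minimize(A, tau, step=1e-3):
    """Independent oracle: exhaustive enumeration of the torque-balance
    solution set at the given activation resolution.

    Every pattern of clamped bounds (each muscle free, at 0, or at 1) is
    enumerated; for each, the balance manifold of the free activations
    (min-norm solution plus null-space directions gridded at ``step``) is
    scanned inside the box and the minimum-effort point kept. Requires an
    instance whose demand is attainable within the box."""
    from itertools import product

    from scipy.linalg import null_space

    n_m = A.shape[1]
    best, best_obj = None, np.inf
    for pattern in product((None, 0.0, 1.0), repeat=n_m):
        free = [i for i, p in enumerate(pattern) if p is None]
        fixed = np.array([0.0 if p is None else p for p in pattern])
        resid_target = tau - A @ fixed
        if not free:
            if np.abs(resid_target).max() < step * np.abs(A).max():
                obj = float((fixed**2).sum())
                if obj < best_obj:
                    best, best_obj = fixed, obj
            continue
        Af = A[:, free]
        a0, *_ = np.linalg.lstsq(Af, resid_target, rcond=None)
        if np.abs(Af @ a0 - resid_target).max() > step * max(1.0, np.abs(A).max()):
            continue  # this face cannot balance the demand
        N = null_space(Af)
        if N.shape[1] == 0:
            cand = [a0]
        else:
            span = np.sqrt(len(free))
            axes = [np.arange(-span, span + step / 2, step)] * N.shape[1]
            mesh = np.meshgrid(*axes, indexing="ij")
            coeffs = np.column_stack([m.ravel() for m in mesh])
            cand = a0[None, :] + coeffs @ N.T
        pts = np.atleast_2d(cand)
        ok = ((pts >= 0.0) & (pts <= 1.0)).all(axis=1)
        if not ok.any():
            continue
        pts = pts[ok]
        full = np.tile(fixed, (pts.shape[0], 1))
        full[:, free] = pts
        obj = (full**2).sum(axis=1)
        i = int(np.argmin(obj))
        if obj[i] < best_obj:
            best, best_obj = full[i], obj[i]
    assert best is not None, "no feasible grid point; bad oracle instance"
    return best


def _random_feasible_instance(rng):
    n_dof = int(rng.integers(1, 3))
    n_m = int(rng.integers(1, 4))
    A = rng.uniform(-30, 30, size=(n_dof, n_m))
    a_inner = rng.uniform(0.1, 0.85, size=n_m)
    return A, A @ a_inner * rng.uniform(0.3, 0.95)


@pytest.mark.parametrize("seed", range(6))
def test_qp_matches_grid_search_oracle(seed):
    rng = np.random.default_rng(seed)
    A, tau = _random_feasible_instance(rng)
    sol = resolve_redundancy(A, tau)
    oracle = _grid_minimize(A, tau)
    np.testing.assert_allclose(sol.activations, oracle, atol=2e-3)


def test_torque_balance_residual_identity(rng):
    for _ in range(5):
        A = rng.uniform(-40, 40, size=(3, 6))
        tau = rng.uniform(-20, 20, size=3)
        B = rng.uniform(-1, 1, size=(2, 3))
        sol = resolve_redundancy(A, tau, B)
        balance = A @ sol.activations + sol.slack + B.T @ sol.wrench - tau
        assert np.abs(balance).max() < 1e-8


def test_infeasible_empty_actuators_reported():
    sol = resolve_redundancy(np.zeros((2, 1)), np.array([5.0, -3.0]))
    assert not sol.feasible
    np.testing.assert_allclose(sol.slack, [5.0, -3.0])


# -- task simulation --------------------------------------------------------

def test_low_task_none_severity_is_feasible(bilateral):
    res = simulate_task(bilateral, make_static_task("low", rate=20.0), load=13.3,
                        severity="none")
    assert res.feasible.all()
    assert np.abs(res.slack).max() < 1e-4


def test_zero_gravity_means_zero_activation(bilateral):
    m = bilateral.copy()
    m.gravity = np.zeros(3)
    res = simulate_task(m, make_static_task("low", rate=20.0))
    np.testing.assert_allclose(res.activations, 0.0, atol=1e-12)


def test_simulation_is_deterministic(bilateral):
    task = make_static_task("high", rate=20.0)
    r1 = simulate_task(bilateral, task, load=44.5, severity="full")
    r2 = simulate_task(bilateral, task, load=44.5, severity="full")
    np.testing.assert_array_equal(r1.activations, r2.activations)
    np.testing.assert_array_equal(r1.slack, r2.slack)
    np.testing.assert_array_equal(r1.load_com, r2.load_com)


def test_zero_load_limit_matches_unloaded(bilateral):
    task = make_static_task("low", rate=20.0)
    loaded0 = simulate_task(bilateral, task, load=0.0)
    unloaded = simulate_task(bilateral, task)
    np.testing.assert_allclose(loaded0.activations, unloaded.activations, atol=1e-9)


def test_bilateral_recruitment_symmetric_at_none(bilateral):
    res = simulate_task(bilateral, make_static_task("low", rate=20.0), load=13.3,
                        severity="none")
    a = res.activations[0]
    for i, n in enumerate(res.muscle_names):
        if n.endswith("_r"):
            j = res.muscle_names.index(n[:-2] + "_l")
            assert abs(a[i] - a[j]) < 1e-9


def test_hand_forces_sum_to_load_weight(bilateral):
    res = simulate_task(bilateral, make_static_task("low", rate=20.0), load=44.5,
                        severity="none")
    total = res.hand_force_left + res.hand_force_right
    expected = np.broadcast_to(-res.load_mass * res.gravity, total.shape)
    np.testing.assert_allclose(total, expected, atol=1e-9)
    # symmetric task, no tear: equal vertical share
    assert res.hand_force_right[0, 1] == pytest.approx(res.load_mass * 9.80665 / 2, rel=1e-6)


def test_solve_step_matches_simulation_first_step(bilateral):
    loaded = make_shared_load(bilateral, 13.3)
    pose = {n: np.deg2rad(80.0) for n in
            ("shoulder_elevation_r", "shoulder_elevation_l",
             "elevation_angle_r", "elevation_angle_l")}
    sol = solve_step(loaded, pose)
    assert sol.feasible
    assert sol.activations.max() <= 1.0 and sol.activations.min() >= 0.0


# -- deviation surrogate ----------------------------------------------------

def test_feasible_steps_have_zero_deviation(bilateral):
    res = simulate_task(bilateral, make_static_task("low", rate=20.0), load=13.3,
                        severity="massive")
    assert res.feasible.all()
    np.testing.assert_array_equal(load_deviation(res), 0.0)


def test_elevation_deficit_maps_to_inferior_deviation(bilateral):
    res = simulate_task(bilateral, make_static_task("low", rate=20.0), load=13.3)
    # inject a pure elevation deficit on both sides
    res.slack[:] = 0.0
    for j, d in enumerate(res.dof_names):
        if "shoulder_elevation" in d:
            res.slack[:, j] = 5.0
    dev = load_deviation(res)
    assert (dev[:, 1] < 0).all()  # strictly inferior


def test_deviation_requires_load(bilateral):
    res = simulate_task(bilateral, make_static_task("low", rate=20.0))
    with pytest.raises(ValueError, match="load"):
        load_deviation(res)
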