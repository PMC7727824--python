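"""Trajectory planners for the two-axis microgravity simulator.

Three control schemes are provided:

* :func:`random_walk_sphere` — the textbook random walk on the sphere with
  90-degree left/right turns, as a direction-path reference process;
* :func:`classic_random_control` — conventional random axis control
  (piecewise-constant random rates with random dwell times), which
  concentrates the direction path at the inner-axis poles;
* :func:`uniform_coverage_planner` — the optimized planner: low-discrepancy
  spherical waypoints visited in a greedily compensated order, joined by
  rest-to-rest seven-phase jerk-limited (S-curve) moves, supporting both
  zero-gravity and partial-gravity targets.

All planners respect :class:`MotionLimits` (rate, acceleration and jerk)
at every sample and are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .kinematics import DirectionPath, Trajectory, gravity_direction


class PlannerError(RuntimeError):
    """Raised when a plan cannot be realized within its configuration."""


@dataclass(frozen=True)
class MotionLimits:
    """Per-axis kinematic bounds (radians).  Defaults correspond to
    60 deg/s, 60 deg/s^2, 120 deg/s^3 — a typical operating envelope for a
    benchtop random-positioning machine."""

    rate_max: float = math.radians(60.0)
    acc_max: float = math.radians(60.0)
    jerk_max: float = math.radians(120.0)

    def __post_init__(self) -> None:
        if min(self.rate_max, self.acc_max, self.jerk_max) <= 0:
            raise ValueError("motion limits must be strictly positive")


@dataclass(frozen=True)
class PlannerConfig:
    """Configuration of a planner run.

    ``mode`` is ``"zero"`` (nullify the time-averaged gravity vector) or
    ``"partial"`` (drive its magnitude to ``target_g`` in units of g).
    ``compensation`` enables greedy cancellation of the running direction
    sum, including the deterministic end-of-run trim.
    """

    duration: float
    dt: float = 0.01
    limits: MotionLimits = field(default_factory=MotionLimits)
    mode: str = "zero"
    target_g: float = 0.0
    seed: int = 0
    compensation: bool = True

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.mode not in ("zero", "partial"):
            raise ValueError("mode must be 'zero' or 'partial'")
        if not 0.0 <= self.target_g < 1.0:
            raise ValueError("target_g must lie in [0, 1)")
        if self.mode == "zero" and self.target_g != 0.0:
            raise ValueError("target_g must be 0 in zero-gravity mode")


# ---------------------------------------------------------------------------
# seven-phase jerk-limited segment


def _scurve_plan(D: float, vm: float, am: float, jm: float):
    """Phase times (tj, ta, tc) and peak rate for a rest-to-rest move of
    non-negative distance D under rate/acc/jerk limits."""
    if D <= 0.0:
        return 0.0, 0.0, 0.0, 0.0

    def t_acc(v: float) -> float:  # time from rest to rate v
        if v * jm >= am * am:
            return v / am + am / jm
        return 2.0 * math.sqrt(v / jm)

    if vm * t_acc(vm) <= D:  # cruise phase exists
        vp = vm
        tc = (D - vp * t_acc(vp)) / vp
    else:
        tc = 0.0
        v_crit = am * am / jm
        if v_crit * t_acc(v_crit) >= D:  # acceleration limit never reached
            vp = (0.5 * D * math.sqrt(jm)) ** (2.0 / 3.0)
        else:
            b = am * am / jm
            vp = 0.5 * (-b + math.sqrt(b * b + 4.0 * am * D))
    if vp * jm >= am * am:
        tj = am / jm
        ta = vp / am - am / jm
    else:
        tj = math.sqrt(vp / jm)
        ta = 0.0
    return tj, ta, tc, vp


def scurve_duration(D: float, limits: MotionLimits) -> float:
    """Minimum time of a rest-to-rest move of distance |D|."""
    tj, ta, tc, _ = _scurve_plan(abs(D), limits.rate_max, limits.acc_max,
                                 limits.jerk_max)
    return 4.0 * tj + 2.0 * ta + tc


def scurve_segment(q0: float, q1: float, limits: MotionLimits,
                   dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rest-to-rest seven-phase S-curve profile from q0 to q1.

    Returns ``(angle, rate, acc)`` sampled at 0, dt, ..., N*dt with
    ``N = ceil(T/dt)``; samples at or beyond the analytic end time T hold
    ``(q1, 0, 0)``.  Endpoints are exact; |rate| <= rate_max,
    |acc| <= acc_max and the sampled jerk never exceeds jerk_max.
    A degenerate move (q0 == q1) returns a single constant sample.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    D = q1 - q0
    if D == 0.0:
        return (np.array([q0]), np.zeros(1), np.zeros(1))
    s = math.copysign(1.0, D)
    jm = limits.jerk_max
    tj, ta, tc, _vp = _scurve_plan(abs(D), limits.rate_max, limits.acc_max, jm)
    phases = [(tj, jm), (ta, 0.0), (tj, -jm), (tc, 0.0),
              (tj, -jm), (ta, 0.0), (tj, jm)]
    # integrate phase-boundary states of the |D| move
    tb = [0.0]
    qb, vb, ab = [0.0], [0.0], [0.0]
    for dur, j in phases:
        q, v, a = qb[-1], vb[-1], ab[-1]
        qb.append(q + v * dur + 0.5 * a * dur ** 2 + j * dur ** 3 / 6.0)
        vb.append(v + a * dur + 0.5 * j * dur ** 2)
        ab.append(a + j * dur)
        tb.append(tb[-1] + dur)
    T = tb[-1]
    n = int(math.ceil(T / dt - 1e-12))
    t = np.arange(n + 1) * dt
    jerks = np.array([j for _, j in phases] + [0.0])
    tb_arr = np.array(tb)
    idx = np.minimum(np.searchsorted(tb_arr, t, side="right") - 1, len(phases))
    tau = t - tb_arr[idx]
    q0b = np.array(qb)[idx]
    v0b = np.array(vb)[idx]
    a0b = np.array(ab)[idx]
    jb = jerks[idx]
    q = q0b + v0b * tau + 0.5 * a0b * tau ** 2 + jb * tau ** 3 / 6.0
    v = v0b + a0b * tau + 0.5 * jb * tau ** 2
    a = a0b + jb * tau
    done = t >= T - 1e-12
    q[done], v[done], a[done] = abs(D), 0.0, 0.0
    return q0 + s * q, s * v, s * a


# ---------------------------------------------------------------------------
# inverse kinematics


def _unwrap_to(x: float, ref: float) -> float:
    """Equivalent angle of x (mod 2 pi) nearest to ref."""
    return x + 2.0 * math.pi * round((ref - x) / (2.0 * math.pi))


def inverse_kinematics(u, current: tuple[float, float] = (0.0, 0.0)
                       ) -> tuple[float, float]:
    """Gimbal angles (alpha, beta) whose forward map reproduces the gravity
    direction ``u``, choosing the solution branch nearest to ``current``.

    At gimbal lock (|u_y| = 1 under the package convention) beta is
    redundant and keeps its current value.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (3,) or abs(np.linalg.norm(u) - 1.0) > 1e-6:
        raise ValueError("u must be a unit 3-vector (|norm - 1| <= 1e-6)")
    a0, b0 = current
    sa = -u[1]
    ca_mag = math.sqrt(max(0.0, 1.0 - sa * sa))
    if ca_mag < 1e-8:  # gimbal lock: any beta works
        alpha = _unwrap_to(math.copysign(math.pi / 2.0, sa), a0)
        return alpha, b0
    best = None
    for s in (1.0, -1.0):
        alpha = _unwrap_to(math.atan2(sa, s * ca_mag), a0)
        beta = _unwrap_to(math.atan2(s * u[0], -s * u[2]), b0)
        cost = max(abs(alpha - a0), abs(beta - b0))
        if best is None or cost < best[0]:
            best = (cost, alpha, beta)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# random walk on the sphere


def random_walk_sphere(n_steps: int, step_arc: float = math.radians(5.0),
                       seed: int = 0) -> DirectionPath:
    """Random walk on the unit sphere: geodesic steps of fixed arc length,
    with the heading turning exactly 90 degrees left or right (probability
    1/2 each) after every step.

    Returns the ``n_steps + 1`` visited points (timestamps are step
    indices).  The walk starts at the south pole with a seeded random
    initial heading.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not 0.0 < step_arc < math.pi:
        raise ValueError("step_arc must lie in (0, pi)")
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    p = np.array([0.0, 0.0, -1.0])
    h = np.array([math.cos(phi), math.sin(phi), 0.0])
    turns = rng.integers(0, 2, size=n_steps)  # 0 = left, 1 = right
    c, s = math.cos(step_arc), math.sin(step_arc)
    pts = np.empty((n_steps + 1, 3))
    pts[0] = p
    for k in range(n_steps):
        p, h = c * p + s * h, -s * p + c * h
        # re-orthonormalize the moving frame: the rotate/turn recursion is
        # otherwise numerically unstable over long walks
        p /= np.linalg.norm(p)
        h -= (p @ h) * p
        h /= np.linalg.norm(h)
        pts[k + 1] = p
        sign = 1.0 if turns[k] == 0 else -1.0
        h = sign * np.cross(p, h)
    return DirectionPath(t=np.arange(n_steps + 1, dtype=float), directions=pts)


# ---------------------------------------------------------------------------
# conventional random axis control


def classic_random_control(config: PlannerConfig) -> Trajectory:
    """Conventional random control: each axis tracks a piecewise-constant
    random rate target (uniform within the rate limit, dwell times uniform
    in [1, 10] s) through a jerk-limited velocity ramp.

    The induced direction path is the classic latitude-longitude measure of
    a doubly rotating frame: it concentrates at the inner-axis poles and is
    far from uniform.
    """
    lim = config.limits
    dt = config.dt
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration / dt)) + 1
    # 1% margin keeps the discretized ramp strictly inside the rate limit
    # (the jerk-limited tracker can overshoot its target by O(jerk dt^2))
    vm = lim.rate_max * 0.99
    ang = np.zeros((2, n))
    rate = np.zeros((2, n))
    acc = np.zeros((2, n))
    target = rng.uniform(-vm, vm, size=2)
    next_event = rng.uniform(1.0, 10.0, size=2)
    v = np.zeros(2)
    a = np.zeros(2)
    for k in range(1, n):
        t = k * dt
        for ax in range(2):
            if t >= next_event[ax]:
                target[ax] = rng.uniform(-vm, vm)
                next_event[ax] += rng.uniform(1.0, 10.0)
            verr = target[ax] - v[ax]
            alim = min(lim.acc_max, math.sqrt(2.0 * lim.jerk_max * abs(verr)))
            a_des = min(max(verr / dt, -alim), alim)
            a_new = min(max(a_des, a[ax] - lim.jerk_max * dt),
                        a[ax] + lim.jerk_max * dt)
            v_new = v[ax] + a_new * dt
            ang[ax, k] = ang[ax, k - 1] + 0.5 * (v[ax] + v_new) * dt
            v[ax], a[ax] = v_new, a_new
            rate[ax, k] = v_new
            acc[ax, k] = a_new
    t_arr = np.arange(n) * dt
    return Trajectory(t=t_arr, alpha=ang[0], beta=ang[1],
                      alpha_rate=rate[0], beta_rate=rate[1],
                      alpha_acc=acc[0], beta_acc=acc[1], dt=dt)


# ---------------------------------------------------------------------------
# optimized uniform-coverage planner


def fibonacci_sphere(n: int) -> np.ndarray:
    """Spherical Fibonacci lattice: n nearly equal-spaced unit vectors."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=-1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a seeded generator."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class _Builder:
    """Accumulates trajectory samples and the running direction sum."""

    def __init__(self, n_total: int, dt: float):
        self.N = n_total
        self.dt = dt
        self.cols = np.zeros((6, n_total))  # alpha, beta, rates, accs
        self.n = 0
        self.S = np.zeros(3)
        self.pose = (0.0, 0.0)

    @property
    def room(self) -> int:
        return self.N - self.n

    def push(self, alpha, beta, a_rate, b_rate, a_acc, b_acc) -> None:
        k = len(alpha)
        if k == 0:
            return
        if k > self.room:
            raise PlannerError("internal: segment exceeds trajectory length")
        sl = slice(self.n, self.n + k)
        self.cols[0, sl] = alpha
        self.cols[1, sl] = beta
        self.cols[2, sl] = a_rate
        self.cols[3, sl] = b_rate
        self.cols[4, sl] = a_acc
        self.cols[5, sl] = b_acc
        self.S += gravity_direction(alpha, beta).sum(axis=0)
        self.n += k
        self.pose = (float(alpha[-1]), float(beta[-1]))

    def dwell(self, k: int) -> None:
        if k <= 0:
            return
        a0, b0 = self.pose
        z = np.zeros(k)
        self.push(np.full(k, a0), np.full(k, b0), z, z, z, z)

    def finish(self) -> Trajectory:
        if self.n != self.N:
            raise PlannerError("internal: trajectory not fully planned")
        t = np.arange(self.N) * self.dt
        c = self.cols
        return Trajectory(t=t, alpha=c[0], beta=c[1], alpha_rate=c[2],
                          beta_rate=c[3], alpha_acc=c[4], beta_acc=c[5],
                          dt=self.dt)


def _biaxial_segment(pose: tuple[float, float], target: tuple[float, float],
                     limits: MotionLimits, dt: float):
    """Synchronized rest-to-rest move of both axes; the faster axis rests
    while the slower finishes.  Returns six arrays with the initial sample
    (the current pose) dropped."""
    a0, b0 = pose
    a1, b1 = target
    qa, va, aa = scurve_segment(a0, a1, limits, dt)
    qb, vb, ab = scurve_segment(b0, b1, limits, dt)
    L = max(len(qa), len(qb))

    def pad(q, v, a, q_end):
        k = L - len(q)
        if k <= 0:
            return q, v, a
        return (np.concatenate([q, np.full(k, q_end)]),
                np.concatenate([v, np.zeros(k)]),
                np.concatenate([a, np.zeros(k)]))

    qa, va, aa = pad(qa, va, aa, a1)
    qb, vb, ab = pad(qb, vb, ab, b1)
    return qa[1:], qb[1:], va[1:], vb[1:], aa[1:], ab[1:]


def _segment_to_direction(b: _Builder, w, limits: MotionLimits):
    """Plan (without pushing) the move from the builder pose to direction w."""
    tgt = inverse_kinematics(w, b.pose)
    return _biaxial_segment(b.pose, tgt, limits, b.dt)


def _geodesic_mean(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Average direction along the great-circle arc from u to w."""
    d = float(np.clip(u @ w, -1.0, 1.0))
    theta = math.acos(d)
    if theta < 1e-9:
        return u
    return (u + w) * (math.tan(0.5 * theta) / theta)


def _greedy_pick(b: _Builder, pool: list[np.ndarray], limits: MotionLimits,
                 m_target: np.ndarray) -> int:
    """Index of the pool waypoint whose visit best keeps the accumulated
    direction sum on the target ray (estimate: S-curve segment time plus
    geodesic mean of the transit arc)."""
    u_now = gravity_direction(*b.pose)
    best_i, best_cost = 0, float("inf")
    for i, w in enumerate(pool):
        ta, tb = inverse_kinematics(w, b.pose)
        T = max(scurve_duration(ta - b.pose[0], limits),
                scurve_duration(tb - b.pose[1], limits))
        n_c = max(1, int(round(T / b.dt)))
        est = b.S + n_c * _geodesic_mean(u_now, w) - (b.n + n_c) * m_target
        cost = float(est @ est)
        if cost < best_cost:
            best_i, best_cost = i, cost
    return best_i


def _alpha_pi_move(b: _Builder, limits: MotionLimits):
    """Plan a pure outer-axis half turn from the current pose (u -> -u)."""
    a0, b0 = b.pose
    return _biaxial_segment(b.pose, (a0 + math.pi, b0), limits, b.dt)


def _compensation_finale(b: _Builder, m_target: np.ndarray,
                         limits: MotionLimits) -> None:
    """Deterministic end-of-run trim: drive the total direction sum to
    N * m_target to within a few samples' worth.

    Strategy: (1) short transits toward the current deficit direction;
    (2) fill the remaining budget with dwells at the deficit direction and
    its exact antipode (reached by outer-axis half turns), splitting the
    dwell counts so the projected deficit cancels.  The two half turns
    traverse opposite halves of a great circle, so their sums cancel to
    first order as well.
    """
    # (1) transits toward the deficit
    seg_pi = _alpha_pi_move(b, limits)
    L_pi = len(seg_pi[0])
    for _ in range(2):
        r = b.N * m_target - b.S
        if np.linalg.norm(r) < 1.0:
            break
        w = r / np.linalg.norm(r)
        seg = _segment_to_direction(b, w, limits)
        if len(seg[0]) > b.room - 2 * L_pi - 2:
            break
        b.push(*seg)
    # (2) balanced antipodal dwell fill
    seg1 = _alpha_pi_move(b, limits)
    L1 = len(seg1[0])
    a0, b0 = b.pose
    seg2 = _biaxial_segment((a0 + math.pi, b0), (a0 + 2 * math.pi, b0),
                            limits, b.dt)
    L2 = len(seg2[0])
    B = b.room
    if B < L1 + L2 + 2:  # no room for the turns: plain dwell-out
        b.dwell(B)
        return
    u_now = gravity_direction(*b.pose)
    s1 = gravity_direction(seg1[0], seg1[1]).sum(axis=0)
    s2 = gravity_direction(seg2[0], seg2[1]).sum(axis=0)
    D = B - L1 - L2
    need = (b.N * m_target - b.S) - s1 - s2
    p = int(round(min(max(float(need @ u_now), -D), D)))
    k2 = (D - p) // 2
    k13 = D - k2
    k1 = k13 // 2
    k3 = k13 - k1
    b.dwell(k1)
    b.push(*seg1)
    b.dwell(k2)
    b.push(*seg2)
    b.dwell(k3)


def _waypoint_pool(config: PlannerConfig, rng: np.random.Generator,
                   size: int) -> list[np.ndarray]:
    """Fresh pool of waypoint directions for one coverage pass."""
    if config.mode == "zero":
        pts = fibonacci_sphere(size) @ _random_rotation(rng).T
    else:
        from .metrics import sample_vmf, vmf_kappa_for_mean_length
        kappa = vmf_kappa_for_mean_length(config.target_g)
        pts = sample_vmf(np.array([0.0, 0.0, -1.0]), kappa, size, rng=rng)
    return [pts[i] for i in range(len(pts))]


def uniform_coverage_planner(config: PlannerConfig,
                             pool_size: int = 64) -> Trajectory:
    """Optimized trajectory planner with uniform sphere coverage (zero
    gravity) or a controlled concentration about the downward pole (partial
    gravity).

    Waypoint gravity directions come from a spherical Fibonacci lattice
    (zero mode; re-rotated each pass) or a von Mises-Fisher sample whose
    mean resultant length equals ``target_g`` (partial mode).  When
    ``compensation`` is on, waypoints are visited in the order that best
    cancels the running direction sum, and a deterministic trim at the end
    of the run removes the remaining imbalance.
    """
    lim = config.limits
    rng = np.random.default_rng(config.seed)
    N = int(round(config.duration / config.dt)) + 1
    b = _Builder(N, config.dt)
    z = np.zeros(1)
    b.push(z, z, z, z, z, z)  # start at rest, pose (0, 0)
    m_target = np.array([0.0, 0.0, -config.target_g])
    pool = _waypoint_pool(config, rng, pool_size)
    # reserve room for the compensation finale
    seg_pi_len = max(1, int(math.ceil(
        scurve_duration(math.pi, lim) / config.dt)))
    dwell_cap = int(min(0.02 * N, 12.0 / config.dt))
    reserve = min(N - 1, 2 * seg_pi_len + max(dwell_cap, 100)) \
        if config.compensation else 0
    stop_at = N - reserve
    first = True
    while b.n < stop_at:
        i = _greedy_pick(b, pool, lim, m_target) if config.compensation else 0
        seg = _segment_to_direction(b, pool[i], lim)
        L = len(seg[0])
        if first and L > N - 1:
            raise PlannerError(
                f"duration {config.duration} s too short for a single "
                f"waypoint move ({L * config.dt:.1f} s)")
        first = False
        if b.n + L > stop_at:
            if config.compensation:
                break
            take = min(L, b.room)
            b.push(*(c[:take] for c in seg))
            break
        b.push(*seg)
        pool.pop(i)
        if not pool:
            pool = _waypoint_pool(config, rng, pool_size)
    if config.compensation:
        _compensation_finale(b, m_target, lim)
    else:
        b.dwell(b.room)
    return b.finish()


# ---------------------------------------------------------------------------


def trajectory_to_direction_path(traj: Trajectory,
                                 decimate: int = 1) -> DirectionPath:
    """Gravity direction of every ``decimate``-th trajectory state.

    Decimation thins the serially correlated path before uniformity
    testing; timestamps are preserved.
    """
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    u = gravity_direction(traj.alpha[::decimate], traj.beta[::decimate])
    return DirectionPath(t=traj.t[::decimate].copy(), directions=u)
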