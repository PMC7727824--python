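"""Rigid-body kinematics of a two-axis microgravity simulator.

The machine is modelled as a gimbal with a fixed pivot: an outer frame
rotating about the laboratory x-axis by the angle ``alpha``, carrying an
inner frame that rotates about the outer frame's y-axis by ``beta``.
The laboratory frame is z-up, so gravity is ``(0, 0, -G_STD)``.

Axis convention (used everywhere in this package)
-------------------------------------------------
``R = Rx(alpha) @ Ry(beta)`` maps inner-frame (sample) coordinates to the
laboratory frame.  The gravity direction seen by a sample is

    u = R.T @ (0, 0, -1) = (sin(beta) cos(alpha), -sin(alpha), -cos(beta) cos(alpha))

Angles are radians, times are seconds, lengths are metres throughout the
library; degrees appear only at the command-line boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard gravitational acceleration, m/s^2.
G_STD = 9.80665

#: Unit vector of gravity in the laboratory frame (z-up convention).
DOWN = np.array([0.0, 0.0, -1.0])


@dataclass(frozen=True)
class LabFrame:
    """The inertial laboratory frame: z-up, gravity pointing down."""

    g_std: float = G_STD

    @property
    def gravity_vector(self) -> np.ndarray:
        return self.g_std * DOWN


@dataclass(frozen=True)
class GimbalState:
    """Instantaneous state of the two gimbal axes.

    Angles are unwrapped reals (a planner may accumulate many turns).
    """

    t: float
    alpha: float
    beta: float
    alpha_rate: float = 0.0
    beta_rate: float = 0.0
    alpha_acc: float = 0.0
    beta_acc: float = 0.0


@dataclass
class Trajectory:
    """Uniformly sampled time series of gimbal states (array-of-columns).

    ``t`` must be strictly increasing with fixed spacing ``dt``; the stored
    rates are the exact time derivatives of the stored angles for every
    planner in this package, so central differences of the angle columns
    reproduce the rate columns to O(dt^2).
    """

    t: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    alpha_rate: np.ndarray
    beta_rate: np.ndarray
    alpha_acc: np.ndarray
    beta_acc: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        cols = (self.t, self.alpha, self.beta, self.alpha_rate,
                self.beta_rate, self.alpha_acc, self.beta_acc)
        n = len(self.t)
        if any(len(c) != n for c in cols):
            raise ValueError("trajectory columns must have equal length")
        if n == 0:
            raise ValueError("empty trajectory")
        if not all(np.all(np.isfinite(c)) for c in cols):
            raise ValueError("trajectory contains non-finite values")
        if n > 1:
            steps = np.diff(self.t)
            if np.any(steps <= 0) or not np.allclose(steps, self.dt, rtol=0, atol=1e-9):
                raise ValueError("trajectory times must increase uniformly by dt")

    def __len__(self) -> int:
        return len(self.t)

    def state(self, i: int) -> GimbalState:
        return GimbalState(self.t[i], self.alpha[i], self.beta[i],
                           self.alpha_rate[i], self.beta_rate[i],
                           self.alpha_acc[i], self.beta_acc[i])


@dataclass(frozen=True)
class SampleSpec:
    """A mounted sample: offset from the pivot (inner-frame coords), control
    volume and density.  Mass is derived, m = rho * V_c."""

    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    volume: float = 4e-15       # m^3, of the order of a single cell
    density: float = 1000.0     # kg/m^3, aqueous

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.density <= 0:
            raise ValueError("volume and density must be positive")

    @property
    def mass(self) -> float:
        return self.density * self.volume

    @property
    def offset_vector(self) -> np.ndarray:
        return np.asarray(self.offset, dtype=float)


@dataclass
class KinematicsSeries:
    """Lab-frame position/velocity/acceleration of one sample point."""

    t: np.ndarray
    position: np.ndarray      # (n, 3) m
    velocity: np.ndarray      # (n, 3) m/s
    acceleration: np.ndarray  # (n, 3) m/s^2


@dataclass
class DirectionPath:
    """Unit gravity-direction vectors in the sample frame — the path on
    the sphere whose homogeneity determines simulation quality."""

    t: np.ndarray
    directions: np.ndarray  # (n, 3), unit rows

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        self.t = np.asarray(self.t, dtype=float)
        if self.directions.shape != (len(self.t), 3):
            raise ValueError("directions must be (n, 3) matching timestamps")
        norms = np.linalg.norm(self.directions, axis=1)
        if len(norms) == 0:
            raise ValueError("empty direction path")
        if np.max(np.abs(norms - 1.0)) > 1e-9:
            raise ValueError("directions must be unit vectors (|norm - 1| <= 1e-9)")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ResidualGravitySeries:
    """Running time average of the gravity vector in the sample frame.

    ``magnitude_g`` is the norm of that average in units of g; it equals the
    mean resultant length of the direction sample by construction.
    """

    t: np.ndarray
    averaged_vector: np.ndarray  # (n, 3) m/s^2
    magnitude_g: np.ndarray      # dimensionless, in [0, 1]

    @property
    def final_magnitude_g(self) -> float:
        return float(self.magnitude_g[-1])


# ---------------------------------------------------------------------------
# rotations and gravity direction


def compose_rotation(alpha, beta) -> np.ndarray:
    """Rotation matrix R = Rx(alpha) @ Ry(beta) (inner frame -> lab frame).

    Accepts scalars or broadcastable arrays; returns shape (..., 3, 3).
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(beta))):
        raise ValueError("angles must be finite")
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    zero = np.zeros(np.broadcast(ca, cb).shape)
    one = np.ones_like(zero)
    # Rx(a) @ Ry(b), written out
    R = np.stack([
        np.stack([cb + zero, zero, sb + zero], axis=-1),
        np.stack([sa * sb, ca + zero, -sa * cb], axis=-1),
        np.stack([-ca * sb, sa + zero, ca * cb], axis=-1),
    ], axis=-2)
    return R


def gravity_direction(alpha, beta) -> np.ndarray:
    """Unit gravity direction in the sample frame, u = R(alpha, beta)^T (0,0,-1).

    Closed form under the package convention:
    ``(sin(beta) cos(alpha), -sin(alpha), -cos(beta) cos(alpha))``.
    Accepts scalars (returns shape (3,)) or arrays (returns (..., 3)).
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not (np.all(np.isfinite(alpha)) and np.all(np.isfinite(beta))):
        raise ValueError("angles must be finite")
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    return np.stack([sb * ca, -sa, -cb * ca], axis=-1)


def state_gravity_direction(state: GimbalState) -> np.ndarray:
    return gravity_direction(state.alpha, state.beta)


# ---------------------------------------------------------------------------
# point kinematics


def body_angular_velocity(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Angular velocity of the inner frame, in inner-frame coordinates, and
    its analytic time derivative.

    omega = alpha_rate * Ry(beta)^T x_hat + beta_rate * y_hat
          = (alpha_rate cos beta, beta_rate, alpha_rate sin beta)

    The derivative is assembled from the stored rates and accelerations
    rather than by differencing, so it carries no sampling error.
    """
    cb, sb = np.cos(traj.beta), np.sin(traj.beta)
    ar, br = traj.alpha_rate, traj.beta_rate
    aa, ba = traj.alpha_acc, traj.beta_acc
    omega = np.stack([ar * cb, br, ar * sb], axis=-1)
    domega = np.stack([aa * cb - ar * br * sb, ba, aa * sb + ar * br * cb], axis=-1)
    return omega, domega


def point_kinematics(traj: Trajectory, sample: SampleSpec) -> KinematicsSeries:
    """Lab-frame position, velocity and analytic acceleration of a sample
    point rigidly mounted at ``sample.offset`` (pivot fixed at the origin).

    a_lab = R (omega x (omega x r) + domega x r): centripetal + Euler terms.
    """
    if len(traj) < 5:
        raise ValueError("trajectory too short (need >= 5 samples)")
    r = sample.offset_vector
    R = compose_rotation(traj.alpha, traj.beta)
    omega, domega = body_angular_velocity(traj)
    a_body = np.cross(omega, np.cross(omega, r)) + np.cross(domega, r)
    v_body = np.cross(omega, r)
    pos = np.einsum("nij,j->ni", R, r)
    vel = np.einsum("nij,nj->ni", R, v_body)
    acc = np.einsum("nij,nj->ni", R, a_body)
    return KinematicsSeries(t=traj.t.copy(), position=pos, velocity=vel, acceleration=acc)


def finite_difference_acceleration(traj: Trajectory, sample: SampleSpec) -> np.ndarray:
    """Cross-validation variant: second derivative of the lab-frame position
    by the 3-point central stencil, O(dt^2) accurate on the interior.

    The sample at each edge is a copy of the nearest interior value;
    comparisons should use the interior ``[1:-1]``.
    """
    if len(traj) < 5:
        raise ValueError("trajectory too short (need >= 5 samples)")
    r = sample.offset_vector
    R = compose_rotation(traj.alpha, traj.beta)
    pos = np.einsum("nij,j->ni", R, r)
    dt2 = traj.dt ** 2
    acc = np.empty_like(pos)
    acc[1:-1] = (pos[:-2] - 2.0 * pos[1:-1] + pos[2:]) / dt2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    return acc


def apparent_and_gravity_force(sample: SampleSpec, a) -> tuple[np.ndarray, np.ndarray]:
    """F_a = m a (apparent force from machine motion) and F_g = m g.

    External forces (shear, magnetic) are not modelled.
    """
    a = np.asarray(a, dtype=float)
    m = sample.mass
    return m * a, m * LabFrame().gravity_vector


# ---------------------------------------------------------------------------
# residual gravity


def residual_gravity(path: DirectionPath) -> ResidualGravitySeries:
    """Running mean of the gravity vector over a direction path.

    g_bar(T) = (g/N_T) sum_{t_k <= T} u(t_k).  The reported magnitude is
    |g_bar|/g, i.e. exactly the mean resultant length of the directions seen
    so far; it starts at 1 and is bounded by [0, 1].
    """
    if len(path) == 0:
        raise ValueError("empty direction path")
    counts = np.arange(1, len(path) + 1, dtype=float)[:, None]
    mean = np.cumsum(path.directions, axis=0) / counts
    mag = np.linalg.norm(mean, axis=1)
    return ResidualGravitySeries(t=path.t.copy(),
                                 averaged_vector=G_STD * mean,
                                 magnitude_g=mag)
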