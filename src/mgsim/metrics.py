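"""Path-quality metrics: spherical uniformity statistics, Monte-Carlo null
calibration, equal-area sphere histograms, residual-gravity and per-sample
equality summaries, plus the direction samplers used for calibration.

Uniformity factor
-----------------
With pairwise angles Theta_ij = arccos(u_i . u_j) over i < j, the Sobolev
components are

    A_n = n/2 - (2 / (n pi)) * sum Theta_ij        (Ajne-type, odd harmonics)
    G_n = n/2 - (4 / (n pi)) * sum sin(Theta_ij)   (Gine-type, even harmonics)

Two normalizations of the uniformity factor F* are offered:

* ``"sum"`` (default): F* = A_n + G_n.  Null reference (iid uniform on the
  sphere): mean 1.00, 95th percentile about 1.68.
* ``"classical"``: F* = 2 A_n + G_n, which equals the classical Gine (1975)
  statistic F_n = 4 A_Ajne + G_n with A_Ajne = n/4 - (1/(n pi)) sum Theta.
  Its null 99th percentile is about 3.63 — the uniformity threshold quoted
  in the random-positioning-machine literature (3.633).

Both grow without bound as the sample concentrates; both are invariant
under global rotations of the point set.  :func:`calibrate_null` provides
seeded Monte-Carlo percentiles for either normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .kinematics import (DirectionPath, SampleSpec, Trajectory,
                         point_kinematics, residual_gravity)

NORMALIZATIONS = ("sum", "classical")


@dataclass(frozen=True)
class UniformityResult:
    """Components and value of the uniformity factor for one point set."""

    n: int
    A_n: float
    G_n: float
    F_star: float
    normalization: str = "sum"


@dataclass(frozen=True)
class CalibrationResult:
    """Monte-Carlo null distribution summary of F* under iid uniformity."""

    n: int
    reps: int
    mean: float
    percentiles: dict[float, float]
    normalization: str = "sum"

    def critical_value(self, level: float = 0.95) -> float:
        return self.percentiles[level]


@dataclass
class EqualityReport:
    """Per-sample motion metrics used to verify equal treatment."""

    offsets: np.ndarray          # (k, 3) m
    rms_acceleration: np.ndarray  # m/s^2
    max_acceleration: np.ndarray  # m/s^2
    mean_residual_g: np.ndarray   # units of g (same for all offsets)


# ---------------------------------------------------------------------------
# uniformity statistic


def _pair_sums(u: np.ndarray, block: int = 2048) -> tuple[float, float]:
    """Sums of Theta_ij and sin(Theta_ij) over i < j, block-wise to bound
    memory for large n."""
    n = len(u)
    s_theta = 0.0
    s_sin = 0.0
    for start in range(0, n, block):
        rows = u[start:start + block]
        g = np.clip(rows @ u.T, -1.0, 1.0)
        # force the diagonal to an exact zero angle: u_i . u_i evaluates to
        # 1 - O(eps) and arccos amplifies that to O(sqrt(eps))
        k = np.arange(len(rows))
        g[k, start + k] = 1.0
        th = np.arccos(g)
        s_theta += th.sum()
        s_sin += np.sin(th).sum()
    # the full double sum counts each pair twice; the diagonal contributes 0
    return 0.5 * s_theta, 0.5 * s_sin


def gine_F(points, normalization: str = "sum") -> UniformityResult:
    """Uniformity factor of a set of unit direction vectors.

    ``normalization="sum"`` returns F* = A_n + G_n (package default);
    ``"classical"`` returns the classical Gine statistic 2 A_n + G_n.
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    u = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(u)
    if n < 2:
        raise ValueError("need at least 2 points")
    if u.shape[1] != 3 or np.max(np.abs(np.linalg.norm(u, axis=1) - 1.0)) > 1e-6:
        raise ValueError("points must be unit 3-vectors")
    s_theta, s_sin = _pair_sums(u)
    A = n / 2.0 - (2.0 / (n * math.pi)) * s_theta
    G = n / 2.0 - (4.0 / (n * math.pi)) * s_sin
    F = A + G if normalization == "sum" else 2.0 * A + G
    return UniformityResult(n=n, A_n=float(A), G_n=float(G), F_star=float(F),
                            normalization=normalization)


def _batch_F(x: np.ndarray, normalization: str) -> np.ndarray:
    """Vectorized F* over a batch of point sets, shape (m, n, 3)."""
    m, n, _ = x.shape
    g = np.clip(np.einsum("mik,mjk->mij", x, x), -1.0, 1.0)
    k = np.arange(n)
    g[:, k, k] = 1.0  # exact zero self-angles (see _pair_sums)
    th = np.arccos(g)
    s_theta = 0.5 * th.sum(axis=(1, 2))
    s_sin = 0.5 * np.sin(th).sum(axis=(1, 2))
    A = n / 2.0 - (2.0 / (n * math.pi)) * s_theta
    G = n / 2.0 - (4.0 / (n * math.pi)) * s_sin
    return A + G if normalization == "sum" else 2.0 * A + G


def calibrate_null(n: int, reps: int, seed: int = 0,
                   normalization: str = "sum",
                   quantiles: tuple[float, ...] = (0.90, 0.95, 0.99),
                   ) -> CalibrationResult:
    """Monte-Carlo null distribution of F* from ``reps`` independent sets
    of ``n`` iid uniform directions.  Reproducible under a fixed seed."""
    if n < 10:
        raise ValueError("n must be >= 10")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    rng = np.random.default_rng(seed)
    values = np.empty(reps)
    chunk = max(1, int(2e7 // (n * n)))
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        x = rng.standard_normal((m, n, 3))
        x /= np.linalg.norm(x, axis=2, keepdims=True)
        values[done:done + m] = _batch_F(x, normalization)
        done += m
    pct = {q: float(np.quantile(values, q)) for q in quantiles}
    return CalibrationResult(n=n, reps=reps, mean=float(values.mean()),
                             percentiles=pct, normalization=normalization)


# ---------------------------------------------------------------------------
# equal-area sphere histogram


def sphere_histogram(points, n_rings: int = 12):
    """Counts of direction vectors over an equal-area partition of the
    sphere: latitude rings (widths chosen so ring area is proportional to
    its number of longitude cells) split into equal-angle longitude cells.

    Returns ``(counts, ratio)`` where ``counts`` is a list of per-ring count
    arrays and ``ratio`` the max/min cell density (inf if a cell is empty).
    """
    if n_rings < 2:
        raise ValueError("n_rings must be >= 2")
    u = np.atleast_2d(np.asarray(points, dtype=float))
    # provisional equal-area rings give the ring mid-latitudes used to set
    # the longitude cell counts proportional to the ring circumference
    z_mid = 1.0 - (2.0 * np.arange(n_rings) + 1.0) / n_rings
    m = np.maximum(1, np.round(2.0 * n_rings * np.sqrt(1.0 - z_mid ** 2))
                   ).astype(int)
    # ring area proportional to m_j <=> z-width proportional to m_j
    widths = 2.0 * m / m.sum()
    z_edges = np.concatenate([[1.0], 1.0 - np.cumsum(widths)])
    z_edges[-1] = -1.0
    z = np.clip(u[:, 2], -1.0, 1.0)
    ring = np.clip(np.searchsorted(-z_edges, -z, side="left") - 1,
                   0, n_rings - 1)
    phi = np.mod(np.arctan2(u[:, 1], u[:, 0]), 2.0 * math.pi)
    counts = []
    for j in range(n_rings):
        sel = ring == j
        cell = np.minimum((phi[sel] * m[j] / (2.0 * math.pi)).astype(int),
                          m[j] - 1)
        counts.append(np.bincount(cell, minlength=m[j]))
    flat = np.concatenate(counts).astype(float)
    ratio = float(flat.max() / flat.min()) if flat.min() > 0 else math.inf
    return counts, ratio


def sphere_cell_areas(n_rings: int = 12) -> np.ndarray:
    """Areas of the cells of :func:`sphere_histogram`'s partition (all
    equal by construction)."""
    z_mid = 1.0 - (2.0 * np.arange(n_rings) + 1.0) / n_rings
    m = np.maximum(1, np.round(2.0 * n_rings * np.sqrt(1.0 - z_mid ** 2))
                   ).astype(int)
    widths = 2.0 * m / m.sum()
    areas = []
    for j in range(n_rings):
        areas.extend([2.0 * math.pi * widths[j] / m[j]] * m[j])
    return np.array(areas)


# ---------------------------------------------------------------------------
# equality of treatment


def equality_report(traj: Trajectory, samples: list[SampleSpec],
                    decimate: int = 1) -> EqualityReport:
    """Per-sample RMS and peak apparent acceleration plus the mean residual
    gravity of the run.

    The gravity direction in the sample frame does not depend on the mount
    offset (the machine only rotates), so the residual-gravity column is
    common to all samples; the acceleration columns are offset-specific.
    """
    if not samples:
        raise ValueError("need at least one sample")
    from .planners import trajectory_to_direction_path
    path = trajectory_to_direction_path(traj, decimate)
    res = residual_gravity(path)
    mean_res = float(res.magnitude_g.mean())
    rms = np.empty(len(samples))
    peak = np.empty(len(samples))
    for i, s in enumerate(samples):
        a = point_kinematics(traj, s).acceleration
        mag2 = np.einsum("ij,ij->i", a, a)
        rms[i] = math.sqrt(float(mag2.mean()))
        peak[i] = math.sqrt(float(mag2.max()))
    return EqualityReport(
        offsets=np.array([s.offset_vector for s in samples]),
        rms_acceleration=rms, max_acceleration=peak,
        mean_residual_g=np.full(len(samples), mean_res))


# ---------------------------------------------------------------------------
# direction samplers (fixtures for calibration and partial-gravity tests)


def sample_uniform_sphere(n: int, seed: int = 0,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """n iid uniform unit vectors (normalized standard normals)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    x = rng.standard_normal((n, 3))
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def sample_vmf(mean_direction, kappa: float, n: int, seed: int = 0,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """n draws from the von Mises-Fisher distribution on the sphere.

    Standard inversion sampler for the polar angle; ``kappa = 0`` reduces
    to the uniform distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(seed) if rng is None else rng
    mu = np.asarray(mean_direction, dtype=float)
    mu = mu / np.linalg.norm(mu)
    v = rng.uniform(size=n)
    if kappa == 0.0:
        w = 2.0 * v - 1.0
    else:
        # stable inversion of the vMF polar CDF
        w = 1.0 + np.log(v + (1.0 - v) * np.exp(-2.0 * kappa)) / kappa
    w = np.clip(w, -1.0, 1.0)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    r = np.sqrt(np.maximum(0.0, 1.0 - w * w))
    local = np.stack([r * np.cos(phi), r * np.sin(phi), w], axis=-1)
    # rotate the pole (0,0,1) onto mu
    if mu[2] > 1.0 - 1e-12:
        return local
    if mu[2] < -1.0 + 1e-12:
        return local * np.array([1.0, -1.0, -1.0])
    axis = np.cross(np.array([0.0, 0.0, 1.0]), mu)
    axis /= np.linalg.norm(axis)
    ang = math.acos(np.clip(mu[2], -1.0, 1.0))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)
    return local @ R.T


def vmf_mean_resultant_length(kappa: float) -> float:
    """Mean resultant length A(kappa) = coth(kappa) - 1/kappa on the sphere."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if kappa == 0.0:
        return 0.0
    if kappa > 20.0:  # coth(k) ~ 1 to double precision well before this
        return 1.0 - 1.0 / kappa
    return 1.0 / math.tanh(kappa) - 1.0 / kappa


def vmf_kappa_for_mean_length(rho: float) -> float:
    """Concentration kappa whose vMF mean resultant length equals rho."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    if rho == 0.0:
        return 0.0
    return brentq(lambda k: vmf_mean_resultant_length(k) - rho,
                  1e-9, 1e6, xtol=1e-12, rtol=1e-12)
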