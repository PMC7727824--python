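"""Diagnostic figures: sphere coverage density, residual-gravity decay and
gimbal motion profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .kinematics import DirectionPath, ResidualGravitySeries, Trajectory


def plot_sphere_density(path: DirectionPath, out, bins: int = 36) -> None:
    """Equal-area density map of the direction path in (longitude, z)."""
    u = path.directions
    phi = np.degrees(np.arctan2(u[:, 1], u[:, 0]))
    z = u[:, 2]
    fig, ax = plt.subplots(figsize=(7, 4))
    h = ax.hist2d(phi, z, bins=[bins, bins // 2],
                  range=[[-180, 180], [-1, 1]], cmap="viridis")
    fig.colorbar(h[3], ax=ax, label="samples per equal-area cell")
    ax.set_xlabel("longitude (deg)")
    ax.set_ylabel("z component of gravity direction")
    ax.set_title("Gravity-direction path density on the sphere")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def plot_residual_curve(res: ResidualGravitySeries, out) -> None:
    """Decay of the running time-averaged gravity magnitude (units of g)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.semilogy(res.t, np.maximum(res.magnitude_g, 1e-12))
    ax.axhline(0.01, color="grey", ls="--", lw=0.8, label="0.01 g")
    ax.axhline(1e-3, color="grey", ls=":", lw=0.8, label="0.001 g")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("residual gravity (g)")
    ax.set_title("Gravity-vector nullification")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def plot_trajectory(traj: Trajectory, out) -> None:
    """Gimbal angles and rates over time."""
    fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    axes[0].plot(traj.t, np.degrees(traj.alpha), label="alpha (outer)")
    axes[0].plot(traj.t, np.degrees(traj.beta), label="beta (inner)")
    axes[0].set_ylabel("angle (deg)")
    axes[0].legend(loc="upper left")
    axes[1].plot(traj.t, np.degrees(traj.alpha_rate), label="alpha rate")
    axes[1].plot(traj.t, np.degrees(traj.beta_rate), label="beta rate")
    axes[1].set_ylabel("rate (deg/s)")
    axes[1].set_xlabel("time (s)")
    axes[1].legend(loc="upper left")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
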