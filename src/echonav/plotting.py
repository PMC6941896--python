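"""Trajectory and gain-curve figures (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np

from .acoustics import BinauralGainModel, EmissionModel, ear_directivity, emitter_directivity
from .environments import Environment
from .simulator import TrialResult

__all__ = ["plot_environment", "plot_trajectory", "export_gain_curves"]


def plot_environment(env: Environment, ax=None):
    """Draw walls, obstacle discs and the scatterer cloud."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    for w in env.walls:
        ax.plot([w.p0[0], w.p1[0]], [w.p0[1], w.p1[1]], "k-", lw=2)
    for o in env.obstacles:
        ax.add_patch(plt.Circle(o.center, o.scatter_radius, color="0.8"))
        ax.add_patch(plt.Circle(o.center, o.collision_radius, color="k"))
    xy = env.scatterer_xy
    if len(xy):
        ax.plot(xy[:, 0], xy[:, 1], ".", ms=1, color="0.5")
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax


def plot_trajectory(env: Environment, result: TrialResult, ax=None, head_every: int = 5):
    """Trajectory overlay: blue path, short red gaze ticks, green collision stars."""
    ax = plot_environment(env, ax)
    ax.plot(result.x, result.y, "b-", lw=1)
    # gaze direction ticks
    sel = np.arange(0, result.n_calls_executed, head_every)
    gaze = np.radians(result.theta[sel] + result.phi[sel])
    ax.quiver(
        result.x[sel],
        result.y[sel],
        np.cos(gaze),
        np.sin(gaze),
        color="r",
        scale=40,
        width=2e-3,
        headwidth=2,
    )
    for c in result.collisions:
        ax.plot(*c.position, "g*", ms=12)
    ax.set_title(f"{result.strategy}: {len(result.collisions)} collisions, {result.termination}")
    return ax


def export_gain_curves(
    path,
    emission: EmissionModel | None = None,
    ears: BinauralGainModel | None = None,
    step: float = 1.0,
) -> None:
    """Write the emitter and ear directivity curves over ±90° azimuth to CSV."""
    import pandas as pd

    emission = emission or EmissionModel()
    ears = ears or BinauralGainModel()
    az = np.arange(-90.0, 90.0 + step, step)
    pd.DataFrame(
        {
            "azimuth_deg": az,
            "emitter": emitter_directivity(az, emission),
            "ear_left": ear_directivity(az, "left", ears),
            "ear_right": ear_directivity(az, "right", ears),
        }
    ).to_csv(path, index=False)
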