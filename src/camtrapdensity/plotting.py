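"""Plots: simulated movement over the camera grid, and the per-tree
density prediction distribution behind an estimate."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_movement", "plot_tree_distribution"]


def plot_movement(trajectories, grid=None, ax=None, max_individuals=None):
    """One realisation of simulated movement, with camera positions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    shown = trajectories[:max_individuals] if max_individuals else trajectories
    for t in shown:
        ax.plot(t.positions[:, 0], t.positions[:, 1], lw=0.3, alpha=0.6)
    if grid is not None:
        pos = grid.positions()
        ax.scatter(pos[:, 0], pos[:, 1], marker="^", s=60, c="k",
                   zorder=5, label="cameras")
        ax.legend(loc="upper right")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    ax.set_title("Simulated movement")
    return ax


def plot_tree_distribution(results, ax=None):
    """Histogram + KDE of per-tree density predictions with CI markers."""
    import matplotlib.pyplot as plt
    from scipy import stats

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    e = results.estimate
    dens = np.asarray(e.tree_predictions) / e.effective_area_km2
    ax.hist(dens, bins=30, density=True, alpha=0.5, color="tab:blue")
    if dens.std() > 0:
        xs = np.linspace(dens.min(), dens.max(), 200)
        ax.plot(xs, stats.gaussian_kde(dens)(xs), c="tab:blue")
    ax.axvline(e.density, c="k", label=f"estimate {e.density:.2f}")
    ax.axvline(e.ci_low, c="k", ls="--",
               label=f"95% CI ({e.ci_low:.2f}, {e.ci_high:.2f})")
    ax.axvline(e.ci_high, c="k", ls="--")
    ax.set_xlabel("density (individuals/km²)")
    ax.set_ylabel("probability density")
    ax.set_title(f"{e.species} — {e.site}")
    ax.legend()
    return ax
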