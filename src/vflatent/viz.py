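"""Latent-space visualization: decoding a 2-D latent lattice into a mosaic."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import NormalizationSpec

__all__ = ["render_latent_grid", "save_mosaic_png"]

# Fixed dB colour range so exported heatmaps are comparable across runs.
DB_RANGE = (-38.0, 6.0)


def render_latent_grid(model, grid_range: tuple[float, float] = (-3.0, 3.0),
                       steps: int = 9) -> np.ndarray:
    """Decode a steps x steps lattice of 2-D latent points.

    Returns a (steps, steps, 12, 12) array of decoded mean images; panel
    [i, j] is the decoding of (z1 = grid[j], z2 = grid[i]) with z2 decreasing
    down the rows, so the mosaic reads like a scatter plot.  Requires a model
    with exactly two latent dimensions.
    """
    from . import vae as _vae
    if model.latent_dim != 2:
        raise ValueError(
            f"latent-grid rendering needs a 2-D latent space, got "
            f"L={model.latent_dim}; train a model with latent_dim=2")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    grid = np.linspace(grid_range[0], grid_range[1], steps)
    z = np.array([[g1, g2] for g2 in grid[::-1] for g1 in grid])
    panels = _vae.decode(model, z)
    return panels.reshape(steps, steps, 12, 12)


def save_mosaic_png(panels: np.ndarray, path: str | Path,
                    norm: NormalizationSpec = NormalizationSpec(),
                    trajectories: list[np.ndarray] | None = None) -> None:
    """Write the mosaic as a PNG heatmap on the fixed dB scale.

    ``trajectories`` optionally overlays encoded patient paths (each an
    n x 2 array of latent points in the same coordinates as the grid).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    steps = panels.shape[0]
    mosaic = panels.transpose(0, 2, 1, 3).reshape(steps * 12, steps * 12)
    mosaic_db = norm.denormalize(mosaic)
    fig, ax = plt.subplots(figsize=(8, 8))
    im = ax.imshow(mosaic_db, cmap="gray", vmin=DB_RANGE[0], vmax=DB_RANGE[1])
    fig.colorbar(im, ax=ax, label="total deviation (dB)")
    for s in range(1, steps):
        ax.axhline(s * 12 - 0.5, color="w", lw=0.5)
        ax.axvline(s * 12 - 0.5, color="w", lw=0.5)
    if trajectories:
        for traj in trajectories:
            traj = np.asarray(traj, dtype=float)
            ax.plot(_to_px(traj[:, 0], steps), _to_px(-traj[:, 1], steps),
                    "-o", ms=3, lw=1.2)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def _to_px(v: np.ndarray, steps: int, grid_range: tuple[float, float] = (-3.0, 3.0)) -> np.ndarray:
    frac = (v - grid_range[0]) / (grid_range[1] - grid_range[0])
    return frac * (steps * 12 - 1)
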