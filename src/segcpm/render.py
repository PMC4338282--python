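"""Snapshot and vector-field rendering (matplotlib).

Styles:

* ``segments`` — red/green cells shaded by segment label, cell boundaries
  darkened;
* ``gradient`` — gradient cells coloured by their protein-B concentration;
* displacement-vector overlays, optionally coloured by neighbour-angle
  coherence.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")  # noqa: E402 — headless rendering
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .params import GRADIENT, GREEN, MEDIUM, RED
from .state import WALL, SimState

__all__ = ["snapshot_rgb", "render_snapshot", "render_vectors"]

_RED_SHADES = np.array([[0.85, 0.15, 0.15], [0.95, 0.45, 0.35]])
_GREEN_SHADES = np.array([[0.15, 0.60, 0.20], [0.45, 0.80, 0.40]])


def _boundary_mask(sites: np.ndarray) -> np.ndarray:
    mask = np.zeros(sites.shape, dtype=bool)
    mask[:, 1:] |= sites[:, 1:] != sites[:, :-1]
    mask[1:, :] |= sites[1:, :] != sites[:-1, :]
    return mask & (sites > 0)


def snapshot_rgb(state: SimState) -> np.ndarray:
    """RGB image (H, W, 3) of the lattice: white medium, black walls,
    type/segment colouring for cells and darkened cell boundaries."""
    sites = state.sites
    img = np.ones(sites.shape + (3,), dtype=np.float64)
    img[sites == WALL] = 0.0
    cell_mask = sites > 0
    sigmas = sites[cell_mask]
    ctypes = state.ctype[sigmas]
    segs = np.maximum(state.segment[sigmas], 0)
    colors = np.ones((sigmas.size, 3))
    red = ctypes == RED
    green = ctypes == GREEN
    grad = ctypes == GRADIENT
    colors[red] = _RED_SHADES[segs[red] // 2 % 2]
    colors[green] = _GREEN_SHADES[(segs[green] - 1) // 2 % 2]
    if grad.any():
        cmap = plt.get_cmap("coolwarm")
        colors[grad] = cmap(state.conc_b[sigmas[grad]])[:, :3]
    img[cell_mask] = colors
    img[_boundary_mask(sites)] *= 0.55
    return img


def render_snapshot(state: SimState, path: str | Path | None = None,
                    ax: plt.Axes | None = None,
                    title: str | None = None) -> plt.Axes:
    """Draw (and optionally save) a label-image snapshot of the state."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(snapshot_rgb(state), origin="upper", interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def render_vectors(vectors: pd.DataFrame,
                   coherence: np.ndarray | None = None,
                   ax: plt.Axes | None = None,
                   path: str | Path | None = None) -> plt.Axes:
    """Quiver plot of per-cell displacement vectors (tail at the start
    position), optionally coloured by neighbour-angle coherence relative to
    its maximum."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    kwargs = dict(angles="xy", scale_units="xy", scale=1.0, width=0.004)
    if coherence is not None and np.any(np.isfinite(coherence)):
        vmax = np.nanmax(coherence)
        ax.quiver(vectors.x0, vectors.y0, vectors.dx, vectors.dy,
                  np.nan_to_num(coherence, nan=vmax) / (vmax or 1.0),
                  cmap="viridis", **kwargs)
    else:
        ax.quiver(vectors.x0, vectors.y0, vectors.dx, vectors.dy, **kwargs)
    ax.set_aspect("equal")
    ax.invert_yaxis()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
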