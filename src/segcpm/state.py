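"""Lattice + per-cell state in struct-of-arrays form.

The lattice is an integer label grid ``sites[y, x]`` holding the identity
(sigma) occupying each site: 0 is medium, positive integers are cells, and
``WALL = -1`` marks the immutable one-site frame around the field.  Per-cell
quantities live in flat arrays indexed by sigma (index 0 is a placeholder for
the medium) so the compiled kernel can update them incrementally.

Coordinates follow image convention: ``x`` is the column index, ``y`` the row
index; centroids are running means of occupied site coordinates, maintained
as coordinate sums ``sum_x``/``sum_y`` divided by the area.
"""

from __future__ import annotations

import numpy as np

from .errors import IntegrityError
from .params import MEDIUM

WALL = -1

#: Moore-8 neighbourhood offsets (dx, dy).
NEIGH_DX = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)
NEIGH_DY = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)


class SimState:
    """Full mutable simulation state: label lattice plus cell bookkeeping."""

    #: names of the per-cell arrays, in checkpoint order
    CELL_ARRAYS = ("area", "target_area", "ctype", "segment", "boundary_row",
                   "sum_x", "sum_y", "conc_b",
                   "tdir_x", "tdir_y", "anchor_x", "anchor_y")

    def __init__(self, height: int, width: int, n_cells: int) -> None:
        self.sites = np.zeros((height, width), dtype=np.int32)
        self.sites[0, :] = WALL
        self.sites[-1, :] = WALL
        self.sites[:, 0] = WALL
        self.sites[:, -1] = WALL
        n = n_cells + 1  # slot 0 = medium
        self.area = np.zeros(n, dtype=np.int64)
        self.target_area = np.zeros(n, dtype=np.int64)
        self.ctype = np.zeros(n, dtype=np.int8)
        self.segment = np.full(n, -1, dtype=np.int32)
        self.boundary_row = np.zeros(n, dtype=np.bool_)
        self.sum_x = np.zeros(n, dtype=np.float64)
        self.sum_y = np.zeros(n, dtype=np.float64)
        self.conc_b = np.full(n, np.nan, dtype=np.float64)
        self.tdir_x = np.full(n, np.nan, dtype=np.float64)
        self.tdir_y = np.full(n, np.nan, dtype=np.float64)
        self.anchor_x = np.full(n, np.nan, dtype=np.float64)
        self.anchor_y = np.full(n, np.nan, dtype=np.float64)
        self.mcs = 0

    # -- basic geometry ----------------------------------------------------

    @property
    def height(self) -> int:
        return self.sites.shape[0]

    @property
    def width(self) -> int:
        return self.sites.shape[1]

    @property
    def n_slots(self) -> int:
        """Number of sigma slots including the medium slot 0."""
        return self.area.shape[0]

    @property
    def wall_mask(self) -> np.ndarray:
        return self.sites == WALL

    def alive(self) -> np.ndarray:
        """Boolean mask over sigma slots: live cells (area > 0, sigma >= 1)."""
        mask = self.area > 0
        mask[MEDIUM] = False
        return mask

    @property
    def n_alive(self) -> int:
        return int(np.count_nonzero(self.alive()))

    def centroids(self) -> np.ndarray:
        """(n_slots, 2) array of (x, y) centroids; NaN for dead cells/medium."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.stack([self.sum_x / self.area, self.sum_y / self.area],
                           axis=1)
        out[~self.alive()] = np.nan
        return out

    def conc_a(self) -> np.ndarray:
        """Concentration of protein A (= 1 - B) for gradient cells."""
        return 1.0 - self.conc_b

    # -- bookkeeping -------------------------------------------------------

    def place_cell(self, sigma: int, y0: int, x0: int, size: int) -> None:
        """Stamp a ``size`` x ``size`` block of sites for cell ``sigma``."""
        block = self.sites[y0:y0 + size, x0:x0 + size]
        if block.shape != (size, size) or np.any(block != MEDIUM):
            raise IntegrityError(f"cannot place cell {sigma} at ({y0}, {x0})")
        block[...] = sigma
        ys, xs = np.mgrid[y0:y0 + size, x0:x0 + size]
        self.area[sigma] = size * size
        self.sum_x[sigma] = xs.sum()
        self.sum_y[sigma] = ys.sum()

    def recount(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Recount areas and coordinate sums from the lattice (ground truth)."""
        n = self.n_slots
        cells = self.sites.ravel()
        ys, xs = np.mgrid[0:self.height, 0:self.width]
        valid = cells >= 0
        area = np.bincount(cells[valid], minlength=n).astype(np.int64)
        sum_x = np.bincount(cells[valid], weights=xs.ravel()[valid], minlength=n)
        sum_y = np.bincount(cells[valid], weights=ys.ravel()[valid], minlength=n)
        return area, sum_x, sum_y

    def validate(self) -> None:
        """Raise :class:`IntegrityError` if bookkeeping disagrees with the lattice."""
        area, sum_x, sum_y = self.recount()
        if np.any(area[1:] != self.area[1:]):
            bad = np.nonzero(area[1:] != self.area[1:])[0] + 1
            raise IntegrityError(f"stored areas disagree with lattice for cells {bad}")
        live = self.alive()
        if not (np.allclose(sum_x[live], self.sum_x[live])
                and np.allclose(sum_y[live], self.sum_y[live])):
            raise IntegrityError("stored centroid sums disagree with lattice")
        n_wall = int(self.wall_mask.sum())
        expected_wall = 2 * self.height + 2 * self.width - 4
        if n_wall != expected_wall:
            raise IntegrityError("wall frame was modified")
        if np.any(self.sites >= self.n_slots):
            raise IntegrityError("lattice holds an unknown cell identity")

    def resync(self) -> None:
        """Recompute area/centroid bookkeeping from the lattice."""
        self.area, self.sum_x, self.sum_y = self.recount()
        self.area[MEDIUM] = 0
        self.sum_x[MEDIUM] = 0.0
        self.sum_y[MEDIUM] = 0.0

    def copy(self) -> "SimState":
        out = SimState.__new__(SimState)
        out.sites = self.sites.copy()
        for name in self.CELL_ARRAYS:
            setattr(out, name, getattr(self, name).copy())
        out.mcs = self.mcs
        return out
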