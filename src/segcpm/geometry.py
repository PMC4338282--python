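"""Initial tissue construction.

Cells are seeded as 5x5 blocks of lattice sites packed contiguously into a
grid of ``n_segments * segment_rows`` rows by ``segment_cols`` columns,
centred in the field (or abutting the top wall for the anterior-blocked
layout).  Segments are stacked along the y-axis, so the tissue's
antero-posterior axis is vertical.  Each cell starts at 25 sites with the
configured target area and inflates under the area constraint during the
first MCS of a run — which is why measurements start after an inflation
period.

Patterns:

* ``segments`` — alternating red/green segment types by segment index;
* ``gradient_sorted`` — all cells carry two opposing protein concentrations,
  with B stepped linearly from 0 to 1 row by row;
* ``gradient_random`` — B drawn uniformly per cell (the "mixed tissue"
  sorting experiment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .params import GRADIENT, GREEN, RED
from .state import SimState

__all__ = ["TissueSpec", "build_tissue", "build_segmented_tissue",
           "build_gradient_tissue", "suggest_field"]

PATTERNS = ("segments", "gradient_sorted", "gradient_random")
LAYOUTS = ("free", "anterior_blocked")


@dataclass
class TissueSpec:
    """Geometry and identity layout of the initial tissue.

    n_segments : number of segments stacked along y
    segment_rows, segment_cols : cells per segment (thickness x width)
    cell_block : linear size of the seed block per cell (5 sites)
    cell_target_area : target area A in sites (500, or 200 for runs with
        persistence / desk-scale runs)
    """

    n_segments: int = 4
    segment_rows: int = 3
    segment_cols: int = 10
    cell_block: int = 5
    cell_target_area: int = 500
    pattern: str = "segments"
    layout: str = "free"

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ConfigurationError(f"pattern must be one of {PATTERNS}")
        if self.layout not in LAYOUTS:
            raise ConfigurationError(f"layout must be one of {LAYOUTS}")
        for name in ("n_segments", "segment_rows", "segment_cols",
                     "cell_block", "cell_target_area"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.pattern == "gradient_sorted" and self.n_rows < 2:
            raise ConfigurationError(
                "a sorted gradient needs at least 2 cell rows")

    @property
    def n_rows(self) -> int:
        return self.n_segments * self.segment_rows

    @property
    def n_cols(self) -> int:
        return self.segment_cols

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


def suggest_field(spec: TissueSpec, expected_fold: float = 2.0,
                  margin: float = 0.25) -> tuple[int, int]:
    """Pick a field size (height, width) that leaves at least ``margin``
    relative clearance around the inflated tissue, with ``expected_fold``
    headroom for elongation along y."""
    side = math.sqrt(spec.cell_target_area)
    w_inf = spec.n_cols * side
    h_inf = spec.n_rows * side
    width = int(math.ceil(w_inf * (1 + 2 * margin)))
    height = int(math.ceil(h_inf * expected_fold * (1 + margin)))
    width = max(width, spec.n_cols * spec.cell_block + 4)
    height = max(height, spec.n_rows * spec.cell_block + 4)
    return height, width


def build_tissue(spec: TissueSpec, field: tuple[int, int] | None = None,
                 rng: np.random.Generator | int | None = None) -> SimState:
    """Build the initial state for ``spec`` on a field of (height, width)
    sites (auto-sized when omitted)."""
    if field is None:
        field = suggest_field(spec)
    height, width = field
    block = spec.cell_block
    rows, cols = spec.n_rows, spec.n_cols
    if spec.layout == "anterior_blocked":
        y0 = 1
    else:
        y0 = (height - rows * block) // 2
    x0 = (width - cols * block) // 2
    if y0 < 1 or x0 < 1 or (y0 + rows * block) > height - 1 \
            or (x0 + cols * block) > width - 1:
        raise ConfigurationError(
            f"initial {rows}x{cols}-cell footprint does not fit a "
            f"{height}x{width} field inside the wall frame")

    state = SimState(height, width, spec.n_cells)
    for row in range(rows):
        for col in range(cols):
            sigma = row * cols + col + 1
            state.place_cell(sigma, y0 + row * block, x0 + col * block, block)
            state.target_area[sigma] = spec.cell_target_area
            if spec.pattern == "segments":
                seg = row // spec.segment_rows
                state.segment[sigma] = seg
                state.ctype[sigma] = RED if seg % 2 == 0 else GREEN
                in_row = row % spec.segment_rows
                state.boundary_row[sigma] = (
                    (in_row == 0 and seg > 0)
                    or (in_row == spec.segment_rows - 1
                        and seg < spec.n_segments - 1))
            else:
                state.segment[sigma] = -1
                state.ctype[sigma] = GRADIENT

    if spec.pattern == "gradient_sorted":
        for row in range(rows):
            b = row / (rows - 1)
            for col in range(cols):
                state.conc_b[row * cols + col + 1] = b
    elif spec.pattern == "gradient_random":
        gen = rng if isinstance(rng, np.random.Generator) \
            else np.random.default_rng(rng)
        state.conc_b[1:] = gen.uniform(0.0, 1.0, size=spec.n_cells)
    return state


def build_segmented_tissue(spec: TissueSpec,
                           field: tuple[int, int] | None = None) -> SimState:
    """Alternating red/green segmented tissue (pattern ``segments``)."""
    if spec.pattern != "segments":
        raise ConfigurationError("build_segmented_tissue needs pattern='segments'")
    return build_tissue(spec, field)


def build_gradient_tissue(spec: TissueSpec,
                          field: tuple[int, int] | None = None,
                          rng: np.random.Generator | int | None = None
                          ) -> SimState:
    """Opposing-gradient tissue (pattern ``gradient_sorted`` or
    ``gradient_random``)."""
    if not spec.pattern.startswith("gradient"):
        raise ConfigurationError("build_gradient_tissue needs a gradient pattern")
    return build_tissue(spec, field, rng)
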