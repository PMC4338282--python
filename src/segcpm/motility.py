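"""Persistent cell motion.

Cells carry a unit *target direction*; copy attempts that extend a cell at
angle ``zeta`` to its target direction have their energy change biased to
``dH' = dH - mu * cos(zeta)``, so extensions along the recent direction of
travel are favoured.  Every ``s`` MCS the target direction is replaced by the
unit vector of the cell's actual displacement since the previous update,
which makes an isolated cell perform a persistent random walk.

The compiled kernel applies the bias and the periodic updates natively
during a run; the functions here are the reference implementations used by
the engine at activation time and by the test-suite.
"""

from __future__ import annotations

import math

import numpy as np

from .params import MEDIUM, Persistence
from .state import SimState

__all__ = ["persistence_bias", "update_target_directions",
           "init_target_directions"]


def persistence_bias(dH: float, mu: float, zeta: float) -> float:
    """Biased energy change ``dH - mu * cos(zeta)`` for an extension whose
    direction makes angle ``zeta`` with the cell's target direction.

    ``mu`` here is an energy; the engine evaluates it as
    ``Persistence.mu * T`` so that the documented dimensionless ``mu`` range
    biases the acceptance exponent directly (see :class:`~segcpm.params.Persistence`).
    """
    return dH - mu * math.cos(zeta)


def init_target_directions(state: SimState, rng: np.random.Generator) -> None:
    """Give every live cell an independent uniform random unit target
    direction and anchor its displacement reference at the current centroid.

    Called once when persistence activates (at the end of the initialization
    period).  The medium never has a target direction.
    """
    alive = state.alive()
    n = state.n_slots
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    state.tdir_x[alive] = np.cos(theta[alive])
    state.tdir_y[alive] = np.sin(theta[alive])
    cents = state.centroids()
    state.anchor_x[alive] = cents[alive, 0]
    state.anchor_y[alive] = cents[alive, 1]


def update_target_directions(state: SimState, mcs: int,
                             params: Persistence) -> None:
    """At every MCS multiple of ``s``, point each live cell's target
    direction along its displacement since the last update and reset the
    anchor; zero displacement leaves the target direction unchanged."""
    if mcs % params.s != 0:
        return
    for sigma in range(1, state.n_slots):
        if state.area[sigma] <= 0 or state.ctype[sigma] == MEDIUM:
            continue
        cx = state.sum_x[sigma] / state.area[sigma]
        cy = state.sum_y[sigma] / state.area[sigma]
        dx = cx - state.anchor_x[sigma]
        dy = cy - state.anchor_y[sigma]
        norm = math.hypot(dx, dy)
        if norm > 0.0:
            state.tdir_x[sigma] = dx / norm
            state.tdir_y[sigma] = dy / norm
        state.anchor_x[sigma] = cx
        state.anchor_y[sigma] = cy
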