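"""Energy functions: total Hamiltonian, incremental energy change, and the
Metropolis acceptance rule.

The Hamiltonian is the sum of contact energies J over all unordered
heterologous Moore-8 neighbour pairs plus the quadratic area constraint
``lambda_a * (a - A)^2`` summed over live cells (the medium carries no area
term).  :func:`hamiltonian_total` is a deliberately simple from-scratch
implementation used as the reference against the compiled incremental
:func:`delta_H`.

The graded and axial mechanisms bias individual copy attempts and do not
define a global pair potential (their J modification depends on which site of
a pair is the copy target), so the total energy is only defined for the plain
table and for the opposing-gradient mechanism, whose modification is a
symmetric function of the two cells.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernel
from .adhesion import Mechanism, effective_pair_J, kernel_mechanism_args
from .errors import ConfigurationError, ContractViolation
from .params import AdhesionTable, AxialAdhesion, GradedAdhesion
from .state import NEIGH_DX, NEIGH_DY, WALL, SimState

__all__ = ["acceptance_probability", "hamiltonian_total", "delta_H"]


def acceptance_probability(dH: float, T: float) -> float:
    """Metropolis acceptance: 1 if ``dH < 0`` else ``exp(-dH / T)``
    (so ``dH == 0`` is accepted with probability 1)."""
    if T <= 0:
        raise ConfigurationError("temperature must be > 0")
    if dH < 0:
        return 1.0
    return math.exp(-dH / T)


def hamiltonian_total(state: SimState, table: AdhesionTable,
                      lambda_area: float = 1.0,
                      mechanism: Mechanism = None) -> float:
    """Total energy of a state, recomputed from scratch.

    Intended for validation on small lattices; it walks every unordered
    neighbour pair in Python.  Raises :class:`IntegrityError` if the stored
    per-cell areas disagree with the lattice, and
    :class:`ConfigurationError` for mechanisms without a global potential
    (graded, axial).
    """
    if isinstance(mechanism, (GradedAdhesion, AxialAdhesion)):
        raise ConfigurationError(
            "graded/axial adhesion bias copy attempts and have no global "
            "potential; hamiltonian_total is undefined for them")
    state.validate()
    sites = state.sites
    height, width = sites.shape
    energy = 0.0
    # forward half of the Moore-8 neighbourhood: each unordered pair once
    forward = [(1, 0), (0, 1), (1, 1), (-1, 1)]
    for y in range(height):
        for x in range(width):
            sa = sites[y, x]
            if sa == WALL:
                continue
            for dx, dy in forward:
                nx, ny = x + dx, y + dy
                if not (0 <= nx < width and 0 <= ny < height):
                    continue
                sb = sites[ny, nx]
                if sb == WALL or sb == sa:
                    continue
                energy += effective_pair_J(table, state, int(sa), int(sb),
                                           x, y, mechanism)
    live = state.alive()
    diff = (state.area[live] - state.target_area[live]).astype(np.float64)
    energy += lambda_area * float(np.sum(diff ** 2))
    return energy


def delta_H(state: SimState, table: AdhesionTable,
            target_site: tuple[int, int], source_site: tuple[int, int],
            lambda_area: float = 1.0, mechanism: Mechanism = None) -> float:
    """Exact energy change of copying the identity at ``source_site`` into
    ``target_site`` (both ``(x, y)``), computed incrementally: only the 8
    contact pairs touching the target site and the two area terms change.

    Mechanism modifications are evaluated at the target site, exactly as the
    simulation kernel does during a run.
    """
    tx, ty = target_site
    sx, sy = source_site
    if (abs(tx - sx) > 1 or abs(ty - sy) > 1 or
            not any(tx + dx == sx and ty + dy == sy
                    for dx, dy in zip(NEIGH_DX, NEIGH_DY))):
        raise ContractViolation("source must be a Moore-8 neighbour of target")
    sig_t = int(state.sites[ty, tx])
    sig_s = int(state.sites[sy, sx])
    if sig_t == WALL or sig_s == WALL:
        raise ContractViolation("wall sites take no part in copy attempts")
    if sig_t == sig_s:
        raise ContractViolation("copy between identical identities is a null move")
    mech, gauss_col, beta, mm = kernel_mechanism_args(mechanism, state.width)
    return float(_kernel.delta_h(
        state.sites, tx, ty, sig_s, table.matrix, state.ctype,
        state.area, state.target_area, state.sum_x, state.sum_y,
        state.conc_b, float(lambda_area), mech, gauss_col, beta, mm))
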