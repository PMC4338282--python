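"""Contact-energy evaluation: J tables, surface tensions and the three
position/state-dependent J-modification mechanisms.

All three mechanisms *reduce* the base contact energy (stronger adhesion) of
cell–cell contacts only; cell–medium energies are never modified:

* graded adhesion — a static Gaussian in the field x-coordinate, so contacts
  near the x-centre of the field are stronger;
* axial adhesion — contacts on the top/bottom faces of cells are stronger,
  through the factor ``|sin(alpha)| * |sin(alpha')|`` of the angles the two
  centroid-to-contact vectors make with the x-axis;
* opposing protein gradients — two proteins A and B with ``A + B = 1``; the
  cell with the lower concentration of a protein limits the bond strength
  contributed by that protein.

At most one of these mechanisms may be active in a simulation.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernel
from .errors import ConfigurationError, ContractViolation
from .params import (AdhesionTable, AxialAdhesion, GradedAdhesion,
                     GradientAdhesion, surface_tension)

__all__ = [
    "surface_tension", "graded_J", "axial_J", "gradient_J",
    "gaussian_profile", "kernel_mechanism_args",
]


def graded_J(J_base: float, x: float, params: GradedAdhesion) -> float:
    """Effective J of a cell–cell contact at field x-coordinate ``x``:
    ``J' = J - w * exp(-(x - b)^2 / (2 c^2))``."""
    if params.b is None:
        raise ContractViolation("graded adhesion: peak position b is unresolved"
                                " (set b or build the profile from a lattice)")
    return J_base - params.w * math.exp(-((x - params.b) ** 2)
                                        / (2.0 * params.c ** 2))


def axial_J(J_base: float, alpha: float, alpha_prime: float,
            params: AxialAdhesion) -> float:
    """Effective J of a cell–cell contact whose centroid-to-contact vectors
    make angles ``alpha``/``alpha_prime`` with the field x-axis:
    ``J' = J - (beta/2) * |sin(alpha)| * |sin(alpha')|``."""
    return J_base - 0.5 * params.beta * abs(math.sin(alpha)) * abs(math.sin(alpha_prime))


def gradient_J(J_base: float, conc_b_i: float, conc_b_j: float,
               params: GradientAdhesion) -> float:
    """Effective J between two gradient cells with protein-B concentrations
    ``conc_b_i``/``conc_b_j`` (A = 1 - B):
    ``J' = J - mm * (min(A_i, A_j) + min(B_i, B_j))``."""
    for b in (conc_b_i, conc_b_j):
        if not (isinstance(b, (int, float)) and 0.0 <= b <= 1.0):
            raise ContractViolation(f"gradient adhesion needs B in [0, 1], got {b!r}")
    return J_base - params.mm * (min(1.0 - conc_b_i, 1.0 - conc_b_j)
                                 + min(conc_b_i, conc_b_j))


def gaussian_profile(width: int, params: GradedAdhesion) -> np.ndarray:
    """Per-column J reduction ``w * exp(-(x-b)^2 / (2c^2))`` for a lattice of
    the given width; ``b`` defaults to the field x-centre."""
    b = (width - 1) / 2.0 if params.b is None else params.b
    x = np.arange(width, dtype=np.float64)
    return params.w * np.exp(-((x - b) ** 2) / (2.0 * params.c ** 2))


Mechanism = GradedAdhesion | AxialAdhesion | GradientAdhesion | None


def kernel_mechanism_args(mechanism: Mechanism, width: int):
    """Translate a mechanism parameter object into the scalar/array arguments
    of the compiled kernel: ``(code, gauss_col, beta, mm)``."""
    gauss = np.zeros(width, dtype=np.float64)
    if mechanism is None:
        return _kernel.MECH_NONE, gauss, 0.0, 0.0
    if isinstance(mechanism, GradedAdhesion):
        return _kernel.MECH_GRADED, gaussian_profile(width, mechanism), 0.0, 0.0
    if isinstance(mechanism, AxialAdhesion):
        return _kernel.MECH_AXIAL, gauss, float(mechanism.beta), 0.0
    if isinstance(mechanism, GradientAdhesion):
        return _kernel.MECH_GRADIENT, gauss, 0.0, float(mechanism.mm)
    raise ConfigurationError(f"unknown adhesion mechanism: {mechanism!r}")


def effective_pair_J(table: AdhesionTable, state, sig_a: int, sig_b: int,
                     x: float, y: float, mechanism: Mechanism = None) -> float:
    """Reference (pure-Python) effective J for the contact between the cells
    holding ``sig_a`` and ``sig_b``, evaluated at site ``(x, y)``.

    Mirrors the compiled kernel and is used by the from-scratch Hamiltonian;
    kept independent of the kernel implementation.
    """
    J = table.J(state.ctype[sig_a], state.ctype[sig_b])
    if sig_a == 0 or sig_b == 0:
        return J
    if mechanism is None:
        return J
    if isinstance(mechanism, GradedAdhesion):
        params = mechanism
        if params.b is None:
            params = GradedAdhesion(w=params.w, c=params.c,
                                    b=(state.width - 1) / 2.0)
        return graded_J(J, x, params)
    if isinstance(mechanism, AxialAdhesion):
        va = (x - state.sum_x[sig_a] / state.area[sig_a],
              y - state.sum_y[sig_a] / state.area[sig_a])
        vb = (x - state.sum_x[sig_b] / state.area[sig_b],
              y - state.sum_y[sig_b] / state.area[sig_b])
        if math.hypot(*va) == 0.0 or math.hypot(*vb) == 0.0:
            return J
        alpha = math.atan2(va[1], va[0])
        alpha_p = math.atan2(vb[1], vb[0])
        return axial_J(J, alpha, alpha_p, mechanism)
    if isinstance(mechanism, GradientAdhesion):
        b_i, b_j = state.conc_b[sig_a], state.conc_b[sig_b]
        if math.isnan(b_i) or math.isnan(b_j):
            raise ContractViolation(
                "gradient adhesion on cells without protein concentrations")
        return gradient_J(J, b_i, b_j, mechanism)
    raise ConfigurationError(f"unknown adhesion mechanism: {mechanism!r}")
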