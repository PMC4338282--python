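"""Parameter containers: adhesion tables, mechanism parameters, run configuration.

Cell types are encoded as small integers so that the compiled kernel can index
the adhesion table directly:

* ``MEDIUM = 0`` — the passive surrounding medium (identity 0 on the lattice),
* ``RED = 1`` / ``GREEN = 2`` — the two alternating segment identities,
* ``GRADIENT = 3`` — cells carrying the two opposing adhesion-protein
  concentrations ``A`` and ``B`` (with ``A + B = 1``).

Adhesion is parameterised by contact energies ``J`` per unit boundary length;
*lower* J means *stronger* adhesion.  The behaviour of a J table is best read
through surface tensions ``gamma_ij = J_ij - (J_ii + J_jj) / 2``: a positive
red–green tension demixes the segment types, a positive cell–medium tension
keeps the tissue compact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

MEDIUM = 0
RED = 1
GREEN = 2
GRADIENT = 3

N_TYPES = 4

TYPE_NAMES = {MEDIUM: "medium", RED: "red", GREEN: "green", GRADIENT: "gradient"}
_NAME_TO_TYPE = {v: k for k, v in TYPE_NAMES.items()}


def surface_tension(J_ij: float, J_ii: float, J_jj: float) -> float:
    """Surface tension between two types: ``gamma = J_ij - (J_ii + J_jj)/2``.

    For a cell–medium contact pass ``J_jj = 0`` (the medium self-energy is
    zero by convention).
    """
    return J_ij - 0.5 * (J_ii + J_jj)


class AdhesionTable:
    """Symmetric table of contact energies J keyed by cell-type pair.

    Parameters
    ----------
    J : mapping of (type, type) -> float
        Types may be integer codes or the names ``"medium"``, ``"red"``,
        ``"green"``, ``"gradient"``.  Missing pairs default to 0.  The
        medium–medium entry is fixed at 0 and may not be overridden.
    """

    def __init__(self, J: dict | None = None) -> None:
        self.matrix = np.zeros((N_TYPES, N_TYPES), dtype=np.float64)
        if J:
            for (a, b), value in J.items():
                i = _NAME_TO_TYPE.get(a, a)
                j = _NAME_TO_TYPE.get(b, b)
                if not (0 <= i < N_TYPES and 0 <= j < N_TYPES):
                    raise ConfigurationError(f"unknown cell type in J table: {(a, b)}")
                if i == MEDIUM and j == MEDIUM and value != 0:
                    raise ConfigurationError("J(medium, medium) is fixed at 0")
                if not np.isfinite(value):
                    raise ConfigurationError(f"J{(a, b)} must be finite")
                self.matrix[i, j] = value
                self.matrix[j, i] = value

    def J(self, i: int, j: int) -> float:
        return float(self.matrix[i, j])

    def gamma(self, i: int, j: int) -> float:
        """Surface tension between types ``i`` and ``j``."""
        m = self.matrix
        return surface_tension(m[i, j], m[i, i], m[j, j])

    # -- constructors for the standard experimental tables -----------------

    @classmethod
    def segmented(cls, J_cm: float, J_rr: float, J_rg: float,
                  J_gg: float | None = None) -> "AdhesionTable":
        """Red/green segmented tissue with equal cell–medium energies."""
        if J_gg is None:
            J_gg = J_rr
        return cls({
            (MEDIUM, RED): J_cm, (MEDIUM, GREEN): J_cm,
            (RED, RED): J_rr, (GREEN, GREEN): J_gg, (RED, GREEN): J_rg,
        })

    @classmethod
    def from_tensions(cls, gamma_rg: float, gamma_cm: float,
                      J_rr: float = 8.0) -> "AdhesionTable":
        """Solve a segmented J table from requested surface tensions.

        With ``J_mm = 0`` and ``J_gg = J_rr`` the system is underdetermined;
        the caller fixes ``J_rr`` and the remaining values follow:
        ``J_cm = gamma_cm + J_rr/2`` and ``J_rg = gamma_rg + J_rr``.
        """
        J_cm = gamma_cm + J_rr / 2.0
        J_rg = gamma_rg + J_rr
        return cls.segmented(J_cm=J_cm, J_rr=J_rr, J_rg=J_rg)

    @classmethod
    def uniform(cls, J_cm: float, J_cc: float) -> "AdhesionTable":
        """No segment-specific adhesion: every cell–cell contact costs J_cc."""
        return cls.segmented(J_cm=J_cm, J_rr=J_cc, J_rg=J_cc)

    @classmethod
    def gradient_tissue(cls, J_cm: float, J_max: float) -> "AdhesionTable":
        """Opposing-gradient tissue: ``J_max`` is the unreduced cell–cell energy."""
        return cls({(MEDIUM, GRADIENT): J_cm, (GRADIENT, GRADIENT): J_max})

    def __repr__(self) -> str:  # pragma: no cover
        return f"AdhesionTable({self.matrix!r})"


@dataclass
class GradedAdhesion:
    """Gaussian strengthening of cell–cell adhesion around the field x-centre.

    The effective contact energy of two adjacent cells becomes
    ``J' = J - w * exp(-(x - b)^2 / (2 c^2))`` where ``x`` is the x-coordinate
    of the copy-attempt target site.  Cell–medium contacts are unmodified.

    w : maximum J reduction (energy), default 11
    b : x-coordinate of the Gaussian peak (field centre); resolved from the
        lattice width at run time when ``None``
    c : standard deviation in lattice sites, default 7
    """

    w: float = 11.0
    c: float = 7.0
    b: float | None = None

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ConfigurationError("graded adhesion: w must be >= 0")
        if self.c <= 0:
            raise ConfigurationError("graded adhesion: c must be > 0")


@dataclass
class AxialAdhesion:
    """Orientation-dependent adhesion: the top and bottom faces of every cell
    adhere more strongly than the lateral faces.

    ``J' = J - (beta/2) * |sin(alpha)| * |sin(alpha')|`` where ``alpha`` and
    ``alpha'`` are the angles with the field x-axis of the vectors from the
    two cells' centroids to the membrane site of the copy attempt.
    """

    beta: float = 2.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ConfigurationError("axial adhesion: beta must be >= 0")


@dataclass
class GradientAdhesion:
    """Adhesion from two opposing protein gradients A and B (A + B = 1).

    The lower of the two cells' concentrations of each protein sets the bond
    strength contributed by that protein:
    ``J' = J - mm * (min(A_i, A_j) + min(B_i, B_j))``.
    ``mm`` is the maximum reduction, reached by identical cells.
    """

    mm: float = 18.0

    def __post_init__(self) -> None:
        if self.mm < 0:
            raise ConfigurationError("gradient adhesion: mm must be >= 0")


@dataclass
class Persistence:
    """Persistent-motion bias.

    Copy attempts that extend a cell at angle ``zeta`` to its target
    direction are biased by ``mu * cos(zeta)`` *on the scale of the
    simulation temperature*: the acceptance probability becomes
    ``exp(-dH / T + mu * cos(zeta))``, i.e. the energy change is biased by
    ``dH' = dH - mu * T * cos(zeta)``.  ``mu`` is therefore dimensionless.
    Every ``s`` MCS the target direction is replaced by the direction of the
    cell's actual displacement since the previous update.

    A bias expressed in plain energy units at ``mu <= 2.5`` against ``T = 15``
    would shift acceptance odds by under 20% per attempt and produces no
    measurable persistence (cell speeds become independent of ``mu``); on the
    temperature scale the documented ``mu`` range reproduces the emergent
    speeds this mechanism is known for.

    mu : bias strength (units of T); 0.5–2.0 in the validated envelope
         (up to 2.5 in stiff tissues)
    s : update interval in MCS (5–40)
    bias_retraction : also bias the cell losing the site (retraction against
        its target direction is favoured), as in the lymphocyte-migration
        implementations this mechanism derives from.  On by default; set
        False to bias only the extending cell.
    """

    mu: float = 0.5
    s: int = 5
    bias_retraction: bool = True

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ConfigurationError("persistence: mu must be >= 0")
        if self.s < 1:
            raise ConfigurationError("persistence: s must be >= 1")


@dataclass
class SimConfig:
    """Run-level parameters (defaults are the standard parameter set).

    temperature : Metropolis temperature T controlling membrane fluctuation
        amplitude (default 15)
    lambda_area : area-constraint stiffness per site^2 (default 1)
    duration : total run length in MCS, including the initialization period
    init_period : MCS during which persistence and measurement are suspended
        while cells inflate from their 5x5 seeds (default 500)
    measurement_interval : cadence of centroid/shape sampling in MCS
        (default 1000)
    seed : integer seed for the single RNG stream driving the run
    """

    duration: int = 500_000
    temperature: float = 15.0
    lambda_area: float = 1.0
    init_period: int = 500
    measurement_interval: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be > 0")
        if self.lambda_area < 0:
            raise ConfigurationError("lambda_area must be >= 0")
        if not (self.duration > self.init_period >= 0):
            raise ConfigurationError("need duration > init_period >= 0")
        if self.measurement_interval < 1:
            raise ConfigurationError("measurement_interval must be >= 1")
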