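"""Pairwise force laws of the IMC model.

Every pair of cells within reach interacts through a linear adhesive
spring (active out to an extra reach ``epsilon`` beyond contact) and a
cubic repulsive contact force.  Migratory (border) cells additionally
push off non-motile substrate cells in the direction of the
chemoattractant gradient projected perpendicular to the contact axis,
and every cell feels a small Gaussian stochastic force.

Sign convention: the unit vector ``d_hat`` points from cell *i* to cell
*j*; adhesion acts on *i* along ``+d_hat`` (attractive) and repulsion
along ``-d_hat``.  All deterministic pair forces are antisymmetric under
exchange of *i* and *j*.

This module provides a clear per-pair reference implementation operating
on :class:`~imcsim.core_model.IMCState` objects; the integrator uses a
vectorised path (:mod:`imcsim.integrator`) that is tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_model import CellType, ForceParameters, GradientField, IMCState

__all__ = [
    "PairGeometry",
    "DegenerateGeometryError",
    "MIGRATORY_SUBSTRATE_TYPES",
    "overlap",
    "pair_geometry",
    "adhesion_force",
    "repulsion_force",
    "migratory_sign",
    "migratory_force",
    "stochastic_force",
    "net_force",
]

#: cell roles a border cell may push off when the restricted eligibility
#: rule is in effect (the default): the fixed/non-motile substrate, but
#: not the polar cells it carries.
MIGRATORY_SUBSTRATE_TYPES = frozenset(
    {CellType.NURSE, CellType.EPITHELIAL, CellType.OOCYTE_SURFACE}
)

#: separations below this are treated as coincident centres.
COINCIDENT_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when two cell centres (nearly) coincide."""


@dataclass(frozen=True)
class PairGeometry:
    """Geometry of one interacting pair.

    ``separation`` is the centre-to-centre distance ``r`` in units of D,
    ``direction`` the unit vector from i toward j, and ``reach`` the
    adhesive reach ``epsilon`` used to compute the extended overlap.
    """

    separation: float
    direction: np.ndarray
    reach: float = 0.0

    @property
    def overlap(self) -> float:
        """Extended overlap ``(1 + epsilon) - r`` (may be negative)."""
        return (1.0 + self.reach) - self.separation

    @property
    def contact_overlap(self) -> float:
        """Contact overlap ``1 - r`` (reach 0)."""
        return 1.0 - self.separation


def overlap(r: float, reach: float = 0.0) -> float:
    """Extended overlap ``(1 + reach) - r`` of two unit-diameter cells.

    Negative values mean the cells are out of reach; callers gate with
    the Heaviside function.  ``r <= 0`` is a degenerate geometry.
    """
    if r <= 0:
        raise DegenerateGeometryError(f"non-positive separation r={r}")
    return (1.0 + reach) - r


def pair_geometry(u_i: np.ndarray, u_j: np.ndarray, reach: float = 0.0) -> PairGeometry:
    """Build the :class:`PairGeometry` for centres ``u_i`` and ``u_j``."""
    u_i = np.asarray(u_i, dtype=float)
    u_j = np.asarray(u_j, dtype=float)
    delta = u_j - u_i
    r = float(np.linalg.norm(delta))
    if r < COINCIDENT_TOL:
        raise DegenerateGeometryError(f"coincident centres (separation {r})")
    return PairGeometry(separation=r, direction=delta / r, reach=reach)


def adhesion_force(geom: PairGeometry, coeff: float) -> np.ndarray:
    """Adhesive force on *i* from *j*: linear in the extended overlap.

    Zero beyond reach (Heaviside gate); otherwise magnitude
    ``coeff * overlap`` directed toward *j*.
    """
    if coeff < 0:
        raise ValueError("adhesion coefficient must be >= 0")
    rho = geom.overlap
    if rho <= 0:
        return np.zeros_like(geom.direction)
    return coeff * rho * geom.direction


def repulsion_force(geom: PairGeometry, c_r: float) -> np.ndarray:
    """Repulsive contact force on *i* from *j*: cubic in the overlap.

    Zero unless the cells actually overlap (``r < 1``); otherwise
    magnitude ``c_r * (1 - r)**3`` directed away from *j*.  The cubic
    law vanishes continuously at contact and stiffens as cells are
    squeezed.
    """
    if c_r < 0:
        raise ValueError("repulsion coefficient must be >= 0")
    rho = geom.contact_overlap
    if rho <= 0:
        return np.zeros_like(geom.direction)
    return -c_r * rho**3 * geom.direction


def migratory_sign(
    i: IMCState,
    j: IMCState,
    restrict_to_substrate: bool = True,
) -> int:
    """Sign of the migratory pair force on *i*.

    +1 if *i* is migratory and *j* is not, -1 in the mirrored case, 0
    when both or neither are migratory.  With the default restricted
    eligibility, a border cell pushes off nurse, epithelial and
    oocyte-surface cells only (not the polar cells it carries);
    ``restrict_to_substrate=False`` restores the pure sign rule.
    """
    if i.migratory == j.migratory:
        return 0
    passive = j if i.migratory else i
    if restrict_to_substrate and passive.cell_type not in MIGRATORY_SUBSTRATE_TYPES:
        return 0
    return 1 if i.migratory else -1


def migratory_force(
    geom: PairGeometry,
    sign: int,
    grad: np.ndarray,
    c_m: float,
    gated: bool = True,
    gate: str = "reach",
) -> np.ndarray:
    """Directed migratory force on *i* for one eligible pair.

    The gradient is projected onto the orthogonal complement of the
    contact axis, ``grad - (grad . d_hat) d_hat`` (valid in 2D and 3D),
    and scaled by ``c_m * sign``.  When ``gated``, the force is active
    only while the pair is interacting: gate ``"reach"`` requires the
    extended overlap to be positive, ``"contact"`` the contact overlap.
    Antisymmetric under i <-> j exchange (sign flips, projection
    unchanged).
    """
    grad = np.asarray(grad, dtype=float)
    if sign == 0 or c_m == 0:
        return np.zeros_like(grad)
    if gated:
        rho = geom.overlap if gate == "reach" else geom.contact_overlap
        if rho <= 0:
            return np.zeros_like(grad)
    d = geom.direction
    perp = grad - np.dot(grad, d) * d
    return c_m * sign * perp


def stochastic_force(rng: np.random.Generator, dim: int, c_s: float) -> np.ndarray:
    """One stochastic force draw: i.i.d. Gaussian components, SD ``c_s``."""
    if dim not in (2, 3):
        raise ValueError("dimension must be 2 or 3")
    return c_s * rng.standard_normal(dim)


def net_force(
    i: IMCState,
    neighbors: Iterable[IMCState],
    params: ForceParameters,
    grad_field: GradientField | None = None,
    rng: np.random.Generator | None = None,
    restrict_to_substrate: bool = True,
    migratory_gate: str = "reach",
) -> np.ndarray:
    """Net force on cell *i*: adhesion + repulsion over neighbours, plus
    migratory contributions over eligible pairs, plus one stochastic
    draw (omitted when ``rng`` is None or ``C^s`` is 0).

    The neighbour list must contain every cell within interaction range
    of *i*; farther cells contribute zero, so over-complete lists are
    safe.
    """
    grad_field = grad_field or GradientField(dimension=i.dimension)
    total = np.zeros(i.dimension)
    for j in neighbors:
        if j.id == i.id:
            continue
        try:
            geom = pair_geometry(i.position, j.position, reach=params.reach)
        except DegenerateGeometryError as err:
            raise DegenerateGeometryError(
                f"cells {i.id} and {j.id} have coincident centres"
            ) from err
        coeff = params.adhesion.coefficient(
            i.cell_type, j.cell_type, i.group_id, j.group_id
        )
        total += adhesion_force(geom, coeff)
        total += repulsion_force(geom, params.repulsion)
        sign = migratory_sign(i, j, restrict_to_substrate=restrict_to_substrate)
        if sign != 0:
            grad = grad_field(0.5 * (i.position + j.position))
            total += migratory_force(
                geom, sign, grad, params.migration, gate=migratory_gate
            )
    if rng is not None and params.stochastic > 0:
        total += stochastic_force(rng, i.dimension, params.stochastic)
    return total
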