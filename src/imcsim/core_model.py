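"""Domain types and the unit system of the IMC model.

An Identical Math Cell (IMC) is a rigid disc (2D) or sphere (3D) of
diameter ``D`` = 7 micrometres.  All lengths in the simulation are
expressed in units of ``D`` and all times in units of the time scale
``alpha`` = 1 hour; the damping viscosity never appears on its own
because every force coefficient is a composite already scaled by
``alpha * D / mu``.  Small cells (border, polar, epithelial) are one IMC
each; large nurse cells are adhesive aggregates of many IMCs sharing a
``group_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CellType",
    "UnitSystem",
    "IMCState",
    "PairAdhesionTable",
    "ForceParameters",
    "GradientField",
    "adhesion_coefficient",
    "unit_convert",
]


class CellType(str, Enum):
    """The five cell roles used by the egg-chamber presets.

    Only border cells generate migratory force; every other role is
    non-motile.
    """

    BORDER = "border"
    POLAR = "polar"
    EPITHELIAL = "epithelial"
    NURSE = "nurse"
    OOCYTE_SURFACE = "oocyte_surface"

    @property
    def migratory(self) -> bool:
        return self is CellType.BORDER


@dataclass(frozen=True)
class UnitSystem:
    """Physical scales of the non-dimensionalisation.

    Attributes
    ----------
    length_um:
        The IMC diameter ``D`` in micrometres (default 7).  One
        non-dimensional length unit equals one IMC diameter.
    time_hours:
        The time scale ``alpha`` in hours (default 1).  One
        non-dimensional time unit equals one hour.
    """

    length_um: float = 7.0
    time_hours: float = 1.0

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.time_hours <= 0:
            raise ValueError("length and time scales must be positive")


def unit_convert(
    value: float,
    quantity: str,
    direction: str,
    units: UnitSystem | None = None,
) -> float:
    """Convert between non-dimensional and physical units.

    Parameters
    ----------
    value:
        The number to convert.
    quantity:
        ``"length"`` (scale ``D`` = 7 um) or ``"time"`` (scale 1 h).
    direction:
        ``"to_physical"`` multiplies by the scale (um / hours out);
        ``"to_nondimensional"`` divides by it.
    """
    units = units or UnitSystem()
    if quantity == "length":
        scale = units.length_um
    elif quantity == "time":
        scale = units.time_hours
    else:
        raise ValueError(f"unknown quantity {quantity!r}; expected 'length' or 'time'")
    if direction == "to_physical":
        return value * scale
    if direction == "to_nondimensional":
        return value / scale
    raise ValueError(
        f"unknown direction {direction!r}; expected 'to_physical' or 'to_nondimensional'"
    )


@dataclass
class IMCState:
    """One cell's identity: position, type, group membership and flags.

    Positions are non-dimensional (units of the IMC diameter).  The
    ``migratory`` flag is derived from the cell type; ``fixed`` cells are
    never moved by the integrator (the oocyte surface from the start, the
    epithelium after the fixing time).
    """

    id: int
    position: np.ndarray
    cell_type: CellType
    group_id: int = 0
    migratory: bool | None = None
    fixed: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.ndim != 1 or self.position.size not in (2, 3):
            raise ValueError("position must be a 2- or 3-vector")
        if not isinstance(self.cell_type, CellType):
            self.cell_type = CellType(self.cell_type)
        derived = self.cell_type.migratory
        if self.migratory is None:
            self.migratory = derived
        elif self.migratory != derived:
            raise ValueError(
                f"migratory={self.migratory} inconsistent with type {self.cell_type.value}"
            )

    @property
    def dimension(self) -> int:
        return self.position.size


@dataclass
class PairAdhesionTable:
    """Composite adhesion coefficients by interacting pair class.

    Entries are the non-dimensional composites (basal attraction times
    the pair-class multiplier, scaled by ``alpha * D / mu``).  Lookup is
    symmetric; nurse-nurse pairs from *different* nurse cells fall back
    to the basal level, as do all pair classes not listed.
    """

    border_border: float = 1.872
    polar_polar: float = 1.872
    polar_border: float = 7.02
    epithelial_epithelial: float = 7.02e-4
    same_nurse: float = 7.02e-4
    basal: float = 7.02e-4

    def __post_init__(self) -> None:
        for name in (
            "border_border",
            "polar_polar",
            "polar_border",
            "epithelial_epithelial",
            "same_nurse",
            "basal",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"adhesion coefficient {name} must be >= 0")

    def coefficient(
        self,
        type_i: CellType,
        type_j: CellType,
        group_i: int = 0,
        group_j: int = 0,
    ) -> float:
        """Look up the composite coefficient for one interacting pair."""
        type_i = CellType(type_i)
        type_j = CellType(type_j)
        pair = frozenset((type_i, type_j))
        if pair == {CellType.BORDER}:
            return self.border_border
        if pair == {CellType.POLAR}:
            return self.polar_polar
        if pair == {CellType.POLAR, CellType.BORDER}:
            return self.polar_border
        if pair == {CellType.EPITHELIAL}:
            return self.epithelial_epithelial
        if pair == {CellType.NURSE} and group_i == group_j:
            return self.same_nurse
        return self.basal


def adhesion_coefficient(
    type_i: CellType,
    type_j: CellType,
    group_i: int,
    group_j: int,
    table: PairAdhesionTable,
) -> float:
    """Pair-class adhesion coefficient; symmetric in (i, j).

    Nurse-nurse pairs with differing ``group_id`` (different nurse
    cells) receive the basal coefficient.
    """
    return table.coefficient(type_i, type_j, group_i, group_j)


@dataclass
class ForceParameters:
    """Composite non-dimensional force coefficients.

    Attributes
    ----------
    adhesion:
        The pair-class adhesion table.
    repulsion:
        ``C^r`` (default 15.6), shared by all pairs; the repulsive
        contact law is cubic in the overlap.
    migration:
        ``C^m`` (default 1.56), the strength of the directed force a
        border cell generates against a non-motile substrate cell.
    stochastic:
        ``C^s`` (default 5); each position component receives an
        independent Gaussian force of this standard deviation per step.
    reach:
        ``epsilon``, the adhesive reach beyond the cell edge, in units
        of D.  Must satisfy 0 < epsilon < 1/2 (half a diameter);
        repulsion always acts with reach 0 (contact only).
    """

    adhesion: PairAdhesionTable = field(default_factory=PairAdhesionTable)
    repulsion: float = 15.6
    migration: float = 1.56
    stochastic: float = 5.0
    reach: float = 0.45

    #: exponents of the overlap in the adhesive (linear) and repulsive
    #: (cubic) laws; fixed by the model.
    ADHESION_EXPONENT = 1
    REPULSION_EXPONENT = 3

    def __post_init__(self) -> None:
        if not (0.0 < self.reach < 0.5):
            raise ValueError(
                f"adhesive reach epsilon must satisfy 0 < epsilon < D/2 "
                f"(non-dimensional 0.5); got {self.reach}"
            )
        for name in ("repulsion", "migration", "stochastic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} coefficient must be >= 0")


@dataclass
class GradientField:
    """Chemoattractant gradient ``grad f`` evaluated at a position.

    The default is a constant unit vector along the anterior->posterior
    axis (+x); any overall magnitude is absorbed into the migration
    coefficient.  A custom callable may map an (..., dim) array of
    positions to an array of gradient vectors of the same shape.
    """

    function: Callable[[np.ndarray], np.ndarray] | None = None
    dimension: int = 3

    def __call__(self, position: Sequence[float] | np.ndarray) -> np.ndarray:
        position = np.asarray(position, dtype=float)
        if self.function is not None:
            return np.asarray(self.function(position), dtype=float)
        grad = np.zeros(position.shape[-1] if position.ndim else self.dimension)
        grad[0] = 1.0
        return np.broadcast_to(grad, position.shape).copy() if position.ndim > 1 else grad

    @property
    def is_constant(self) -> bool:
        return self.function is None
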