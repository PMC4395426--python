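"""Initial-condition construction for the egg-chamber domain.

The anterior->posterior axis is x.  The chamber is a box whose boundary
lattice carries one epithelial cell per diameter on every face except
the posterior one, which carries the fixed oocyte-surface layer (the
migration target).  The interior is tiled by large nurse cells, each an
aggregate of unit cells placed on a close-packed lattice inside a
sphere; aggregates are arranged in axial stations of three around the
axis (3D) or in two rows (2D), leaving the gaps between nurse cells
through which the cluster squeezes.  The migratory cluster (border
cells packed around two central polar cells) seats just inside the
anterior epithelium on the axis.

All builders are deterministic: no randomness enters the initial
condition.  Default dimensions follow an in-vivo migration path of
roughly 150 um (about 21 cell diameters); nurse radii approximate the
~5x size ratio between nurse and epithelial cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core_model import CellType, IMCState

__all__ = [
    "DomainSpec",
    "Plane",
    "PlaneSpec",
    "GeometryError",
    "build_egg_chamber",
    "place_aggregate",
    "from_planes",
    "to_planes",
    "two_cell_pair",
    "random_blob",
    "mini_chamber",
]

#: minimum centre-to-centre separation enforced at initialisation.
MIN_SEPARATION = 0.8

# group-id conventions
CLUSTER_GROUP = 0
EPITHELIUM_GROUP = 1
OOCYTE_GROUP = 2
FIRST_NURSE_GROUP = 3


class GeometryError(ValueError):
    """An initial-condition constraint cannot be satisfied."""


@dataclass
class DomainSpec:
    """Geometry of the egg-chamber preset.

    Lengths are in cell diameters.  ``length`` runs along the
    anterior->posterior axis; ``cross_section`` is the transverse extent
    (one number in 2D, two in 3D).
    """

    dimension: int = 3
    length: float = 22.0
    cross_section: tuple[float, ...] | None = None
    nurse_count: int | None = None
    nurse_radius: float = 2.5
    n_border: int = 6
    n_polar: int = 2
    packing: str | None = None  # "fcc" (3D) or "hex" (2D)
    packing_spacing: float = 0.95
    epithelium_spacing: float = 1.0
    cluster_offset: float = 2.0  # cluster centre distance from the anterior face
    #: "spheres": one ball of cells per nurse centre, leaving the
    #: interstitial voids ("gaps between nurse cells") through which the
    #: cluster squeezes and near which it tumbles; "tiled": one
    #: close-packed lattice fills the whole interior and is partitioned
    #: among the nurse centres (a denser medium, in which the cluster
    #: tends to shear apart).
    nurse_fill: str = "spheres"

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise GeometryError("dimension must be 2 or 3")
        if self.cross_section is None:
            self.cross_section = (10.0,) if self.dimension == 2 else (10.0, 10.0)
        self.cross_section = tuple(float(c) for c in self.cross_section)
        if len(self.cross_section) != self.dimension - 1:
            raise GeometryError(
                f"cross_section needs {self.dimension - 1} extent(s) in {self.dimension}D"
            )
        if self.nurse_count is None:
            self.nurse_count = 15 if self.dimension == 3 else 6
        if self.packing is None:
            self.packing = "fcc" if self.dimension == 3 else "hex"
        if self.length <= 0 or any(c <= 0 for c in self.cross_section):
            raise GeometryError("domain extents must be positive")
        if self.n_border < 1:
            raise GeometryError("need at least one border cell")
        if self.n_polar != 2:
            raise GeometryError("the cluster carries exactly two polar cells")
        if self.nurse_radius < 1.0:
            raise GeometryError("nurse radius must be >= 1 diameter")
        if self.nurse_fill not in ("tiled", "spheres"):
            raise GeometryError("nurse_fill must be 'tiled' or 'spheres'")
        half = min(self.cross_section) / 2.0
        if self.nurse_radius > half:
            raise GeometryError(
                f"nurse radius {self.nurse_radius} exceeds the half cross-section {half}"
            )


# ---------------------------------------------------------------------------
# aggregate packing
# ---------------------------------------------------------------------------


def _fcc_lattice(center: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    """FCC lattice points within ``radius`` of ``center`` (3D).

    The nearest-neighbour distance equals ``spacing``; the centre itself
    is a lattice point.  Deterministic: points are sorted
    lexicographically.
    """
    c = spacing * math.sqrt(2.0)  # cubic cell constant
    offsets = np.array(
        [[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]], dtype=float
    )
    m = int(math.ceil(radius / c)) + 1
    idx = np.arange(-m, m + 1)
    ii, jj, kk = np.meshgrid(idx, idx, idx, indexing="ij")
    base = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    pts = (base[:, None, :] + offsets[None, :, :]).reshape(-1, 3) * c
    pts = pts + center
    keep = np.linalg.norm(pts - center, axis=1) <= radius + 1e-9
    pts = pts[keep]
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
    return pts[order]


def _hex_lattice(center: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    """Triangular lattice points within ``radius`` of ``center`` (2D)."""
    dy = spacing * math.sqrt(3.0) / 2.0
    m = int(math.ceil(radius / min(spacing, dy))) + 1
    rows = np.arange(-m, m + 1)
    cols = np.arange(-m, m + 1)
    pts = []
    for r in rows:
        xoff = 0.5 * spacing if r % 2 else 0.0
        for q in cols:
            pts.append((q * spacing + xoff, r * dy))
    pts = np.asarray(pts, dtype=float) + center
    keep = np.linalg.norm(pts - center, axis=1) <= radius + 1e-9
    pts = pts[keep]
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return pts[order]


def place_aggregate(
    center: Sequence[float],
    radius: float,
    group_id: int,
    packing: str = "fcc",
    spacing: float = 0.95,
    cell_type: CellType = CellType.NURSE,
    start_id: int = 0,
) -> list[IMCState]:
    """Fill a disc/sphere with close-packed unit cells of one group.

    The lattice spacing (default 0.95 diameters) keeps members slightly
    compressed, mimicking the internal pressure of a large cell; the
    member count is deterministic for a given packing, spacing and
    radius.
    """
    center = np.asarray(center, dtype=float)
    if radius < 1.0:
        raise GeometryError(
            f"aggregate radius {radius} cannot fit a single unit cell (need >= 1)"
        )
    if packing == "fcc":
        if center.size != 3:
            raise GeometryError("fcc packing requires a 3D centre")
        pts = _fcc_lattice(center, radius, spacing)
    elif packing == "hex":
        if center.size != 2:
            raise GeometryError("hex packing requires a 2D centre")
        pts = _hex_lattice(center, radius, spacing)
    else:
        raise GeometryError(f"unknown packing {packing!r}; expected 'fcc' or 'hex'")
    return [
        IMCState(id=start_id + k, position=p, cell_type=cell_type, group_id=group_id)
        for k, p in enumerate(pts)
    ]


# ---------------------------------------------------------------------------
# cluster and shell construction
# ---------------------------------------------------------------------------


def _sphere_points(n: int, radius: float) -> np.ndarray:
    """n roughly-even points on a sphere (golden-spiral construction)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return radius * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _circle_points(n: int, radius: float) -> np.ndarray:
    theta = 2.0 * math.pi * np.arange(n) / n + math.pi / n
    return radius * np.stack([np.cos(theta), np.sin(theta)], axis=1)


def _cluster_positions(spec: DomainSpec) -> tuple[np.ndarray, np.ndarray]:
    """Border and polar positions: two polar cells at the core, border
    cells on a shell around them."""
    center = np.array(
        [spec.cluster_offset] + [c / 2.0 for c in spec.cross_section], dtype=float
    )
    polar_half_gap = 0.4
    shell_radius = 1.2
    axis = np.zeros(spec.dimension)
    axis[-1] = 1.0
    polar = np.stack([center + polar_half_gap * axis, center - polar_half_gap * axis])
    if spec.dimension == 3:
        border = center + _sphere_points(spec.n_border, shell_radius)
    else:
        border = center + _circle_points(spec.n_border, shell_radius)
    pts = np.vstack([border, polar])
    dists = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(dists, np.inf)
    if dists.min() < MIN_SEPARATION - 1e-9:
        raise GeometryError(
            f"cluster of {spec.n_border} border cells cannot satisfy the "
            f"{MIN_SEPARATION}-diameter minimum separation"
        )
    return border, polar


def _boundary_lattice(spec: DomainSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boundary lattice points, split into epithelium and the posterior
    oocyte face."""
    s = spec.epithelium_spacing
    nx = int(round(spec.length / s))
    axes = [np.linspace(0.0, spec.length, nx + 1)]
    for c in spec.cross_section:
        axes.append(np.linspace(0.0, c, int(round(c / s)) + 1))
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=-1)
    on_face = np.zeros(len(pts), dtype=bool)
    for d, axis in enumerate(axes):
        on_face |= np.isclose(pts[:, d], axis[0]) | np.isclose(pts[:, d], axis[-1])
    pts = pts[on_face]
    posterior = np.isclose(pts[:, 0], spec.length)
    return pts[~posterior], pts[posterior]


def _nurse_centers(spec: DomainSpec) -> list[np.ndarray]:
    """Axial stations of aggregates filling the interior.

    3D: three nurse cells per station ring the axis, with the ring
    rotated 60 degrees between consecutive stations so neighbouring
    spheres interdigitate.  2D: two rows above and below the axis.
    """
    # aggregates span the interior with half-diameter wall clearance so
    # nurse material reaches both the anterior region and the oocyte
    # face (nurse cells fill the chamber in vivo); members colliding
    # with walls or the cluster are pruned at placement.
    r = spec.nurse_radius
    x0 = r + 0.5
    x1 = spec.length - r - 0.5
    if x1 < x0:
        raise GeometryError(
            f"domain length {spec.length} too short for nurse radius {r}"
        )
    centers: list[np.ndarray] = []
    if spec.dimension == 3:
        per_station = 3
        n_stations = math.ceil(spec.nurse_count / per_station)
        xs = np.linspace(x0, x1, n_stations) if n_stations > 1 else [0.5 * (x0 + x1)]
        cy = spec.cross_section[0] / 2.0
        cz = spec.cross_section[1] / 2.0
        ring = min(cy, cz) - r + 0.2 * r  # slight overlap past the axis
        if ring <= 0:
            raise GeometryError("cross-section too small for three nurse cells per station")
        count = 0
        for s, x in enumerate(xs):
            for k in range(per_station):
                if count >= spec.nurse_count:
                    break
                angle = math.radians(90.0 + 60.0 * s + 120.0 * k)
                centers.append(
                    np.array([x, cy + ring * math.cos(angle), cz + ring * math.sin(angle)])
                )
                count += 1
    else:
        per_station = 2
        n_stations = math.ceil(spec.nurse_count / per_station)
        xs = np.linspace(x0, x1, n_stations) if n_stations > 1 else [0.5 * (x0 + x1)]
        cy = spec.cross_section[0] / 2.0
        off = min(cy - r + 0.2 * r, cy / 2.0)
        count = 0
        for x in xs:
            for sgn in (1.0, -1.0):
                if count >= spec.nurse_count:
                    break
                centers.append(np.array([x, cy + sgn * off]))
                count += 1
    return centers


def _interior_lattice(spec: DomainSpec) -> np.ndarray:
    """Close-packed lattice points covering the whole chamber interior."""
    center = np.array([spec.length / 2.0] + [c / 2.0 for c in spec.cross_section])
    radius = float(np.linalg.norm(center))  # covers the full box from its centre
    if spec.dimension == 3:
        pts = _fcc_lattice(center, radius, spec.packing_spacing)
    else:
        pts = _hex_lattice(center, radius, spec.packing_spacing)
    lo = np.full(spec.dimension, 0.0)
    hi = np.array([spec.length, *spec.cross_section])
    keep = np.all((pts >= lo) & (pts <= hi), axis=1)
    return pts[keep]


def build_egg_chamber(spec: DomainSpec | None = None) -> list[IMCState]:
    """Construct the full initial condition for one egg-chamber preset.

    Placement order: migratory cluster, epithelial shell, oocyte layer,
    then the nurse cells; nurse lattice points that would come within
    0.8 diameters of an already-placed cell are dropped, which carves
    the nurse material around the cluster and the walls.  With the
    default ``nurse_fill="spheres"`` one ball of cells is placed per
    nurse centre, leaving interstitial voids; ``"tiled"`` packs the
    interior completely and partitions it among the nurse centres (each
    lattice point joins the nearest centre's cell).  The result is
    deterministic for a fixed spec.
    """
    spec = spec or DomainSpec()
    border, polar = _cluster_positions(spec)
    epithelium, oocyte = _boundary_lattice(spec)

    states: list[IMCState] = []

    def _extend(points, cell_type, group_id, fixed=False):
        for p in points:
            states.append(
                IMCState(
                    id=len(states),
                    position=np.asarray(p, dtype=float),
                    cell_type=cell_type,
                    group_id=group_id,
                    fixed=fixed,
                )
            )

    _extend(border, CellType.BORDER, CLUSTER_GROUP)
    _extend(polar, CellType.POLAR, CLUSTER_GROUP)
    _extend(epithelium, CellType.EPITHELIAL, EPITHELIUM_GROUP)
    _extend(oocyte, CellType.OOCYTE_SURFACE, OOCYTE_GROUP, fixed=True)

    placed = np.array([s.position for s in states])
    centers = _nurse_centers(spec)[: spec.nurse_count]
    if len(centers) < spec.nurse_count:
        raise GeometryError(
            f"could not arrange {spec.nurse_count} nurse cells in this domain"
        )
    if spec.nurse_fill == "tiled":
        pts = _interior_lattice(spec)
        tree = cKDTree(placed)
        near = tree.query_ball_point(pts, MIN_SEPARATION)
        pts = pts[[len(hits) == 0 for hits in near]]
        if len(pts) < spec.nurse_count:
            raise GeometryError("unsatisfiable nurse packing: interior too small")
        _, owner = cKDTree(np.array(centers)).query(pts, k=1)
        for k in range(spec.nurse_count):
            members = pts[owner == k]
            if len(members) == 0:
                raise GeometryError(
                    f"nurse cell {k} at {np.round(centers[k], 2)} owns no cells"
                )
            _extend(members, CellType.NURSE, FIRST_NURSE_GROUP + k)
    else:
        for k, center in enumerate(centers):
            members = place_aggregate(
                center,
                spec.nurse_radius,
                group_id=FIRST_NURSE_GROUP + k,
                packing=spec.packing,
                spacing=spec.packing_spacing,
            )
            pts = np.array([m.position for m in members])
            tree = cKDTree(placed)
            near = tree.query_ball_point(pts, MIN_SEPARATION)
            pts = pts[[len(hits) == 0 for hits in near]]
            if len(pts) == 0:
                raise GeometryError(
                    f"nurse cell {k} at {np.round(center, 2)} has no room: "
                    f"aggregates overlap the cluster or walls entirely"
                )
            _extend(pts, CellType.NURSE, FIRST_NURSE_GROUP + k)
            placed = np.vstack([placed, pts])
    return states


# ---------------------------------------------------------------------------
# plane-by-plane specification
# ---------------------------------------------------------------------------


@dataclass
class Plane:
    """One anterior->posterior plane of cells.

    ``entries`` are (in-plane coordinates, cell type, group id) triples;
    in-plane coordinates have dimension - 1 components.
    """

    axial: float
    entries: list[tuple[tuple[float, ...], CellType | str, int]] = field(
        default_factory=list
    )


@dataclass
class PlaneSpec:
    """Ordered planes of cells from anterior to posterior."""

    planes: list[Plane] = field(default_factory=list)
    dimension: int = 3
    cross_section: tuple[float, ...] | None = None


def from_planes(spec: PlaneSpec) -> list[IMCState]:
    """Concatenate planes into a full state list, preserving declared
    types and groups verbatim.  Oocyte-surface cells are marked fixed.
    """
    states: list[IMCState] = []
    for idx, plane in enumerate(spec.planes):
        for coords, cell_type, group_id in plane.entries:
            coords = tuple(float(c) for c in coords)
            if len(coords) != spec.dimension - 1:
                raise GeometryError(
                    f"plane {idx}: in-plane coordinates need "
                    f"{spec.dimension - 1} components, got {len(coords)}"
                )
            if spec.cross_section is not None:
                for c, extent in zip(coords, spec.cross_section):
                    if not (0.0 <= c <= extent):
                        raise GeometryError(
                            f"plane {idx}: coordinate {c} outside the "
                            f"cross-section [0, {extent}]"
                        )
            cell_type = CellType(cell_type)
            states.append(
                IMCState(
                    id=len(states),
                    position=np.array([plane.axial, *coords]),
                    cell_type=cell_type,
                    group_id=int(group_id),
                    fixed=cell_type is CellType.OOCYTE_SURFACE,
                )
            )
    return states


def to_planes(states: Sequence[IMCState]) -> PlaneSpec:
    """Export a state list as anterior->posterior planes (inverse of
    :func:`from_planes` up to cell ordering).  Cells are grouped by
    exact axial coordinate, so the round trip preserves positions
    bitwise."""
    if not states:
        return PlaneSpec(planes=[])
    dimension = states[0].dimension
    by_axial: dict[float, Plane] = {}
    for s in states:
        ax = float(s.position[0])
        plane = by_axial.setdefault(ax, Plane(axial=ax))
        plane.entries.append(
            (tuple(float(c) for c in s.position[1:]), s.cell_type, s.group_id)
        )
    planes = [by_axial[a] for a in sorted(by_axial)]
    return PlaneSpec(planes=planes, dimension=dimension)


# ---------------------------------------------------------------------------
# toy fixtures
# ---------------------------------------------------------------------------


def two_cell_pair(
    separation: float,
    cell_type: CellType | str = CellType.BORDER,
    dimension: int = 3,
    axis: int = 0,
) -> list[IMCState]:
    """Two cells of one type separated along a coordinate axis."""
    cell_type = CellType(cell_type)
    p0 = np.zeros(dimension)
    p1 = np.zeros(dimension)
    p1[axis] = separation
    return [
        IMCState(id=0, position=p0, cell_type=cell_type),
        IMCState(id=1, position=p1, cell_type=cell_type),
    ]


def random_blob(
    n: int,
    seed: int,
    dimension: int = 3,
    box: float = 6.0,
    cell_type: CellType | str = CellType.NURSE,
    min_separation: float = 0.5,
) -> list[IMCState]:
    """n cells of one type scattered in a box with a minimum spacing
    (rejection-sampled; deterministic for a given seed)."""
    rng = np.random.default_rng(seed)
    cell_type = CellType(cell_type)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        candidate = rng.uniform(0.0, box, size=dimension)
        if all(np.linalg.norm(candidate - p) >= min_separation for p in pts):
            pts.append(candidate)
        attempts += 1
        if attempts > 100000:
            raise GeometryError("random_blob could not satisfy the spacing")
    return [
        IMCState(id=k, position=p, cell_type=cell_type, group_id=0)
        for k, p in enumerate(pts)
    ]


def mini_chamber(n_border: int = 6) -> list[IMCState]:
    """A reduced 3D chamber for fast tests: shorter path, smaller
    cross-section, six nurse cells."""
    spec = DomainSpec(
        dimension=3,
        length=12.0,
        cross_section=(7.0, 7.0),
        nurse_count=6,
        nurse_radius=2.0,
        n_border=n_border,
    )
    return build_egg_chamber(spec)
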