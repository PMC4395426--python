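"""Forward-Euler time stepping with neighbour lists.

The overdamped equation of motion is integrated explicitly: each
non-fixed cell moves by ``dt`` times its net force (velocity equals
force in the non-dimensional, damping-absorbed units).  Pair
interactions are evaluated over a neighbour list built with a KD-tree
at a cutoff of two cell diameters and refreshed on a fixed simulated
-time interval; forces vanish beyond ``1 + epsilon`` separations, so
the cutoff leaves a travel margin between refreshes.

The stochastic force enters the update as ``dt * C^s * zeta`` per step
(plain forcing, no sqrt(dt) scaling); one Gaussian vector is drawn per
cell per step in cell-id order, which makes trajectories bitwise
reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core_model import CellType, ForceParameters, GradientField, IMCState
from .forces import MIGRATORY_SUBSTRATE_TYPES, DegenerateGeometryError

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "NumericalBlowupError",
    "build_neighbor_list",
    "neighbor_pairs",
    "euler_step",
    "run_simulation",
]

_TYPE_ORDER = list(CellType)
_TYPE_CODE = {t: k for k, t in enumerate(_TYPE_ORDER)}
_SUBSTRATE_CODES = np.array(
    [t in MIGRATORY_SUBSTRATE_TYPES for t in _TYPE_ORDER], dtype=bool
)
_MIGRATORY_CODES = np.array([t.migratory for t in _TYPE_ORDER], dtype=bool)


class NumericalBlowupError(RuntimeError):
    """A position became non-finite during integration."""


@dataclass
class SimulationConfig:
    """Numerical controls of one simulation run.

    All times are non-dimensional (hours); lengths are in cell
    diameters.  Defaults: Euler step 0.005 (~18 s), neighbour cutoff 2
    diameters refreshed every 0.2 time units, epithelium fixed after
    0.1 time units, one stored frame per 10 steps.
    """

    duration: float = 2.0
    dt: float = 0.005
    neighbor_cutoff: float = 2.0
    neighbor_refresh: float = 0.2
    epithelium_fix_time: float = 0.1
    record_stride: int = 10
    seed: int = 0
    dimension: int = 3
    #: gate for the migratory pair force: "reach" activates it while the
    #: extended overlap is positive, "contact" only during physical
    #: contact.
    migratory_gate: str = "reach"
    #: restrict border-cell migratory pairs to substrate cells (nurse,
    #: epithelial, oocyte surface); False restores the pure sign rule.
    restrict_migratory_to_substrate: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.neighbor_refresh < self.dt:
            raise ValueError("neighbor_refresh must be >= dt")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if self.migratory_gate not in ("reach", "contact"):
            raise ValueError("migratory_gate must be 'reach' or 'contact'")

    def validate_against(self, params: ForceParameters) -> None:
        if self.neighbor_cutoff < 1.0 + params.reach:
            raise ValueError(
                f"neighbor_cutoff {self.neighbor_cutoff} is below the "
                f"interaction range 1 + epsilon = {1.0 + params.reach}"
            )


@dataclass
class Trajectory:
    """Time-indexed positions of all cells plus static metadata."""

    times: np.ndarray  # (T,)
    frames: np.ndarray  # (T, N, dim)
    ids: np.ndarray  # (N,)
    cell_types: np.ndarray  # (N,) of str values
    group_ids: np.ndarray  # (N,)
    migratory: np.ndarray  # (N,) bool
    fixed: np.ndarray  # (N,) bool, final flags (epithelium fixed)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("one frame per recorded time required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_cells(self) -> int:
        return self.frames.shape[1]

    @property
    def dimension(self) -> int:
        return self.frames.shape[2]

    def type_mask(self, cell_type: CellType | str) -> np.ndarray:
        return self.cell_types == CellType(cell_type).value

    def truncated(self, t_max: float) -> "Trajectory":
        """The prefix of this trajectory with times <= ``t_max``."""
        keep = self.times <= t_max + 1e-12
        return Trajectory(
            times=self.times[keep],
            frames=self.frames[keep],
            ids=self.ids,
            cell_types=self.cell_types,
            group_ids=self.group_ids,
            migratory=self.migratory,
            fixed=self.fixed,
            config=dict(self.config),
        )


# ---------------------------------------------------------------------------
# system arrays
# ---------------------------------------------------------------------------


@dataclass
class _System:
    """Array-of-structs view over a list of IMC states."""

    ids: np.ndarray
    positions: np.ndarray
    type_codes: np.ndarray
    group_ids: np.ndarray
    fixed: np.ndarray

    @classmethod
    def from_states(cls, states: Sequence[IMCState]) -> "_System":
        if not states:
            raise ValueError("cannot simulate an empty system")
        dim = states[0].dimension
        for s in states:
            if s.dimension != dim:
                raise ValueError("all cells must share one spatial dimension")
        return cls(
            ids=np.array([s.id for s in states], dtype=int),
            positions=np.array([s.position for s in states], dtype=float),
            type_codes=np.array([_TYPE_CODE[s.cell_type] for s in states], dtype=int),
            group_ids=np.array([s.group_id for s in states], dtype=int),
            fixed=np.array([s.fixed for s in states], dtype=bool),
        )

    @property
    def migratory(self) -> np.ndarray:
        return _MIGRATORY_CODES[self.type_codes]

    @property
    def cell_type_values(self) -> np.ndarray:
        return np.array([_TYPE_ORDER[c].value for c in self.type_codes])


def _pair_adhesion(table, ti, tj, gi, gj) -> np.ndarray:
    """Vectorised pair-class adhesion coefficients for type-code arrays."""
    b = _TYPE_CODE[CellType.BORDER]
    p = _TYPE_CODE[CellType.POLAR]
    e = _TYPE_CODE[CellType.EPITHELIAL]
    n = _TYPE_CODE[CellType.NURSE]
    coeff = np.full(ti.shape, table.basal, dtype=float)
    coeff[(ti == b) & (tj == b)] = table.border_border
    coeff[(ti == p) & (tj == p)] = table.polar_polar
    coeff[((ti == p) & (tj == b)) | ((ti == b) & (tj == p))] = table.polar_border
    coeff[(ti == e) & (tj == e)] = table.epithelial_epithelial
    coeff[(ti == n) & (tj == n) & (gi == gj)] = table.same_nurse
    return coeff


def _pair_signs(system: _System, i: np.ndarray, j: np.ndarray, restrict: bool):
    """Migratory sign (for the force on i) per pair."""
    mi = system.migratory[i]
    mj = system.migratory[j]
    sub_i = _SUBSTRATE_CODES[system.type_codes[i]]
    sub_j = _SUBSTRATE_CODES[system.type_codes[j]]
    sign = np.zeros(i.shape, dtype=np.int8)
    plus = mi & ~mj
    minus = mj & ~mi
    if restrict:
        plus &= sub_j
        minus &= sub_i
    sign[plus] = 1
    sign[minus] = -1
    return sign


@dataclass
class _PairData:
    i: np.ndarray
    j: np.ndarray
    adhesion: np.ndarray
    sign: np.ndarray
    any_migratory: bool


def neighbor_pairs(positions: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Undirected index pairs (i < j) with separation <= cutoff."""
    tree = cKDTree(positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return pairs[:, 0], pairs[:, 1]


def build_neighbor_list(positions: np.ndarray, cutoff: float) -> list[set[int]]:
    """Per-cell neighbour index sets: all j != i within ``cutoff``."""
    positions = np.asarray(positions, dtype=float)
    i, j = neighbor_pairs(positions, cutoff)
    sets: list[set[int]] = [set() for _ in range(len(positions))]
    for a, b in zip(i.tolist(), j.tolist()):
        sets[a].add(b)
        sets[b].add(a)
    return sets


def _build_pair_data(
    system: _System, params: ForceParameters, config: SimulationConfig
) -> _PairData:
    i, j = neighbor_pairs(system.positions, config.neighbor_cutoff)
    if i.size:
        # pairs of two fixed cells exert no force on anything movable
        keep = ~(system.fixed[i] & system.fixed[j])
        i, j = i[keep], j[keep]
    adhesion = _pair_adhesion(
        params.adhesion,
        system.type_codes[i],
        system.type_codes[j],
        system.group_ids[i],
        system.group_ids[j],
    )
    sign = _pair_signs(system, i, j, config.restrict_migratory_to_substrate)
    return _PairData(i=i, j=j, adhesion=adhesion, sign=sign, any_migratory=bool(np.any(sign)))


def _deterministic_forces(
    system: _System,
    pairs: _PairData,
    params: ForceParameters,
    config: SimulationConfig,
    grad_field: GradientField,
) -> np.ndarray:
    n, dim = system.positions.shape
    total = np.zeros((n, dim))
    if pairs.i.size == 0:
        return total
    pos = system.positions
    delta = pos[pairs.j] - pos[pairs.i]
    r = np.sqrt(np.einsum("ij,ij->i", delta, delta))
    if np.any(r < 1e-9):
        k = int(np.argmin(r))
        raise DegenerateGeometryError(
            f"cells {system.ids[pairs.i[k]]} and {system.ids[pairs.j[k]]} "
            f"have coincident centres"
        )
    dhat = delta / r[:, None]
    rho_eps = (1.0 + params.reach) - r
    rho0 = 1.0 - r
    mag = pairs.adhesion * np.maximum(rho_eps, 0.0)
    mag -= params.repulsion * np.maximum(rho0, 0.0) ** 3
    f = mag[:, None] * dhat
    if pairs.any_migratory and params.migration > 0:
        gate = rho_eps > 0 if config.migratory_gate == "reach" else rho0 > 0
        active = (pairs.sign != 0) & gate
        if np.any(active):
            da = dhat[active]
            if grad_field.is_constant:
                g = grad_field(np.zeros(dim))
                gd = da @ g
                perp = g[None, :] - gd[:, None] * da
            else:
                mid = 0.5 * (pos[pairs.i[active]] + pos[pairs.j[active]])
                g = grad_field(mid)
                gd = np.einsum("ij,ij->i", g, da)
                perp = g - gd[:, None] * da
            f[active] += (params.migration * pairs.sign[active])[:, None] * perp
    for c in range(dim):
        total[:, c] = np.bincount(pairs.i, weights=f[:, c], minlength=n)
        total[:, c] -= np.bincount(pairs.j, weights=f[:, c], minlength=n)
    return total


def euler_step(
    states: Sequence[IMCState],
    params: ForceParameters,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    grad_field: GradientField | None = None,
) -> np.ndarray:
    """One explicit Euler step on a list of cell states.

    Returns the updated position array; convenience wrapper that builds
    the neighbour list for this single step (the main loop in
    :func:`run_simulation` caches it between refreshes).  Fixed cells do
    not move.
    """
    system = _System.from_states(states)
    config.validate_against(params)
    grad_field = grad_field or GradientField(dimension=system.positions.shape[1])
    pairs = _build_pair_data(system, params, config)
    forces = _deterministic_forces(system, pairs, params, config, grad_field)
    if rng is not None and params.stochastic > 0:
        forces = forces + params.stochastic * rng.standard_normal(system.positions.shape)
    new_positions = system.positions.copy()
    free = ~system.fixed
    new_positions[free] += config.dt * forces[free]
    if not np.isfinite(new_positions).all():
        bad = int(np.where(~np.isfinite(new_positions).all(axis=1))[0][0])
        raise NumericalBlowupError(f"non-finite position for cell {system.ids[bad]}")
    return new_positions


def run_simulation(
    initial: Sequence[IMCState],
    params: ForceParameters,
    config: SimulationConfig,
    grad_field: GradientField | None = None,
    stop_when: Callable[[float, np.ndarray], bool] | None = None,
) -> Trajectory:
    """Integrate from t = 0 to ``config.duration``.

    Neighbour lists are rebuilt every ``neighbor_refresh`` simulated
    time units (and at the epithelium-fixing event); epithelial cells
    stop moving once t reaches ``epithelium_fix_time``; oocyte-surface
    cells are fixed throughout.  A frame is recorded at t = 0, every
    ``record_stride`` steps, and at the final step.  ``stop_when(t,
    positions)`` is evaluated at each recorded frame and ends the run
    early when it returns True.  Runs are fully reproducible given the
    seed.
    """
    system = _System.from_states(initial)
    config.validate_against(params)
    if system.positions.shape[1] != config.dimension:
        raise ValueError(
            f"configured dimension {config.dimension} does not match "
            f"initial states ({system.positions.shape[1]}D)"
        )
    # reject (near-)coincident initial centres
    if len(initial) > 1:
        tree = cKDTree(system.positions)
        close = tree.query_pairs(1e-6, output_type="ndarray")
        if close.size:
            a, b = close[0]
            raise DegenerateGeometryError(
                f"initial centres of cells {system.ids[a]} and {system.ids[b]} coincide"
            )
    grad_field = grad_field or GradientField(dimension=config.dimension)
    rng = np.random.default_rng(config.seed)
    eps_t = 1e-9

    n_steps = int(round(config.duration / config.dt))
    epithelial = system.type_codes == _TYPE_CODE[CellType.EPITHELIAL]
    oocyte = system.type_codes == _TYPE_CODE[CellType.OOCYTE_SURFACE]
    system.fixed = system.fixed | oocyte
    fix_applied = config.epithelium_fix_time <= eps_t
    if fix_applied:
        system.fixed = system.fixed | epithelial

    times = [0.0]
    frames = [system.positions.copy()]
    pairs = _build_pair_data(system, params, config)
    last_build = 0.0
    stopped = False

    for step in range(1, n_steps + 1):
        t = (step - 1) * config.dt  # time at the start of this step
        if not fix_applied and t >= config.epithelium_fix_time - eps_t:
            system.fixed = system.fixed | epithelial
            fix_applied = True
            pairs = _build_pair_data(system, params, config)
            last_build = t
        elif t - last_build >= config.neighbor_refresh - eps_t:
            pairs = _build_pair_data(system, params, config)
            last_build = t
        forces = _deterministic_forces(system, pairs, params, config, grad_field)
        if params.stochastic > 0:
            forces += params.stochastic * rng.standard_normal(system.positions.shape)
        free = ~system.fixed
        system.positions[free] += config.dt * forces[free]
        if not np.isfinite(system.positions).all():
            bad = int(np.where(~np.isfinite(system.positions).all(axis=1))[0][0])
            raise NumericalBlowupError(
                f"non-finite position for cell {system.ids[bad]} at step {step}"
            )
        t_now = step * config.dt
        if step % config.record_stride == 0 or step == n_steps:
            times.append(t_now)
            frames.append(system.positions.copy())
            if stop_when is not None and stop_when(t_now, system.positions):
                stopped = True
                break

    final_fixed = system.fixed | epithelial  # epithelium fixes during any long run
    snapshot = {
        "dt": config.dt,
        "duration": config.duration,
        "seed": config.seed,
        "neighbor_cutoff": config.neighbor_cutoff,
        "neighbor_refresh": config.neighbor_refresh,
        "epithelium_fix_time": config.epithelium_fix_time,
        "record_stride": config.record_stride,
        "dimension": config.dimension,
        "stopped_early": stopped,
    }
    return Trajectory(
        times=np.array(times),
        frames=np.array(frames),
        ids=system.ids.copy(),
        cell_types=system.cell_type_values,
        group_ids=system.group_ids.copy(),
        migratory=system.migratory.copy(),
        fixed=final_fixed,
        config=snapshot,
    )
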