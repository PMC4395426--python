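"""High-level run orchestration: from a resolved configuration to a
trajectory, with optional early stop on arrival at the oocyte."""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .analysis import ARRIVAL_CONTACT
from .config import RunConfig
from .core_model import CellType, IMCState
from .domain_builder import build_egg_chamber, from_planes
from .integrator import Trajectory, run_simulation

__all__ = ["initial_states", "arrival_stop", "simulate", "make_border_count_runner"]

logger = logging.getLogger(__name__)


def initial_states(config: RunConfig) -> list[IMCState]:
    """Build the initial condition: explicit planes when given,
    otherwise the egg-chamber preset of the domain block."""
    if config.planes is not None and config.planes.planes:
        return from_planes(config.planes)
    return build_egg_chamber(config.domain)


def arrival_stop(states: Sequence[IMCState], contact: float = ARRIVAL_CONTACT):
    """Early-termination predicate: any cluster cell within ``contact``
    diameters of the (fixed) oocyte layer."""
    oocyte = np.array(
        [s.position for s in states if s.cell_type is CellType.OOCYTE_SURFACE]
    )
    cluster = np.array(
        [
            i
            for i, s in enumerate(states)
            if s.cell_type in (CellType.BORDER, CellType.POLAR)
        ],
        dtype=int,
    )
    if oocyte.size == 0 or cluster.size == 0:
        return None
    tree = cKDTree(oocyte)

    def _stop(t: float, positions: np.ndarray) -> bool:
        d, _ = tree.query(positions[cluster], k=1)
        return bool(np.min(d) <= contact + 1e-12)

    return _stop


def simulate(
    config: RunConfig,
    seed: int | None = None,
    duration: float | None = None,
    n_border: int | None = None,
    record_stride: int | None = None,
    stop_on_arrival: bool = False,
) -> Trajectory:
    """Run one simulation described by a configuration, optionally
    overriding seed, duration, border-cell count or recording stride."""
    domain = config.domain
    if n_border is not None:
        domain = dataclasses.replace(domain, n_border=n_border)
        config = dataclasses.replace(config, domain=domain, planes=None)
    states = initial_states(config)
    sim = config.simulation
    overrides = {}
    if seed is not None:
        overrides["seed"] = int(seed)
    if duration is not None:
        overrides["duration"] = float(duration)
    if record_stride is not None:
        overrides["record_stride"] = int(record_stride)
    dim = states[0].dimension
    if sim.dimension != dim:
        overrides["dimension"] = dim
    if overrides:
        sim = dataclasses.replace(sim, **overrides)
    stop = arrival_stop(states) if stop_on_arrival else None
    logger.info(
        "simulating %d cells for %.3g time units (seed %d)",
        len(states),
        sim.duration,
        sim.seed,
    )
    return run_simulation(states, config.forces, sim, stop_when=stop)


def make_border_count_runner(
    config: RunConfig,
    duration_cap: float | None = None,
    record_stride: int | None = None,
):
    """A ``run_one(n_border, seed)`` callable for the border-cell-number
    sweep: identical parameters across counts, early stop on arrival,
    duration capped by the experiment block."""
    cap = duration_cap if duration_cap is not None else config.experiment.duration_cap

    def run_one(n_border: int, seed: int) -> Trajectory:
        return simulate(
            config,
            seed=seed,
            duration=cap,
            n_border=n_border,
            record_stride=record_stride,
            stop_on_arrival=True,
        )

    return run_one
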