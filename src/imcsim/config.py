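"""Run configuration files and trajectory persistence.

Configuration is a YAML mapping with optional blocks ``forces``,
``simulation``, ``domain`` (or ``planes``), ``output`` and
``experiment``; every omitted field takes the documented model default,
so an empty file is a complete, valid configuration.  Unknown keys are
rejected by name.

Trajectories are stored as plain CSV (one row per time and cell, nine
significant digits) with a JSON sidecar holding the config snapshot,
seed and fixed-cell ids, so a read-back reproduces the trajectory up to
float formatting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core_model import CellType, ForceParameters, PairAdhesionTable
from .domain_builder import DomainSpec, Plane, PlaneSpec
from .integrator import SimulationConfig, Trajectory

__all__ = [
    "RunConfig",
    "ExperimentConfig",
    "OutputConfig",
    "ConfigError",
    "TrajectoryParseError",
    "read_config",
    "write_config",
    "write_trajectory",
    "read_trajectory",
]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.9g"


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


class TrajectoryParseError(ValueError):
    """A trajectory file could not be parsed."""


@dataclass
class ExperimentConfig:
    """Border-cell-number sweep settings."""

    counts: list[int] = field(default_factory=lambda: [4, 6, 8])
    replicates: int = 3
    master_seed: int = 0
    duration_cap: float = 30.0

    def __post_init__(self) -> None:
        if not self.counts:
            raise ConfigError("experiment.counts must be non-empty")
        if self.replicates < 1:
            raise ConfigError("experiment.replicates must be >= 1")
        if self.duration_cap <= 0:
            raise ConfigError("experiment.duration_cap must be positive")


@dataclass
class OutputConfig:
    trajectory: str = "trajectory.csv"
    report: str = "report.csv"


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    forces: ForceParameters = field(default_factory=ForceParameters)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    domain: DomainSpec = field(default_factory=DomainSpec)
    planes: PlaneSpec | None = None
    output: OutputConfig = field(default_factory=OutputConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)


def _build_dataclass(cls, data: dict[str, Any], context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context}; "
            f"allowed: {sorted(names)}"
        )
    kwargs = dict(data)
    if "cross_section" in kwargs and kwargs["cross_section"] is not None:
        kwargs["cross_section"] = tuple(kwargs["cross_section"])
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as err:
        raise ConfigError(f"invalid {context}: {err}") from err


def _planes_from_data(data: Any) -> PlaneSpec:
    if not isinstance(data, dict):
        raise ConfigError("planes must be a mapping")
    allowed = {"dimension", "cross_section", "planes"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in planes")
    dimension = int(data.get("dimension", 3))
    cross = data.get("cross_section")
    cross = tuple(cross) if cross is not None else None
    planes = []
    for k, p in enumerate(data.get("planes", [])):
        if set(p) - {"axial", "entries"}:
            raise ConfigError(f"unknown key(s) in planes.planes[{k}]")
        entries = [
            (tuple(e[0]), CellType(e[1]), int(e[2])) for e in p.get("entries", [])
        ]
        planes.append(Plane(axial=float(p["axial"]), entries=entries))
    return PlaneSpec(planes=planes, dimension=dimension, cross_section=cross)


def _planes_to_data(spec: PlaneSpec) -> dict[str, Any]:
    return {
        "dimension": spec.dimension,
        "cross_section": list(spec.cross_section) if spec.cross_section else None,
        "planes": [
            {
                "axial": p.axial,
                "entries": [
                    [list(coords), CellType(t).value, int(g)]
                    for coords, t, g in p.entries
                ],
            }
            for p in spec.planes
        ],
    }


def config_from_dict(data: dict[str, Any] | None) -> RunConfig:
    """Validate a raw mapping and fill defaults."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    allowed = {"forces", "simulation", "domain", "planes", "output", "experiment"}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    forces_data = dict(data.get("forces", {}))
    if not isinstance(forces_data, dict):
        raise ConfigError("forces must be a mapping")
    adhesion_data = forces_data.pop("adhesion", {})
    adhesion = _build_dataclass(PairAdhesionTable, adhesion_data, "forces.adhesion")
    known = {f.name for f in dataclasses.fields(ForceParameters)} - {"adhesion"}
    unknown = set(forces_data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in forces")
    try:
        forces = ForceParameters(adhesion=adhesion, **forces_data)
    except ValueError as err:
        raise ConfigError(f"invalid forces: {err}") from err
    simulation = _build_dataclass(
        SimulationConfig, data.get("simulation", {}), "simulation"
    )
    domain = _build_dataclass(DomainSpec, data.get("domain", {}), "domain")
    planes = _planes_from_data(data["planes"]) if "planes" in data else None
    output = _build_dataclass(OutputConfig, data.get("output", {}), "output")
    experiment = _build_dataclass(
        ExperimentConfig, data.get("experiment", {}), "experiment"
    )
    return RunConfig(
        forces=forces,
        simulation=simulation,
        domain=domain,
        planes=planes,
        output=output,
        experiment=experiment,
    )


def config_to_dict(config: RunConfig) -> dict[str, Any]:
    data = {
        "forces": {
            **{
                f.name: getattr(config.forces, f.name)
                for f in dataclasses.fields(ForceParameters)
                if f.name != "adhesion"
            },
            "adhesion": dataclasses.asdict(config.forces.adhesion),
        },
        "simulation": dataclasses.asdict(config.simulation),
        "domain": {
            **dataclasses.asdict(config.domain),
            "cross_section": list(config.domain.cross_section),
        },
        "output": dataclasses.asdict(config.output),
        "experiment": dataclasses.asdict(config.experiment),
    }
    if config.planes is not None:
        data["planes"] = _planes_to_data(config.planes)
    return data


def read_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration; defaults fill every
    omitted field.  The fully resolved configuration is echoed to the
    log."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    config = config_from_dict(data)
    logger.info("resolved configuration from %s:\n%s", path, config_to_dict(config))
    return config


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# trajectory persistence
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV plus a JSON metadata sidecar.

    One row per (time, cell); columns time, imc_id, cell_type,
    group_id, x, y, z (z empty for 2D runs).
    """
    path = Path(path)
    n_frames, n_cells, dim = traj.frames.shape
    times = np.repeat(traj.times, n_cells)
    ids = np.tile(traj.ids, n_frames)
    types = np.tile(traj.cell_types, n_frames)
    groups = np.tile(traj.group_ids, n_frames)
    flat = traj.frames.reshape(n_frames * n_cells, dim)
    df = pd.DataFrame(
        {
            "time": times,
            "imc_id": ids,
            "cell_type": types,
            "group_id": groups,
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2] if dim == 3 else np.full(len(flat), np.nan),
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    meta = {
        "config": {k: _json_safe(v) for k, v in traj.config.items()},
        "fixed_ids": traj.ids[traj.fixed].tolist(),
        "dimension": int(dim),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def _json_safe(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (np.bool_,)):
        return bool(value)
    return value


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as err:  # pandas reports the offending line
        raise TrajectoryParseError(f"cannot parse {path}: {err}") from err
    required = {"time", "imc_id", "cell_type", "group_id", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise TrajectoryParseError(f"{path} lacks column(s) {sorted(missing)}")
    bad = df["x"].isna() | df["y"].isna() | df["time"].isna()
    if bad.any():
        line = int(np.where(bad)[0][0]) + 2  # header is line 1
        raise TrajectoryParseError(f"{path}: malformed row at line {line}")
    meta: dict[str, Any] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    dimension = int(meta.get("dimension", 2 if df["z"].isna().all() else 3))
    times = np.unique(df["time"].to_numpy())
    first = df[df["time"] == times[0]].sort_values("imc_id")
    ids = first["imc_id"].to_numpy(dtype=int)
    cell_types = first["cell_type"].to_numpy(dtype=object).astype(str)
    groups = first["group_id"].to_numpy(dtype=int)
    cols = ["x", "y", "z"][:dimension]
    df = df.sort_values(["time", "imc_id"], kind="stable")
    frames = df[cols].to_numpy(dtype=float).reshape(len(times), len(ids), dimension)
    fixed_ids = set(meta.get("fixed_ids", []))
    fixed = np.array([i in fixed_ids for i in ids], dtype=bool)
    migratory = np.array(
        [CellType(t).migratory for t in cell_types], dtype=bool
    )
    return Trajectory(
        times=times,
        frames=frames,
        ids=ids,
        cell_types=np.array(cell_types),
        group_ids=groups,
        migratory=migratory,
        fixed=fixed,
        config=meta.get("config", {}),
    )
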