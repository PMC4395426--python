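"""Migration summaries: arrival times, polar-cell lead tracking,
lead-switch counts, rotation angles, and the border-cell-number sweep.

Cluster rotation is quantified along the anterior->posterior axis only:
the relative lead ``l(t)`` of the two polar cells (their axial
separation, in micrometres) changes sign when the cluster tumbles.  A
"clear" lead switch is a sign change later confirmed by the lead
magnitude exceeding a threshold (0.1 cell diameters by default) before
the next sign change.  The maximal rotation angle is estimated from the
largest confirmed leads either way and the mean polar-cell
centre-to-centre distance:

    theta = arcsin(L+ / d_mean) + arcsin(L- / d_mean)

which maps maximal leads of +-1.4 um at the polar cells' typical
adhesion-repulsion equilibrium separation (~0.5 diameter) to roughly a
45-degree tumble.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_model import CellType, UnitSystem
from .integrator import Trajectory

__all__ = [
    "AnalysisError",
    "MigrationSummary",
    "detect_arrival",
    "relative_lead",
    "polar_separation",
    "count_lead_switches",
    "max_rotation_angle",
    "summarize_migration",
    "replicate_stats",
    "border_count_experiment",
    "replicate_seed",
]

logger = logging.getLogger(__name__)

#: contact distance (in diameters) defining arrival at the oocyte.
ARRIVAL_CONTACT = 1.0
#: lead-switch confirmation threshold, in diameters.
SWITCH_THRESHOLD_D = 0.1


class AnalysisError(ValueError):
    """A trajectory lacks the structure an analysis requires."""


@dataclass
class MigrationSummary:
    """Per-run migration measurements (physical units)."""

    arrival_time_h: float | None
    lead_times_h: np.ndarray
    lead_um: np.ndarray
    switch_count: int
    max_rotation_deg: float
    polar_axial_um: np.ndarray  # (T, 2) axial positions of the two polar cells
    mean_polar_separation_um: float

    @property
    def arrived(self) -> bool:
        return self.arrival_time_h is not None


def _polar_indices(traj: Trajectory) -> np.ndarray:
    idx = np.where(traj.type_mask(CellType.POLAR))[0]
    if idx.size != 2:
        raise AnalysisError(f"expected exactly 2 polar cells, found {idx.size}")
    # fixed sign convention: order by cell id
    return idx[np.argsort(traj.ids[idx])]


def detect_arrival(
    traj: Trajectory, contact_distance: float = ARRIVAL_CONTACT
) -> float | None:
    """Earliest recorded time (hours) at which any cluster cell touches
    the oocyte layer.

    Contact means a border or polar cell centre within ``contact_distance``
    diameters of any oocyte-surface cell centre.  Returns None when the
    cluster never arrives within the recorded trajectory.
    """
    oocyte = traj.type_mask(CellType.OOCYTE_SURFACE)
    if not oocyte.any():
        raise AnalysisError("trajectory has no oocyte-surface cells")
    cluster = traj.type_mask(CellType.BORDER) | traj.type_mask(CellType.POLAR)
    if not cluster.any():
        raise AnalysisError("trajectory has no cluster cells")
    # the oocyte layer is fixed; use its first-frame positions throughout
    from scipy.spatial import cKDTree

    tree = cKDTree(traj.frames[0][oocyte])
    for k, t in enumerate(traj.times):
        d, _ = tree.query(traj.frames[k][cluster], k=1)
        if np.min(d) <= contact_distance + 1e-12:
            return float(t)
    return None


def polar_separation(traj: Trajectory, units: UnitSystem | None = None) -> np.ndarray:
    """Centre-to-centre distance of the two polar cells per frame (um)."""
    units = units or UnitSystem()
    p1, p2 = _polar_indices(traj)
    sep = np.linalg.norm(traj.frames[:, p1, :] - traj.frames[:, p2, :], axis=1)
    return sep * units.length_um


def relative_lead(
    traj: Trajectory, units: UnitSystem | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Relative axial lead l(t) of the two polar cells, in micrometres.

    l(t) is the axial (anterior->posterior) coordinate of the lower-id
    polar cell minus that of the other; swapping the two ids negates
    the series.
    """
    units = units or UnitSystem()
    p1, p2 = _polar_indices(traj)
    lead = (traj.frames[:, p1, 0] - traj.frames[:, p2, 0]) * units.length_um
    return traj.times.copy(), lead


def _sign_segments(lead: np.ndarray) -> list[tuple[int, float]]:
    """Maximal runs of constant nonzero sign: (sign, max |l| in run)."""
    segments: list[tuple[int, float]] = []
    current_sign = 0
    current_max = 0.0
    for value in lead:
        s = int(np.sign(value))
        if s == 0:
            continue
        if s != current_sign:
            if current_sign != 0:
                segments.append((current_sign, current_max))
            current_sign = s
            current_max = abs(value)
        else:
            current_max = max(current_max, abs(value))
    if current_sign != 0:
        segments.append((current_sign, current_max))
    return segments


def count_lead_switches(lead: Sequence[float], threshold: float) -> int:
    """Number of clear lead switches in a relative-lead series.

    A switch is a sign change of the lead confirmed by |l| exceeding
    ``threshold`` (same units as the series) before the next sign
    change; unconfirmed wobbles around zero do not count.  The count is
    invariant under an overall sign flip and under time rescaling.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    lead = np.asarray(lead, dtype=float)
    if lead.size == 0:
        warnings.warn("empty lead series; returning 0 switches", stacklevel=2)
        return 0
    segments = _sign_segments(lead)
    confirmed_sign = 0
    count = 0
    for sign, peak in segments:
        if peak <= threshold:
            continue
        if confirmed_sign != 0 and sign != confirmed_sign:
            count += 1
        confirmed_sign = sign
    return count


def max_rotation_angle(
    lead: Sequence[float], separation: Sequence[float]
) -> float:
    """Maximal rotation angle (degrees) from a relative-lead series.

    ``theta = arcsin(L+/d) + arcsin(L-/d)`` where L+ and L- are the
    maximal leads of each polar cell (floored at zero) and d the
    time-mean polar separation, all in the same units.  Returns 0 when
    the lead never changes sign (no tumble); ratios above 1 are clipped
    with a warning.
    """
    lead = np.asarray(lead, dtype=float)
    separation = np.asarray(separation, dtype=float)
    if lead.size == 0 or separation.size == 0:
        raise AnalysisError("empty lead or separation series")
    if np.any(separation <= 0):
        raise AnalysisError("polar separations must be positive")
    signs = np.sign(lead)
    nonzero = signs[signs != 0]
    if nonzero.size == 0 or np.all(nonzero == nonzero[0]):
        return 0.0
    d_mean = float(np.mean(separation))
    l_plus = max(float(np.max(lead)), 0.0)
    l_minus = max(float(np.max(-lead)), 0.0)
    ratios = np.array([l_plus, l_minus]) / d_mean
    if np.any(ratios > 1.0):
        warnings.warn(
            "lead exceeds mean polar separation; clipping arcsine argument",
            stacklevel=2,
        )
        ratios = np.clip(ratios, 0.0, 1.0)
    return float(np.degrees(np.arcsin(ratios[0]) + np.arcsin(ratios[1])))


def summarize_migration(
    traj: Trajectory,
    units: UnitSystem | None = None,
    switch_threshold_d: float = SWITCH_THRESHOLD_D,
    contact_distance: float = ARRIVAL_CONTACT,
) -> MigrationSummary:
    """All per-run measurements for one trajectory."""
    units = units or UnitSystem()
    times, lead = relative_lead(traj, units)
    sep = polar_separation(traj, units)
    p1, p2 = _polar_indices(traj)
    axial = traj.frames[:, [p1, p2], 0] * units.length_um
    arrival = detect_arrival(traj, contact_distance=contact_distance)
    return MigrationSummary(
        arrival_time_h=arrival,
        lead_times_h=times,
        lead_um=lead,
        switch_count=count_lead_switches(lead, switch_threshold_d * units.length_um),
        max_rotation_deg=max_rotation_angle(lead, sep),
        polar_axial_um=axial,
        mean_polar_separation_um=float(np.mean(sep)),
    )


def replicate_stats(runs: Sequence[MigrationSummary]) -> pd.DataFrame:
    """Mean, SD and range of switch count, maximal rotation and arrival
    time over replicate runs (>= 2 required).

    Arrival statistics are computed over arrived runs only; the number
    of censored (non-arrived) runs is reported alongside.
    """
    if len(runs) < 2:
        raise AnalysisError("replicate statistics require at least 2 runs")
    rows = {}

    def _row(name, values):
        values = np.asarray(values, dtype=float)
        rows[name] = {
            "mean": float(np.mean(values)) if values.size else np.nan,
            "sd": float(np.std(values, ddof=1)) if values.size > 1 else np.nan,
            "min": float(np.min(values)) if values.size else np.nan,
            "max": float(np.max(values)) if values.size else np.nan,
            "n": int(values.size),
        }

    _row("switch_count", [r.switch_count for r in runs])
    _row("max_rotation_deg", [r.max_rotation_deg for r in runs])
    arrivals = [r.arrival_time_h for r in runs if r.arrived]
    _row("arrival_time_h", arrivals)
    df = pd.DataFrame(rows).T
    df.attrs["n_runs"] = len(runs)
    df.attrs["n_censored"] = len(runs) - len(arrivals)
    return df


def replicate_seed(master_seed: int, n_border: int, replicate: int) -> int:
    """Deterministic per-replicate seed derived from a master seed."""
    ss = np.random.SeedSequence((int(master_seed), int(n_border), int(replicate)))
    return int(ss.generate_state(1)[0] % (2**31))


def border_count_experiment(
    counts: Sequence[int],
    replicates: int,
    run_one: Callable[[int, int], Trajectory],
    master_seed: int = 0,
    units: UnitSystem | None = None,
) -> pd.DataFrame:
    """Migration time versus border-cell number.

    ``run_one(n_border, seed)`` must execute a simulation identical in
    every parameter except the border-cell count and return its
    trajectory.  Per count the mean arrival time (hours) over
    ``replicates`` seeded runs is reported, with runs that never arrive
    within their duration cap counted as censored; relative times are
    normalised to the fastest (largest) cluster.
    """
    if not counts:
        raise AnalysisError("counts must be non-empty")
    if replicates < 1:
        raise AnalysisError("need at least one replicate")
    units = units or UnitSystem()
    records = []
    for n_border in counts:
        arrivals = []
        censored = 0
        for rep in range(replicates):
            seed = replicate_seed(master_seed, n_border, rep)
            traj = run_one(n_border, seed)
            arrival = detect_arrival(traj)
            logger.info(
                "border-count run n=%d rep=%d seed=%d arrival=%s",
                n_border,
                rep,
                seed,
                arrival,
            )
            if arrival is None:
                censored += 1
            else:
                arrivals.append(arrival)
        records.append(
            {
                "n_border": int(n_border),
                "mean_arrival_h": float(np.mean(arrivals)) if arrivals else np.nan,
                "sd_arrival_h": (
                    float(np.std(arrivals, ddof=1)) if len(arrivals) > 1 else np.nan
                ),
                "n_arrived": len(arrivals),
                "n_censored": censored,
            }
        )
    df = pd.DataFrame.from_records(records).set_index("n_border")
    reference = df.loc[df.index.max(), "mean_arrival_h"]
    df["relative_time"] = df["mean_arrival_h"] / reference
    return df
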