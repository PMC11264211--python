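"""Water availability around a target carbon.

Three complementary views of active-site hydration: how many water oxygens
sit inside a spherical shell around the target per frame (occupancy
distribution, default 5.5 Å cutoff, closed ball), whether any water makes a
close approach (default 3.4 Å) that could quench a carbocation, and whether
a given water is mobile or "stuck" in a pocket (minimum sliding-window rms
displacement below a threshold).

Waters are counted by their oxygen atoms; hydrogens are ignored.  The
optional Mg-coordination exclusion drops waters within 2.6 Å of any Mg ion
and is off by default, so the headline occupancy is never silently altered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SiteSpecError
from .trajectory_io import (
    Frame,
    ResolvedSite,
    SiteSpec,
    Topology,
    Trajectory,
    max_safe_cutoff,
    minimum_image_distance_array,
)
from .cyclization_metrics import DistanceSeries

__all__ = [
    "OccupancyDistribution",
    "ApproachEvent",
    "MobilityScore",
    "waters_within",
    "occupancy_distribution",
    "approach_events",
    "approach_replica_summary",
    "water_mobility",
    "min_water_distance_series",
]

DEFAULT_SHELL_CUTOFF = 5.5
DEFAULT_APPROACH_CUTOFF = 3.4
MG_EXCLUSION_RADIUS = 2.6
DEFAULT_STUCK_THRESHOLD = 1.0
DEFAULT_MOBILITY_WINDOW = 50


@dataclass
class OccupancyDistribution:
    """Fraction of frames with exactly k in-shell waters, for every observed k."""

    probs: dict[int, float]
    n_frames: int
    cutoff: float
    excluded_waters: list[str]

    def fraction_with_at_least(self, k: int) -> float:
        return sum(v for c, v in self.probs.items() if c >= k)


@dataclass(frozen=True)
class ApproachEvent:
    frame: int
    water: str
    distance: float


@dataclass
class MobilityScore:
    water: str
    window: int
    rms_displacement: float
    stuck: bool


def _resolved(topology: Topology, site: SiteSpec | ResolvedSite) -> ResolvedSite:
    return site if isinstance(site, ResolvedSite) else ResolvedSite(topology, site)


def _check_cutoff(frame: Frame, cutoff: float) -> None:
    if frame.box is not None and cutoff > max_safe_cutoff(frame.box):
        raise ValueError(
            f"cutoff {cutoff} Å exceeds half the shortest cell height "
            f"({max_safe_cutoff(frame.box):.3f} Å); minimum-image counting "
            "would be ambiguous"
        )


def _mg_excluded(frame: Frame, rs: ResolvedSite, waters: list[int]) -> set[int]:
    mg = rs.many("mg_ions")
    excluded: set[int] = set()
    for m in mg:
        d = minimum_image_distance_array(frame, m, waters)
        excluded.update(np.asarray(waters)[d <= MG_EXCLUSION_RADIUS].tolist())
    return excluded


def waters_within(
    frame: Frame,
    topology: Topology,
    site: SiteSpec | ResolvedSite,
    target_role: str = "c11",
    cutoff: float = DEFAULT_SHELL_CUTOFF,
    exclude_mg_coordinated: bool = False,
) -> tuple[int, list[str]]:
    """Count water oxygens within *cutoff* (inclusive) of the target atom.

    Returns the count and the matching water identifiers.  With
    ``exclude_mg_coordinated`` waters within 2.6 Å of any Mg ion are dropped.
    """
    rs = _resolved(topology, site)
    target = rs.single(target_role)
    waters = rs.waters()
    if not waters:
        raise SiteSpecError("site spec water selector matches no atoms")
    _check_cutoff(frame, cutoff)
    excluded = _mg_excluded(frame, rs, waters) if exclude_mg_coordinated else set()
    kept = [w for w in waters if w not in excluded]
    if not kept:
        return 0, []
    d = minimum_image_distance_array(frame, target, kept)
    hits = [kept[i] for i in np.nonzero(d <= cutoff)[0]]
    return len(hits), [topology.atom_id(i) for i in hits]


def occupancy_distribution(
    traj: Trajectory,
    site: SiteSpec | ResolvedSite,
    cutoff: float = DEFAULT_SHELL_CUTOFF,
    target_role: str = "c11",
    exclude_mg_coordinated: bool = False,
) -> OccupancyDistribution:
    """Per-count fractions of frames; reports every observed count."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    rs = _resolved(traj.topology, site)
    counts = np.empty(traj.n_frames, dtype=int)
    all_excluded: set[str] = set()
    for f, frame in enumerate(traj.frames):
        k, _ = waters_within(
            frame, traj.topology, rs, target_role, cutoff, exclude_mg_coordinated
        )
        counts[f] = k
        if exclude_mg_coordinated:
            waters = rs.waters()
            for i in _mg_excluded(frame, rs, waters):
                all_excluded.add(traj.topology.atom_id(i))
    values, freq = np.unique(counts, return_counts=True)
    probs = {int(v): float(c) / traj.n_frames for v, c in zip(values, freq)}
    return OccupancyDistribution(
        probs=probs,
        n_frames=traj.n_frames,
        cutoff=cutoff,
        excluded_waters=sorted(all_excluded),
    )


def approach_events(
    traj: Trajectory,
    site: SiteSpec | ResolvedSite,
    target_role: str = "c3",
    cutoff: float = DEFAULT_APPROACH_CUTOFF,
) -> tuple[list[ApproachEvent], bool]:
    """All (frame, water) pairs at distance <= cutoff from the target.

    Returns the event list and a per-trajectory boolean (any event exists);
    replica booleans aggregate to "k of n" summaries via
    :func:`approach_replica_summary`.
    """
    rs = _resolved(traj.topology, site)
    target = rs.single(target_role)
    waters = rs.waters()
    if not waters:
        raise SiteSpecError("site spec water selector matches no atoms")
    events: list[ApproachEvent] = []
    for f, frame in enumerate(traj.frames):
        _check_cutoff(frame, cutoff)
        d = minimum_image_distance_array(frame, target, waters)
        for i in np.nonzero(d <= cutoff)[0]:
            events.append(
                ApproachEvent(
                    frame=f,
                    water=traj.topology.atom_id(waters[i]),
                    distance=float(d[i]),
                )
            )
    return events, bool(events)


def approach_replica_summary(
    replicas: Sequence[Trajectory],
    site: SiteSpec,
    target_role: str = "c3",
    cutoff: float = DEFAULT_APPROACH_CUTOFF,
) -> tuple[int, int]:
    """(k, n): number of replicas with at least one approach event, of n."""
    flags = [approach_events(t, site, target_role, cutoff)[1] for t in replicas]
    return sum(flags), len(flags)


def _water_index(topology: Topology, water: str | int) -> int:
    if isinstance(water, (int, np.integer)):
        if not 0 <= water < topology.n_atoms:
            raise IndexError(f"atom index {water} out of range")
        return int(water)
    for i in range(topology.n_atoms):
        if topology.atom_id(i) == water:
            return i
    raise IndexError(f"unknown water identifier {water!r}")


def water_mobility(
    traj: Trajectory,
    water: str | int,
    window: int = DEFAULT_MOBILITY_WINDOW,
    stuck_threshold: float = DEFAULT_STUCK_THRESHOLD,
) -> MobilityScore:
    """Minimum over sliding windows of the rms displacement from the window
    start; a persistently immobile water scores low and is flagged stuck.

    The minimum (not the maximum) is reported so that a water that is pinned
    for any full window counts as stuck even if it diffuses elsewhere.
    """
    if window < 2:
        raise ValueError("window must be >= 2 frames")
    if traj.n_frames < window:
        raise ValueError(
            f"trajectory has {traj.n_frames} frames, shorter than window {window}"
        )
    idx = _water_index(traj.topology, water)
    x = np.stack([f.coordinates[idx] for f in traj.frames])
    best = np.inf
    for t in range(traj.n_frames - window + 1):
        disp = x[t + 1 : t + window] - x[t]
        rms = float(np.sqrt(np.mean(np.sum(disp**2, axis=1))))
        best = min(best, rms)
    return MobilityScore(
        water=traj.topology.atom_id(idx),
        window=window,
        rms_displacement=best,
        stuck=best < stuck_threshold,
    )


def min_water_distance_series(
    traj: Trajectory,
    site: SiteSpec | ResolvedSite,
    target_role: str = "c3",
) -> DistanceSeries:
    """Per frame, the minimum water-oxygen distance to the target atom."""
    rs = _resolved(traj.topology, site)
    target = rs.single(target_role)
    waters = rs.waters()
    if not waters:
        raise ValueError("no waters in topology")
    values = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        values[f] = minimum_image_distance_array(frame, target, waters).min()
    return DistanceSeries(values=values, label=traj.label)
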