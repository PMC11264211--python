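"""Prochiral-face classification of water attack on a trigonal carbocation.

A trigonal-planar sp2 cation has two faces; water attack from one yields the
S configuration at the new stereocentre, from the other the R.  Geometry
alone cannot know which face is which — that depends on substituent
priorities — so the mapping from the signed face normal to the chemical
labels pre-S/pre-R is supplied explicitly as a :class:`FaceConvention`.

The face normal is the normalised cross product (s1-c) x (s2-c) of the first
two substituents in the convention's order (right-hand rule); a water on the
normal's positive side gets the convention's ``positive_face_label``.
Classification is refused ("undefined") for pyramidalised centres
(planarity deviation above threshold) and for grazing approaches nearly in
the substituent plane.  Hydrogen-bond partners near the attacking water are
labelled by role (diphosphate, engineered acid, other) to reproduce
coordination analyses; without water hydrogens in the topology the angle
criterion downgrades to distance-only with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, SiteSpecError
from .trajectory_io import (
    Frame,
    ResolvedSite,
    SiteSpec,
    Topology,
    Trajectory,
    minimum_image_distance_array,
    resolve_selection,
)
from .cyclization_metrics import DistanceSeries
from .hydration_metrics import (
    ApproachEvent,
    DEFAULT_APPROACH_CUTOFF,
    DEFAULT_MOBILITY_WINDOW,
    DEFAULT_STUCK_THRESHOLD,
    MobilityScore,
    approach_events,
    water_mobility,
)

__all__ = [
    "FaceConvention",
    "HBondPartner",
    "ClassifiedAttack",
    "AttackSummary",
    "face_normal",
    "classify_face",
    "hbond_partners",
    "coordination_label",
    "deprotonation_distances",
    "summarize_attacks",
]

PRE_S = "pre-S"
PRE_R = "pre-R"
UNDEFINED = "undefined"
_OPPOSITE = {PRE_S: PRE_R, PRE_R: PRE_S}

DEFAULT_PLANARITY_THRESHOLD = 0.25   # Å
DEFAULT_GRAZING_ANGLE = 15.0         # degrees above the substituent plane
DEFAULT_HBOND_DISTANCE = 3.5         # Å, heavy-atom
DEFAULT_HBOND_ANGLE = 120.0          # degrees, D-H...A


@dataclass(frozen=True)
class FaceConvention:
    """Maps the geometric face sign to the chemical labels pre-S/pre-R.

    ``substituents`` is the ordered triple of selectors for the atoms bonded
    to the centre; its order fixes the normal by the right-hand rule, and
    ``positive_face_label`` names the face on the normal's positive side.
    """

    center: str
    substituents: tuple[str, str, str]
    positive_face_label: str = PRE_S

    def __post_init__(self) -> None:
        if self.positive_face_label not in _OPPOSITE:
            raise ValueError(f"face label must be one of {sorted(_OPPOSITE)}")
        if len(self.substituents) != 3:
            raise ValueError("exactly three substituent selectors required")

    @classmethod
    def from_site(
        cls, site: SiteSpec, positive_face_label: str = PRE_S
    ) -> "FaceConvention":
        if len(site.c3_substituents) != 3:
            raise SiteSpecError("site spec lists no c3_substituents triple")
        return cls(
            center=site.c3,
            substituents=tuple(site.c3_substituents),
            positive_face_label=positive_face_label,
        )

    def resolve(self, topology: Topology) -> tuple[int, tuple[int, int, int]]:
        def one(sel: str) -> int:
            hits = resolve_selection(topology, sel)
            if len(hits) != 1:
                raise SiteSpecError(f"{sel!r} resolves to {len(hits)} atoms, need 1")
            return hits[0]

        center = one(self.center)
        subs = tuple(one(s) for s in self.substituents)
        if len({center, *subs}) != 4:
            raise SiteSpecError("centre and substituents must be 4 distinct atoms")
        return center, subs  # type: ignore[return-value]


@dataclass(frozen=True)
class HBondPartner:
    atom: str
    kind: str            # ppi | acid | other
    distance: float
    angle: float | None  # None in distance-only mode


@dataclass
class ClassifiedAttack:
    event: ApproachEvent
    face: str
    planarity_deviation: float
    partners: list[HBondPartner] = field(default_factory=list)


@dataclass
class AttackSummary:
    n_events: int
    n_classified: int
    face_counts: dict[str, int]
    frac_preS: float | None
    coordination_by_face: dict[str, dict[str, int]]
    events: list[ClassifiedAttack]
    attacking_water_mobility: dict[str, MobilityScore] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry

def face_normal(
    frame: Frame, center: int, substituents: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Unit normal of the substituent plane and the centre's out-of-plane
    displacement (planarity deviation, Å).

    The normal's sign follows the right-hand rule on the ordered triple:
    it is the normalised (s1-c) x (s2-c).
    """
    if len(substituents) != 3:
        raise ValueError("need exactly three substituents")
    if len({center, *substituents}) != 4:
        raise ValueError("centre and substituents must be distinct atoms")
    c = frame.coordinates[center]
    s1, s2, s3 = (frame.coordinates[i] for i in substituents)
    cross = np.cross(s1 - c, s2 - c)
    norm = np.linalg.norm(cross)
    if norm < 1e-8:
        raise DegenerateGeometryError("substituents are collinear with the centre")
    normal = cross / norm
    plane_n = np.cross(s2 - s1, s3 - s1)
    pn = np.linalg.norm(plane_n)
    if pn < 1e-8:
        raise DegenerateGeometryError("substituents are collinear")
    deviation = abs(float(np.dot(c - s1, plane_n / pn)))
    return normal, deviation


def classify_face(
    frame: Frame,
    topology: Topology,
    convention: FaceConvention,
    water: int | str,
    planarity_threshold: float = DEFAULT_PLANARITY_THRESHOLD,
    grazing_angle: float = DEFAULT_GRAZING_ANGLE,
) -> str:
    """Label the water's approach face, or ``undefined`` for ambiguous
    geometry (pyramidalised centre or in-plane grazing approach)."""
    center, subs = convention.resolve(topology)
    widx = _atom_index(topology, water)
    if widx in {center, *subs}:
        raise ValueError("water must be distinct from the centre atoms")
    normal, deviation = face_normal(frame, center, subs)
    if deviation > planarity_threshold:
        return UNDEFINED
    w = frame.coordinates[widx] - frame.coordinates[center]
    wn = np.linalg.norm(w)
    if wn < 1e-8:
        return UNDEFINED
    sin_elevation = float(np.dot(w, normal)) / wn
    if abs(sin_elevation) < math.sin(math.radians(grazing_angle)):
        return UNDEFINED
    label = convention.positive_face_label
    return label if sin_elevation > 0 else _OPPOSITE[label]


def _atom_index(topology: Topology, atom: int | str) -> int:
    if isinstance(atom, (int, np.integer)):
        if not 0 <= atom < topology.n_atoms:
            raise IndexError(f"atom index {atom} out of range")
        return int(atom)
    for i in range(topology.n_atoms):
        if topology.atom_id(i) == atom:
            return i
    raise IndexError(f"unknown atom identifier {atom!r}")


# ---------------------------------------------------------------------------
# hydrogen bonding

def _water_hydrogens(topology: Topology, widx: int) -> list[int]:
    wa = topology.atoms[widx]
    return [
        i
        for i, a in enumerate(topology.atoms)
        if a.residue_id == wa.residue_id
        and a.residue_name == wa.residue_name
        and a.chain == wa.chain
        and a.element.upper() == "H"
    ]


def hbond_partners(
    frame: Frame,
    topology: Topology,
    water: int | str,
    candidates: Sequence[tuple[int, str]],
    d_max: float = DEFAULT_HBOND_DISTANCE,
    angle_min: float = DEFAULT_HBOND_ANGLE,
) -> list[HBondPartner]:
    """Hydrogen-bond partners of the water among (atom index, kind) candidates.

    A candidate qualifies if the water-oxygen heavy-atom distance is <= d_max
    and, when the topology contains the water's hydrogens, the best
    O-H...acceptor angle at H is >= angle_min.  Without hydrogens the angle
    criterion is skipped (distance-only mode, ``angle=None``) with a warning.
    Angles use raw coordinates; distances are minimum-image.
    """
    widx = _atom_index(topology, water)
    if not candidates:
        return []
    hydrogens = _water_hydrogens(topology, widx)
    if not hydrogens:
        warnings.warn(
            "water has no hydrogens in the topology; "
            "hydrogen bonds use the distance criterion only",
            stacklevel=2,
        )
    idx = [c[0] for c in candidates]
    dists = minimum_image_distance_array(frame, widx, idx)
    partners: list[HBondPartner] = []
    for (cand, kind), dist in zip(candidates, dists):
        if dist > d_max:
            continue
        angle: float | None = None
        if hydrogens:
            best = 0.0
            for h in hydrogens:
                v1 = frame.coordinates[widx] - frame.coordinates[h]
                v2 = frame.coordinates[cand] - frame.coordinates[h]
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom < 1e-12:
                    continue
                cosang = np.clip(np.dot(v1, v2) / denom, -1.0, 1.0)
                best = max(best, math.degrees(math.acos(cosang)))
            if best < angle_min:
                continue
            angle = best
        partners.append(
            HBondPartner(
                atom=topology.atom_id(cand),
                kind=kind,
                distance=float(dist),
                angle=angle,
            )
        )
    return partners


def coordination_label(partners) -> str:
    """Collapse partner kinds to ppi_only / ppi_plus_acid / acid_only /
    uncoordinated."""
    if isinstance(partners, ClassifiedAttack):
        partners = partners.partners
    kinds = {p.kind for p in partners}
    has_ppi = "ppi" in kinds
    has_acid = "acid" in kinds
    if has_ppi and has_acid:
        return "ppi_plus_acid"
    if has_ppi:
        return "ppi_only"
    if has_acid:
        return "acid_only"
    return "uncoordinated"


# ---------------------------------------------------------------------------
# deprotonation geometry

def deprotonation_distances(traj: Trajectory, site: SiteSpec) -> DistanceSeries:
    """Per-frame minimum distance from any diphosphate oxygen to any C15
    proton — the competing proton-abstraction geometry."""
    rs = ResolvedSite(traj.topology, site)
    oxygens = rs.many("ppi_oxygens", require=True)
    protons = rs.many("c15_protons", require=True)
    values = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        values[f] = min(
            minimum_image_distance_array(frame, o, protons).min() for o in oxygens
        )
    return DistanceSeries(values=values, label=traj.label)


# ---------------------------------------------------------------------------
# aggregate

def summarize_attacks(
    traj: Trajectory,
    site: SiteSpec,
    convention: FaceConvention | None = None,
    cutoff: float = DEFAULT_APPROACH_CUTOFF,
    d_max: float = DEFAULT_HBOND_DISTANCE,
    angle_min: float = DEFAULT_HBOND_ANGLE,
    planarity_threshold: float = DEFAULT_PLANARITY_THRESHOLD,
    grazing_angle: float = DEFAULT_GRAZING_ANGLE,
    mobility_window: int = DEFAULT_MOBILITY_WINDOW,
    stuck_threshold: float = DEFAULT_STUCK_THRESHOLD,
    compute_mobility: bool = True,
) -> AttackSummary:
    """Classify every approach event by face, label its coordination
    partners, and score the mobility of each attacking water."""
    if cutoff <= 0:
        raise ValueError("approach cutoff must be > 0")
    if convention is None:
        convention = FaceConvention.from_site(site)
    rs = ResolvedSite(traj.topology, site)
    candidates = [(i, "ppi") for i in rs.many("ppi_oxygens")]
    candidates += [(i, "acid") for i in rs.many("acid_atoms")]

    raw_events, _ = approach_events(traj, rs, target_role="c3", cutoff=cutoff)
    classified: list[ClassifiedAttack] = []
    face_counts: dict[str, int] = {PRE_S: 0, PRE_R: 0, UNDEFINED: 0}
    coordination: dict[str, dict[str, int]] = {}
    for ev in raw_events:
        frame = traj.frames[ev.frame]
        face = classify_face(
            frame, traj.topology, convention, ev.water,
            planarity_threshold, grazing_angle,
        )
        partners = hbond_partners(
            frame, traj.topology, ev.water, candidates, d_max, angle_min
        )
        attack = ClassifiedAttack(
            event=ev,
            face=face,
            planarity_deviation=face_normal(
                frame, *convention.resolve(traj.topology)
            )[1],
            partners=partners,
        )
        classified.append(attack)
        face_counts[face] = face_counts.get(face, 0) + 1
        label = coordination_label(attack)
        coordination.setdefault(face, {})
        coordination[face][label] = coordination[face].get(label, 0) + 1

    n_classified = face_counts[PRE_S] + face_counts[PRE_R]
    frac = face_counts[PRE_S] / n_classified if n_classified else None
    mobility: dict[str, MobilityScore] = {}
    if compute_mobility and traj.n_frames >= mobility_window:
        for water in sorted({ev.water for ev in raw_events}):
            mobility[water] = water_mobility(
                traj, water, mobility_window, stuck_threshold
            )
    return AttackSummary(
        n_events=len(raw_events),
        n_classified=n_classified,
        face_counts=face_counts,
        frac_preS=frac,
        coordination_by_face=coordination,
        events=classified,
        attacking_water_mobility=mobility,
    )
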