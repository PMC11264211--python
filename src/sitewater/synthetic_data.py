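"""Synthetic trajectories with known statistical structure.

Every analysis stage in this package gets a parameter-recovery test without
running molecular dynamics: these generators draw per-frame latent variables
(a C1-C10 distance from a compact/extended two-Gaussian mixture, an in-shell
water count from a categorical distribution, a water-approach event with a
chosen prochiral face and coordination partners, stuck vs diffusive water
motion) and then place atoms so the latent value is realised exactly.  The
sampled latents are stored on ``Trajectory.metadata`` so tests can compare
analysis output against construction truth.

Randomness is counter-based: one Philox stream per (seed, variant, replica,
frame), so replicas are independent yet fully reproducible and frames can be
regenerated in isolation.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .trajectory_io import Atom, Frame, SiteSpec, Topology, Trajectory, infer_element

__all__ = [
    "CyclizationParams",
    "HydrationParams",
    "AttackParams",
    "MobilityParams",
    "SyntheticConfig",
    "generate_cyclization_trajectory",
    "generate_hydration_trajectory",
    "generate_carbocation_trajectory",
    "generate_variant_trajectory",
    "make_fixture_suite",
    "synthetic_sitespec",
]

# Geometry constants of the synthetic carbocation site (Å).
_SHELL_MIN = 2.6          # lower bound of the hydration shell
_BULK_GAP = 2.0           # bulk waters start this far beyond the cutoff
_BULK_WIDTH = 6.0
_APPROACH_LO, _APPROACH_HI = 2.5, 3.35   # keeps every approach inside 3.4 Å
_APPROACH_JITTER = 0.08   # bounded off-axis tilt; keeps PPi in H-bond range
_MOBILITY_RADIUS = 14.0   # mobility waters orbit this far from C3
_PARKED = np.array([0.0, 0.0, 30.0])     # attack water position between events


@dataclass(frozen=True)
class CyclizationParams:
    """Two-component mixture for the per-frame C1-C10 distance (Å)."""

    p_extended: float = 0.26
    mean_compact: float = 5.5
    sd_compact: float = 0.7
    mean_extended: float = 9.5
    sd_extended: float = 0.8

    def validate(self) -> None:
        if not 0.0 <= self.p_extended <= 1.0:
            raise ConfigError("p_extended must be in [0, 1]")
        if self.sd_compact <= 0 or self.sd_extended <= 0:
            raise ConfigError("mixture component sds must be > 0")

    def exceedance_probability(self, threshold: float = 8.0) -> float:
        """P(distance > threshold) under the mixture, from the Gaussian CDFs."""
        from scipy.stats import norm

        p = self.p_extended
        return float(
            (1 - p) * norm.sf(threshold, self.mean_compact, self.sd_compact)
            + p * norm.sf(threshold, self.mean_extended, self.sd_extended)
        )


@dataclass(frozen=True)
class HydrationParams:
    """Categorical in-shell water count around the probe carbon."""

    shell_probs: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.1, 1: 0.4, 2: 0.3, 3: 0.15, 4: 0.05}
    )
    cutoff: float = 5.5
    n_bulk_waters: int = 20

    def __post_init__(self) -> None:
        probs = {int(k): float(v) for k, v in dict(self.shell_probs).items()}
        object.__setattr__(self, "shell_probs", probs)

    def validate(self) -> None:
        probs = self.shell_probs
        if not probs:
            raise ConfigError("shell_probs may not be empty")
        if any(k < 0 for k in probs) or any(not 0 <= v <= 1 for v in probs.values()):
            raise ConfigError("shell_probs keys must be >= 0 and values in [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ConfigError("shell_probs must sum to 1")
        if self.cutoff <= _SHELL_MIN:
            raise ConfigError(f"cutoff must exceed the {_SHELL_MIN} Å shell floor")
        if max(probs) > self.n_bulk_waters:
            raise ConfigError("k_max exceeds the number of placed waters")


@dataclass(frozen=True)
class AttackParams:
    """Water-approach events to the trigonal-planar cationic carbon."""

    p_preS: float = 0.5
    approach_rate: float = 0.3
    approach_dist_mean: float = 3.0
    approach_dist_sd: float = 0.15
    p_coord_acid_given_preS: float = 0.6
    n_mobility_waters: int = 4

    def validate(self) -> None:
        for nm in ("p_preS", "approach_rate", "p_coord_acid_given_preS"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{nm} must be in [0, 1]")
        if self.approach_dist_sd <= 0:
            raise ConfigError("approach_dist_sd must be > 0")
        if not _APPROACH_LO < self.approach_dist_mean < _APPROACH_HI:
            raise ConfigError(
                f"approach_dist_mean must lie in ({_APPROACH_LO}, {_APPROACH_HI}) Å"
            )
        if self.n_mobility_waters < 0:
            raise ConfigError("n_mobility_waters must be >= 0")


@dataclass(frozen=True)
class MobilityParams:
    """Two water-mobility regimes: a stuck water sits at a fixed position,
    a mobile one travels ``diffusion_step`` Å per frame along a closed orbit
    around the site (constant speed, so window displacements have a closed
    form and the regimes stay cleanly separated)."""

    stuck_fraction: float = 0.25
    diffusion_step: float = 0.5

    def validate(self) -> None:
        if not 0.0 <= self.stuck_fraction <= 1.0:
            raise ConfigError("stuck_fraction must be in [0, 1]")
        if self.diffusion_step < 0:
            raise ConfigError("diffusion_step must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    n_frames: int = 1000
    n_replicas: int = 10
    seed: int = 0
    cyclization: CyclizationParams = field(default_factory=CyclizationParams)
    hydration: HydrationParams = field(default_factory=HydrationParams)
    attack: AttackParams = field(default_factory=AttackParams)
    mobility: MobilityParams = field(default_factory=MobilityParams)

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.n_replicas < 1:
            raise ConfigError("n_replicas must be >= 1")
        self.cyclization.validate()
        self.hydration.validate()
        self.attack.validate()
        self.mobility.validate()

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        kwargs = dict(data)
        for key, sub in (
            ("cyclization", CyclizationParams),
            ("hydration", HydrationParams),
            ("attack", AttackParams),
            ("mobility", MobilityParams),
        ):
            if key in kwargs and isinstance(kwargs[key], Mapping):
                kwargs[key] = sub(**kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# RNG plumbing

_SETUP_FRAME = 2**32  # pseudo-frame index for per-replica setup draws


def _variant_code(variant: str) -> int:
    return zlib.crc32(variant.encode("utf-8")) & 0xFFFFFFFF


def _frame_rng(seed: int, variant: str, replica: int, frame: int) -> np.random.Generator:
    key = (int(seed) << 64) | (_variant_code(variant) << 32) | (replica & 0xFFFFFFFF)
    return np.random.Generator(np.random.Philox(counter=frame << 64, key=key))


def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


# ---------------------------------------------------------------------------
# topology builders

def _atom(serial: int, name: str, resname: str, resid: int, chain: str = "A") -> Atom:
    return Atom(serial, name, resname, resid, chain, infer_element(name))


def _cyclization_atoms(serial0: int) -> list[Atom]:
    return [
        _atom(serial0, "C1", "FDP", 1),
        _atom(serial0 + 1, "C10", "FDP", 1),
    ]


def _hydration_atoms(serial0: int, n_waters: int) -> list[Atom]:
    atoms = [_atom(serial0, "C11", "FDP", 1)]
    for i in range(n_waters):
        atoms.append(_atom(serial0 + 1 + i, "O", "HOH", 101 + i, "W"))
    return atoms


# Trigonal-planar centre: three substituents 1.5 Å from C3 at 120° in the
# xy-plane; the +z side is the generator's pre-S face by construction.
_SUBSTITUENT_DIRS = np.array(
    [
        [1.0, 0.0, 0.0],
        [-0.5, math.sqrt(3) / 2, 0.0],
        [-0.5, -math.sqrt(3) / 2, 0.0],
    ]
)
_C15_LOCAL = 1.5 * _SUBSTITUENT_DIRS[2]
_H15_OFFSETS = np.array([[0.0, -1.1, 0.0], [-0.95, 0.55, 0.0], [0.95, 0.55, 0.0]])
_PPI_LOCAL = {"O1": np.array([2.6, 0.0, 2.9]),
              "O2": np.array([2.6, 0.0, -2.9]),
              "O3": np.array([4.0, 0.0, 0.0])}
_ACID_REST = {"OE1": np.array([-1.0, 4.5, 4.5]), "OE2": np.array([-2.0, 5.0, 5.0])}
_ACID_HB_DIR = np.array([-1.0, 1.5, 1.5]) / np.linalg.norm([-1.0, 1.5, 1.5])
_ACID_HB_DIST = 2.8


def _carbocation_atoms(serial0: int, n_mobility: int) -> list[Atom]:
    atoms = [
        _atom(serial0, "C3", "FDP", 1),
        _atom(serial0 + 1, "C2", "FDP", 1),
        _atom(serial0 + 2, "C4", "FDP", 1),
        _atom(serial0 + 3, "C15", "FDP", 1),
        _atom(serial0 + 4, "H15A", "FDP", 1),
        _atom(serial0 + 5, "H15B", "FDP", 1),
        _atom(serial0 + 6, "H15C", "FDP", 1),
        _atom(serial0 + 7, "O1", "POP", 2),
        _atom(serial0 + 8, "O2", "POP", 2),
        _atom(serial0 + 9, "O3", "POP", 2),
        _atom(serial0 + 10, "OE1", "GLU", 305),
        _atom(serial0 + 11, "OE2", "GLU", 305),
        _atom(serial0 + 12, "O", "HOH", 500, "W"),
    ]
    for i in range(n_mobility):
        atoms.append(_atom(serial0 + 13 + i, "O", "HOH", 601 + i, "W"))
    return atoms


def synthetic_sitespec() -> SiteSpec:
    """The SiteSpec matching the atom naming used by all generators here."""
    return SiteSpec(
        c1="name C1",
        c10="name C10",
        c11="name C11",
        c3="name C3",
        c3_substituents=("name C2", "name C4", "name C15"),
        c15_protons=("resname FDP and name H15A H15B H15C",),
        ppi_oxygens=("resname POP and name O1 O2 O3",),
        acid_atoms=("resname GLU and name OE1 OE2",),
        water_oxygens="resname HOH and element O",
        mg_ions=(),
    )


# ---------------------------------------------------------------------------
# per-frame coordinate blocks

def _cyclization_coords(rng, p: CyclizationParams):
    extended = rng.random() < p.p_extended
    mean, sd = (
        (p.mean_extended, p.sd_extended) if extended else (p.mean_compact, p.sd_compact)
    )
    d = rng.normal(mean, sd)
    while d <= 0:
        d = rng.normal(mean, sd)
    direction = _unit_vector(rng)
    coords = np.vstack([np.zeros(3), d * direction])
    return coords, d, extended


def _hydration_coords(rng, p: HydrationParams):
    counts = sorted(p.shell_probs)
    probs = np.array([p.shell_probs[k] for k in counts])
    k = int(rng.choice(counts, p=probs))
    coords = np.zeros((1 + p.n_bulk_waters, 3))
    for w in range(p.n_bulk_waters):
        if w < k:
            r = rng.uniform(_SHELL_MIN, p.cutoff)
        else:
            r = rng.uniform(p.cutoff + _BULK_GAP, p.cutoff + _BULK_GAP + _BULK_WIDTH)
        coords[1 + w] = r * _unit_vector(rng)
    return coords, k


def _mobility_setup(config: SyntheticConfig, variant: str, replica: int):
    n = config.attack.n_mobility_waters
    rng = _frame_rng(config.seed, variant, replica, _SETUP_FRAME)
    stuck = rng.random(n) < config.mobility.stuck_fraction
    phases = 2 * math.pi * (np.arange(n) + rng.random()) / max(n, 1)
    return stuck, phases


def _mobility_positions(frame: int, phases, stuck, step: float) -> np.ndarray:
    # Mobile waters orbit at constant speed `step` Å/frame on a circle of
    # radius _MOBILITY_RADIUS in the z=3 plane; stuck waters stay at phase 0.
    omega = step / _MOBILITY_RADIUS
    theta = np.where(stuck, phases, phases + omega * frame)
    return np.stack(
        [
            _MOBILITY_RADIUS * np.cos(theta),
            _MOBILITY_RADIUS * np.sin(theta),
            np.full(len(phases), 3.0),
        ],
        axis=1,
    )


def _carbocation_coords(rng, p: AttackParams, mobility_block):
    n_atoms = 13 + mobility_block.shape[0]
    coords = np.zeros((n_atoms, 3))
    coords[1:4] = 1.5 * _SUBSTITUENT_DIRS
    coords[4:7] = _C15_LOCAL + _H15_OFFSETS
    coords[7] = _PPI_LOCAL["O1"]
    coords[8] = _PPI_LOCAL["O2"]
    coords[9] = _PPI_LOCAL["O3"]
    coords[10] = _ACID_REST["OE1"]
    coords[11] = _ACID_REST["OE2"]

    approach = rng.random() < p.approach_rate
    face = 0
    dist = math.nan
    acid = False
    if approach:
        face = 1 if rng.random() < p.p_preS else -1
        dist = rng.normal(p.approach_dist_mean, p.approach_dist_sd)
        while not (_APPROACH_LO <= dist <= _APPROACH_HI):
            dist = rng.normal(p.approach_dist_mean, p.approach_dist_sd)
        jitter = rng.uniform(-_APPROACH_JITTER, _APPROACH_JITTER, size=2)
        direction = np.array([jitter[0], jitter[1], float(face)])
        direction /= np.linalg.norm(direction)
        water = dist * direction
        coords[12] = water
        if face == 1 and rng.random() < p.p_coord_acid_given_preS:
            acid = True
            coords[10] = water + _ACID_HB_DIST * _ACID_HB_DIR
    else:
        coords[12] = _PARKED

    coords[13:] = mobility_block
    return coords, approach, face, dist, acid


# ---------------------------------------------------------------------------
# public generators

_BLOCKS = ("cyclization", "hydration", "carbocation")
_OFFSETS = {"cyclization": np.zeros(3),
            "hydration": np.array([60.0, 0.0, 0.0]),
            "carbocation": np.array([120.0, 0.0, 0.0])}


def _generate(config: SyntheticConfig, variant: str, replica: int,
              blocks: tuple[str, ...]) -> Trajectory:
    config.validate()
    if not 0 <= replica < config.n_replicas:
        raise ConfigError(f"replica {replica} outside 0..{config.n_replicas - 1}")
    single = len(blocks) == 1

    atoms: list[Atom] = []
    starts: dict[str, int] = {}
    for b in blocks:
        starts[b] = len(atoms)
        if b == "cyclization":
            atoms += _cyclization_atoms(len(atoms) + 1)
        elif b == "hydration":
            atoms += _hydration_atoms(len(atoms) + 1, config.hydration.n_bulk_waters)
        else:
            atoms += _carbocation_atoms(len(atoms) + 1, config.attack.n_mobility_waters)
    topology = Topology(tuple(atoms))

    meta: dict = {"variant": variant, "replica": replica}
    if "cyclization" in blocks:
        meta["c1_c10_distance"] = np.empty(config.n_frames)
        meta["extended"] = np.empty(config.n_frames, dtype=bool)
    if "hydration" in blocks:
        meta["shell_counts"] = np.empty(config.n_frames, dtype=int)
    if "carbocation" in blocks:
        meta["approach"] = np.empty(config.n_frames, dtype=bool)
        meta["face"] = np.zeros(config.n_frames, dtype=int)
        meta["approach_distance"] = np.full(config.n_frames, math.nan)
        meta["acid_coordinated"] = np.zeros(config.n_frames, dtype=bool)
        stuck, phases = _mobility_setup(config, variant, replica)
        meta["mobility_stuck"] = stuck.copy()
        meta["attack_water"] = "HOH:500:O"
        meta["mobility_waters"] = [f"HOH:{601 + i}:O" for i in range(len(stuck))]

    frames: list[Frame] = []
    for f in range(config.n_frames):
        rng = _frame_rng(config.seed, variant, replica, f)
        coords = np.empty((topology.n_atoms, 3))
        for b in blocks:
            off = np.zeros(3) if single else _OFFSETS[b]
            s = starts[b]
            if b == "cyclization":
                block, d, ext = _cyclization_coords(rng, config.cyclization)
                meta["c1_c10_distance"][f] = d
                meta["extended"][f] = ext
            elif b == "hydration":
                block, k = _hydration_coords(rng, config.hydration)
                meta["shell_counts"][f] = k
            else:
                mob_block = _mobility_positions(
                    f, phases, stuck, config.mobility.diffusion_step
                )
                block, app, face, dist, acid = _carbocation_coords(
                    rng, config.attack, mob_block
                )
                meta["approach"][f] = app
                meta["face"][f] = face
                meta["approach_distance"][f] = dist
                meta["acid_coordinated"][f] = acid
            coords[s : s + block.shape[0]] = block + off
        frames.append(Frame(coordinates=coords, time=float(f)))
    label = f"{variant}/rep{replica}"
    return Trajectory(topology=topology, frames=frames, label=label, metadata=meta)


def generate_cyclization_trajectory(
    config: SyntheticConfig, replica: int = 0, variant: str = "synthetic"
) -> Trajectory:
    """C1/C10 pair with a per-frame distance drawn from the two-Gaussian
    compact/extended mixture, realised along a random direction."""
    return _generate(config, variant, replica, ("cyclization",))


def generate_hydration_trajectory(
    config: SyntheticConfig, replica: int = 0, variant: str = "synthetic"
) -> Trajectory:
    """Probe carbon C11 plus bulk waters; the in-shell count in
    [2.6 Å, cutoff] follows ``shell_probs`` exactly by construction."""
    return _generate(config, variant, replica, ("hydration",))


def generate_carbocation_trajectory(
    config: SyntheticConfig, replica: int = 0, variant: str = "synthetic"
) -> Trajectory:
    """Trigonal-planar C3 with substituents, PPi oxygens, acid side-chain
    oxygens, an attack water approaching a chosen prochiral face, and
    stuck/diffusive mobility waters."""
    return _generate(config, variant, replica, ("carbocation",))


def generate_variant_trajectory(
    config: SyntheticConfig, replica: int = 0, variant: str = "synthetic"
) -> Trajectory:
    """All three subsystems in one trajectory, spatially separated so the
    metrics never cross-count each other's waters."""
    return _generate(config, variant, replica, _BLOCKS)


def make_fixture_suite(
    configs: Mapping[str, SyntheticConfig] | SyntheticConfig,
) -> dict[str, list[Trajectory]]:
    """Replica sets for one or more synthetic variants.

    Mirrors a study design of n independent replicas per enzyme variant;
    labels encode variant and replica, and the whole suite is reproducible
    from the per-variant seeds.
    """
    if isinstance(configs, SyntheticConfig):
        configs = {"synthetic": configs}
    if not configs:
        raise ConfigError("no variants given")
    suite: dict[str, list[Trajectory]] = {}
    for variant, cfg in configs.items():
        cfg.validate()
        suite[variant] = [
            generate_variant_trajectory(cfg, replica=r, variant=variant)
            for r in range(cfg.n_replicas)
        ]
    return suite
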