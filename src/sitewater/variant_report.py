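"""Per-variant aggregation and triage.

A candidate variant is worth taking to the bench when its simulations say
the substrate still reaches cyclization-competent conformations AND water
remains available near the reaction centre.  This module runs the
cyclization, hydration and (optionally) attack stages over a replica set,
stores the aggregate numbers, applies explicit thresholds to produce the
two triage flags, ranks variants deterministically, and writes
machine-readable reports that round-trip losslessly.

The two triage fractions (maximum extended-conformation fraction, minimum
fraction of frames with water in the shell) are this package's defaults and
are exposed in :class:`Thresholds`; the distance cutoffs they combine with
(8.0, 5.5, 3.4 Å) are the field-standard ones for this system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import SiteSpecError
from .trajectory_io import SiteSpec, Trajectory
from .cyclization_metrics import (
    CyclizationSummary,
    aggregate_cyclization,
    distance_series,
)
from .hydration_metrics import (
    OccupancyDistribution,
    approach_replica_summary,
    occupancy_distribution,
)
from .attack_geometry import (
    PRE_R,
    PRE_S,
    UNDEFINED,
    AttackSummary,
    FaceConvention,
    summarize_attacks,
)

__all__ = [
    "Thresholds",
    "VariantMetrics",
    "compute_variant_metrics",
    "compute_flags",
    "rank_variants",
    "write_report",
    "read_report",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Thresholds:
    cyclization_extended_max: float = 0.15
    occupancy_min_frames_with_water: float = 0.5
    approach_cutoff: float = 3.4
    shell_cutoff: float = 5.5
    extended_distance: float = 8.0

    def __post_init__(self) -> None:
        if not 0 <= self.cyclization_extended_max <= 1:
            raise ValueError("cyclization_extended_max must be in [0, 1]")
        if not 0 <= self.occupancy_min_frames_with_water <= 1:
            raise ValueError("occupancy_min_frames_with_water must be in [0, 1]")
        if min(self.approach_cutoff, self.shell_cutoff, self.extended_distance) <= 0:
            raise ValueError("distance cutoffs must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VariantMetrics:
    """Aggregated per-variant summary feeding the triage report."""

    variant: str
    n_replicas: int
    n_frames: int
    cyclization_fraction: float
    cyclization_ci: tuple[float, float]
    cyclization_per_replica: list[float]
    cyclization_sd: float
    occupancy_probs: dict[int, float]
    frac_frames_with_water: float
    approach_k: int
    approach_n: int
    attack: dict | None
    cyclization_competent: bool
    water_available: bool

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "n_replicas": self.n_replicas,
            "n_frames": self.n_frames,
            "cyclization_fraction": self.cyclization_fraction,
            "cyclization_ci": list(self.cyclization_ci),
            "cyclization_per_replica": list(self.cyclization_per_replica),
            "cyclization_sd": self.cyclization_sd,
            "occupancy_probs": {str(k): v for k, v in self.occupancy_probs.items()},
            "frac_frames_with_water": self.frac_frames_with_water,
            "approach_k": self.approach_k,
            "approach_n": self.approach_n,
            "attack": self.attack,
            "cyclization_competent": self.cyclization_competent,
            "water_available": self.water_available,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariantMetrics":
        return cls(
            variant=d["variant"],
            n_replicas=d["n_replicas"],
            n_frames=d["n_frames"],
            cyclization_fraction=d["cyclization_fraction"],
            cyclization_ci=tuple(d["cyclization_ci"]),
            cyclization_per_replica=list(d["cyclization_per_replica"]),
            cyclization_sd=d["cyclization_sd"],
            occupancy_probs={int(k): v for k, v in d["occupancy_probs"].items()},
            frac_frames_with_water=d["frac_frames_with_water"],
            approach_k=d["approach_k"],
            approach_n=d["approach_n"],
            attack=d["attack"],
            cyclization_competent=d["cyclization_competent"],
            water_available=d["water_available"],
        )


def compute_flags(
    cyclization_fraction: float,
    frac_frames_with_water: float,
    thresholds: Thresholds,
) -> tuple[bool, bool]:
    """(cyclization_competent, water_available) from the stored metrics."""
    return (
        cyclization_fraction <= thresholds.cyclization_extended_max,
        frac_frames_with_water >= thresholds.occupancy_min_frames_with_water,
    )


def _merge_attack(summaries: Sequence[AttackSummary]) -> dict | None:
    if not summaries:
        return None
    face_counts: dict[str, int] = {PRE_S: 0, PRE_R: 0, UNDEFINED: 0}
    coordination: dict[str, dict[str, int]] = {}
    n_events = 0
    n_stuck = 0
    for s in summaries:
        n_events += s.n_events
        for face, c in s.face_counts.items():
            face_counts[face] = face_counts.get(face, 0) + c
        for face, table in s.coordination_by_face.items():
            dst = coordination.setdefault(face, {})
            for lab, c in table.items():
                dst[lab] = dst.get(lab, 0) + c
        n_stuck += sum(m.stuck for m in s.attacking_water_mobility.values())
    n_classified = face_counts[PRE_S] + face_counts[PRE_R]
    return {
        "n_events": n_events,
        "n_classified": n_classified,
        "face_counts": face_counts,
        "frac_preS": (face_counts[PRE_S] / n_classified) if n_classified else None,
        "coordination_by_face": coordination,
        "n_stuck_attacking_waters": n_stuck,
    }


def compute_variant_metrics(
    variant: str,
    replicas: Sequence[Trajectory],
    site: SiteSpec,
    thresholds: Thresholds = Thresholds(),
    convention: FaceConvention | None = None,
) -> VariantMetrics:
    """Run all analysis stages over one variant's replica set.

    The attack stage runs only when a face convention is supplied (it
    requires the substituent-order stereochemistry the user must assert).
    """
    if not replicas:
        raise ValueError(f"variant {variant!r}: empty replica set")
    try:
        series = [distance_series(t, site) for t in replicas]
        cyc: CyclizationSummary = aggregate_cyclization(
            series, threshold=thresholds.extended_distance
        )
        occ_per_replica = [
            occupancy_distribution(t, site, cutoff=thresholds.shell_cutoff)
            for t in replicas
        ]
        k, n = approach_replica_summary(
            replicas, site, cutoff=thresholds.approach_cutoff
        )
        attack = None
        if convention is not None:
            attack = _merge_attack(
                [
                    summarize_attacks(
                        t, site, convention, cutoff=thresholds.approach_cutoff
                    )
                    for t in replicas
                ]
            )
    except SiteSpecError as exc:
        raise SiteSpecError(f"variant {variant!r}: {exc}") from exc

    # pool occupancy across replicas, weighted by frame counts
    total_frames = sum(o.n_frames for o in occ_per_replica)
    pooled: dict[int, float] = {}
    for o in occ_per_replica:
        for c, p in o.probs.items():
            pooled[c] = pooled.get(c, 0.0) + p * o.n_frames / total_frames
    frac_with_water = sum(p for c, p in pooled.items() if c >= 1)

    competent, watered = compute_flags(cyc.pooled.fraction, frac_with_water, thresholds)
    return VariantMetrics(
        variant=variant,
        n_replicas=len(replicas),
        n_frames=total_frames,
        cyclization_fraction=cyc.pooled.fraction,
        cyclization_ci=(cyc.pooled.ci_low, cyc.pooled.ci_high),
        cyclization_per_replica=[f.fraction for f in cyc.per_replica],
        cyclization_sd=cyc.across_replica_sd,
        occupancy_probs=dict(sorted(pooled.items())),
        frac_frames_with_water=frac_with_water,
        approach_k=k,
        approach_n=n,
        attack=attack,
        cyclization_competent=competent,
        water_available=watered,
    )


def rank_variants(metrics: Sequence[VariantMetrics]) -> pd.DataFrame:
    """Deterministic triage table: water-available variants first, then by
    ascending extended-conformation fraction, ties broken by name."""
    if not metrics:
        raise ValueError("no variants to rank")
    rows = [
        {
            "variant": m.variant,
            "n_replicas": m.n_replicas,
            "n_frames": m.n_frames,
            "cyclization_fraction": m.cyclization_fraction,
            "ci_low": m.cyclization_ci[0],
            "ci_high": m.cyclization_ci[1],
            "frac_frames_with_water": m.frac_frames_with_water,
            "approach_k": m.approach_k,
            "approach_n": m.approach_n,
            "frac_preS": (m.attack or {}).get("frac_preS"),
            "cyclization_competent": m.cyclization_competent,
            "water_available": m.water_available,
        }
        for m in metrics
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["water_available", "cyclization_fraction", "variant"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def write_report(
    metrics: Sequence[VariantMetrics],
    outdir: str | Path,
    thresholds: Thresholds = Thresholds(),
) -> tuple[Path, Path]:
    """Write ``variants.csv`` (ranked flat table) and ``variants.json``
    (full metrics, schema-versioned).  Output is byte-stable: identical
    inputs produce identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "variants.csv"
    json_path = outdir / "variants.json"
    table = rank_variants(metrics)
    table.to_csv(csv_path, index=False, lineterminator="\n")
    payload = {
        "schema_version": SCHEMA_VERSION,
        "thresholds": thresholds.to_dict(),
        "variants": [m.to_dict() for m in metrics],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return csv_path, json_path


def read_report(json_path: str | Path) -> tuple[list[VariantMetrics], Thresholds]:
    with open(json_path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema {payload.get('schema_version')!r}"
        )
    thresholds = Thresholds(**payload["thresholds"])
    return [VariantMetrics.from_dict(d) for d in payload["variants"]], thresholds
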