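"""Shared builders for hand-constructed toy systems."""

from __future__ import annotations

import numpy as np

from sitewater import Atom, Frame, Topology, Trajectory
from sitewater.trajectory_io import infer_element


def toy_topology(entries) -> Topology:
    """Build a topology from (name, resname, resid[, chain]) tuples."""
    atoms = []
    for i, entry in enumerate(entries):
        name, resname, resid = entry[:3]
        chain = entry[3] if len(entry) > 3 else "A"
        atoms.append(
            Atom(i + 1, name, resname, resid, chain, infer_element(name) or "X")
        )
    return Topology(tuple(atoms))


def toy_trajectory(topology: Topology, coords_per_frame, label="toy") -> Trajectory:
    frames = [Frame(coordinates=np.asarray(c, dtype=float)) for c in coords_per_frame]
    return Trajectory(topology=topology, frames=frames, label=label)


def brute_force_min_image(d: np.ndarray, box: np.ndarray) -> float:
    """Independent oracle: minimum over the 27 neighbour translates."""
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                best = min(
                    best, float(np.linalg.norm(d + i * box[0] + j * box[1] + k * box[2]))
                )
    return best


def random_triclinic_cell(rng: np.random.Generator) -> np.ndarray:
    """A moderately skewed triclinic cell (reduced enough for 27-translate
    searches to be exact)."""
    box = np.diag(rng.uniform(8.0, 15.0, 3))
    box[1, 0], box[2, 0], box[2, 1] = rng.uniform(-3.0, 3.0, 3)
    return box


# A planar trigonal toy: centre at origin, three substituents at 120 degrees
# in the xy-plane, right-hand normal +z.
TRIGONAL_SUBS = np.array(
    [
        [1.0, 0.0, 0.0],
        [-0.5, np.sqrt(3) / 2, 0.0],
        [-0.5, -np.sqrt(3) / 2, 0.0],
    ]
)


def trigonal_frame(water_pos, center_lift=0.0) -> tuple[Topology, Frame]:
    """Centre + 3 substituents + one water oxygen, optionally pyramidalised."""
    top = toy_topology(
        [
            ("C3", "LIG", 1),
            ("S1", "LIG", 1),
            ("S2", "LIG", 1),
            ("S3", "LIG", 1),
            ("O", "HOH", 2, "W"),
        ]
    )
    coords = np.vstack(
        [np.array([0.0, 0.0, center_lift]), TRIGONAL_SUBS, np.asarray(water_pos)]
    )
    return top, Frame(coordinates=coords)
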