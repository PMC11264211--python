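"""Topology/trajectory containers, atom-role selections, and periodic distances.

Coordinates are Ångström throughout; XTC files (stored in nm) are converted
at read time.  Atom addressing in configs and reports uses PDB serials or
(residue id, atom name); 0-based positional indices are internal only.

The minimum-image distance searches the 27 neighbour translates of the
fractionally wrapped displacement, which is exact for distances below half
the shortest cell height; :func:`max_safe_cutoff` exposes that bound so
cutoff-based callers can refuse unsafe cells.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import (
    ConsistencyError,
    FormatError,
    SelectionError,
    SiteSpecError,
)

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "SiteSpec",
    "ResolvedSite",
    "load_topology",
    "load_trajectory",
    "write_trajectory",
    "resolve_selection",
    "minimum_image_distance",
    "minimum_image_distance_array",
    "max_safe_cutoff",
    "infer_element",
]

# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain: str
    element: str


@dataclass(frozen=True)
class Topology:
    """An ordered list of atoms; order is the coordinate order of all frames."""

    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ConsistencyError("atom serials must be unique")
        for a in self.atoms:
            if not a.element:
                raise ConsistencyError(f"atom serial {a.serial} has empty element")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_id(self, index: int) -> str:
        """Stable external identifier 'RESNAME:RESID:NAME' for atom *index*."""
        a = self.atoms[index]
        return f"{a.residue_name}:{a.residue_id}:{a.name}"

    def index_of(self, residue_id: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.residue_id == residue_id and a.name == name:
                return i
        raise KeyError(f"no atom ({residue_id}, {name!r})")


@dataclass
class Frame:
    """Per-atom coordinates (n, 3) in Å with an optional triclinic cell.

    ``box`` rows are the cell vectors a, b, c; ``time`` is picoseconds.
    """

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ConsistencyError("coordinates must have shape (n_atoms, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3, 3):
                raise ConsistencyError("box must be a 3x3 cell-vector matrix")
            if abs(np.linalg.det(self.box)) < 1e-9:
                raise ConsistencyError("box cell vectors are linearly dependent")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """A topology plus an ordered frame sequence and a variant/replica label.

    ``metadata`` carries generator latents for synthetic trajectories (the
    sampled distances, shell counts, approach faces, ...) so analyses can be
    checked against construction truth; file loaders leave it empty.
    """

    topology: Topology
    frames: list[Frame]
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ConsistencyError("a trajectory needs at least one frame")
        n = self.topology.n_atoms
        for k, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ConsistencyError(
                    f"frame {k} has {f.n_atoms} atoms, topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def coords(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])


# ---------------------------------------------------------------------------
# element inference

_TWO_LETTER = {
    "MG", "CL", "NA", "ZN", "FE", "BR", "MN", "CU", "NI", "SE", "CO", "LI",
}


def infer_element(name: str) -> str:
    """Guess an element symbol from a PDB atom name.

    Leading digits are stripped ('1HB' → H); whole names matching a common
    ion/two-letter element (MG, CL, ...) take that element, otherwise the
    first alphabetic character wins ('C1' → C, 'OW' → O).
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    upper = stripped.upper()
    if upper in _TWO_LETTER:
        return upper.capitalize()
    for ch in upper:
        if ch.isalpha():
            return ch
    return ""


# ---------------------------------------------------------------------------
# loading / writing

_WATER_RESNAMES = ("HOH", "WAT", "TIP3", "SOL")


def _dims_to_box(dimensions) -> np.ndarray | None:
    if dimensions is None:
        return None
    dims = np.asarray(dimensions, dtype=float)
    if dims.size < 6 or np.all(dims[:3] == 0):
        return None
    from MDAnalysis.lib.mdamath import triclinic_vectors

    return np.asarray(triclinic_vectors(dims), dtype=float)


def load_topology(path: str | Path, format: str = "pdb") -> Topology:
    """Read a topology from a PDB file.

    Atom order, serials, names, residues and chains follow the file; a blank
    element column falls back to :func:`infer_element` on the atom name.
    """
    path = Path(path)
    if format.lower() != "pdb":
        raise ValueError(f"unsupported topology format {format!r}")
    if not path.exists():
        raise IOError(f"topology file not found: {path}")
    import MDAnalysis as mda
    from MDAnalysis.exceptions import NoDataError

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format="PDB", to_guess=())
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    except Exception as exc:  # noqa: BLE001 - parser failures become FormatError
        raise FormatError(f"cannot parse {path} as PDB: {exc}") from exc
    n = len(u.atoms)
    if n == 0:
        raise FormatError(f"{path} contains no atoms")

    def attr(name, default):
        try:
            return list(getattr(u.atoms, name))
        except (NoDataError, AttributeError):
            return [default] * n

    serials = attr("ids", 0)
    if all(s == 0 for s in serials):
        serials = list(range(1, n + 1))
    names = attr("names", "")
    resnames = attr("resnames", "UNK")
    resids = attr("resids", 1)
    chains = attr("chainIDs", "")
    try:
        elements = [str(e).strip() for e in u.atoms.elements]
    except (NoDataError, AttributeError):
        elements = [""] * n
    atoms = []
    for i in range(n):
        elem = elements[i] or infer_element(names[i])
        if not elem:
            raise FormatError(
                f"cannot infer element for atom serial {serials[i]} ({names[i]!r})"
            )
        atoms.append(
            Atom(
                serial=int(serials[i]),
                name=str(names[i]).strip(),
                residue_name=str(resnames[i]).strip(),
                residue_id=int(resids[i]),
                chain=str(chains[i]).strip(),
                element=elem.capitalize(),
            )
        )
    return Topology(tuple(atoms))


_READERS = {
    "multimodel-pdb": ("MDAnalysis.coordinates.PDB", "PDBReader"),
    "dcd": ("MDAnalysis.coordinates.DCD", "DCDReader"),
    "xtc": ("MDAnalysis.coordinates.XTC", "XTCReader"),
}


def load_trajectory(
    path: str | Path,
    topology: Topology,
    format: str = "multimodel-pdb",
    label: str = "",
) -> Trajectory:
    """Read frames from *path* against an already-loaded topology.

    Supported formats: multi-model PDB, DCD, XTC (nm → Å), and the
    project's plain-text ``xyz-frames`` dialect.  Frame atom counts must
    match the topology.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"trajectory file not found: {path}")
    fmt = format.lower()
    if fmt == "xyz-frames":
        frames = _read_xyz_frames(path, topology)
    elif fmt in _READERS:
        modname, clsname = _READERS[fmt]
        import importlib

        reader_cls = getattr(importlib.import_module(modname), clsname)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reader = reader_cls(str(path))
        except OSError as exc:
            raise IOError(f"cannot read {path}: {exc}") from exc
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"cannot parse {path} as {format}: {exc}") from exc
        with reader:
            if reader.n_atoms != topology.n_atoms:
                raise ConsistencyError(
                    f"{path}: {reader.n_atoms} atoms per frame, "
                    f"topology has {topology.n_atoms}"
                )
            frames = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for ts in reader:
                    t = float(ts.time) if ts.time is not None else None
                    frames.append(
                        Frame(
                            coordinates=np.array(ts.positions, dtype=float),
                            box=_dims_to_box(ts.dimensions),
                            time=t,
                        )
                    )
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")
    if not frames:
        raise FormatError(f"{path} contains no frames")
    return Trajectory(topology=topology, frames=frames, label=label)


def _read_xyz_frames(path: Path, topology: Topology) -> list[Frame]:
    # Dialect: header "natoms nframes", then per frame one comment line and
    # natoms lines "element x y z".
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path} is empty")
    head = lines[0].split()
    if len(head) != 2:
        raise FormatError(f"{path}: header must be 'natoms nframes'")
    try:
        natoms, nframes = int(head[0]), int(head[1])
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer header") from exc
    if natoms != topology.n_atoms:
        raise ConsistencyError(
            f"{path}: {natoms} atoms per frame, topology has {topology.n_atoms}"
        )
    frames: list[Frame] = []
    pos = 1
    for k in range(nframes):
        block = lines[pos : pos + 1 + natoms]
        if len(block) < 1 + natoms:
            raise FormatError(f"{path}: truncated frame {k}")
        comment = block[0]
        time = None
        m = re.search(r"time=([-0-9.eE+]+)", comment)
        if m:
            time = float(m.group(1))
        coords = np.empty((natoms, 3))
        for i, line in enumerate(block[1:]):
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}: bad atom line in frame {k}: {line!r}")
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(Frame(coordinates=coords, time=time))
        pos += 1 + natoms
    return frames


def write_trajectory(
    traj: Trajectory, path: str | Path, format: str = "multimodel-pdb"
) -> Path:
    """Write a trajectory as multi-model PDB or the xyz-frames dialect.

    Output round-trips through :func:`load_trajectory` to format precision
    (1e-3 Å for PDB, better than 1e-6 Å for xyz-frames, which drops the box).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "multimodel-pdb":
        _write_multimodel_pdb(traj, path)
    elif fmt == "xyz-frames":
        _write_xyz_frames(traj, path)
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")
    return path


def _pdb_atom_name(name: str) -> str:
    # Names shorter than 4 chars start in column 14, per PDB convention.
    return name.ljust(4) if len(name) >= 4 else f" {name:<3s}"


def _write_multimodel_pdb(traj: Trajectory, path: Path) -> None:
    from MDAnalysis.lib.mdamath import triclinic_box

    with open(path, "w") as fh:
        for m, frame in enumerate(traj.frames, start=1):
            if frame.box is not None:
                a, b, c, al, be, ga = triclinic_box(*frame.box)
                fh.write(
                    f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
                    f"{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1\n"
                )
            fh.write(f"MODEL     {m:4d}\n")
            for atom, (x, y, z) in zip(traj.topology.atoms, frame.coordinates):
                fh.write(
                    f"ATOM  {atom.serial % 100000:5d} {_pdb_atom_name(atom.name)}"
                    f" {atom.residue_name:<4.4s}{(atom.chain or 'A')[:1]}"
                    f"{atom.residue_id % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2.2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _write_xyz_frames(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{traj.topology.n_atoms} {traj.n_frames}\n")
        for k, frame in enumerate(traj.frames):
            t = f" time={frame.time:.6f}" if frame.time is not None else ""
            fh.write(f"# frame {k}{t}\n")
            for atom, (x, y, z) in zip(traj.topology.atoms, frame.coordinates):
                fh.write(f"{atom.element} {x:.9f} {y:.9f} {z:.9f}\n")


# ---------------------------------------------------------------------------
# selections

_KEYWORDS = {"name", "resname", "resid", "chain", "element"}
_VALUE_RE = re.compile(r"^[A-Za-z0-9'*+\-:]+$")


def _parse_selector(selector: str) -> list[tuple[str, list[str]]]:
    tokens = selector.split()
    if not tokens:
        raise SelectionError("empty selector")
    clauses: list[tuple[str, list[str]]] = []
    current: tuple[str, list[str]] | None = None
    for pos, tok in enumerate(tokens):
        low = tok.lower()
        if low == "and":
            if current is None or not current[1]:
                raise SelectionError(f"'and' without a complete clause (token {pos})")
            clauses.append(current)
            current = None
        elif low in _KEYWORDS:
            if current is not None:
                if not current[1]:
                    raise SelectionError(
                        f"keyword {current[0]!r} has no values (token {pos})"
                    )
                clauses.append(current)
            current = (low, [])
        else:
            if current is None:
                raise SelectionError(f"expected a keyword, got {tok!r} (token {pos})")
            if not _VALUE_RE.match(tok):
                raise SelectionError(f"malformed value {tok!r} (token {pos})")
            current[1].append(tok)
    if current is None or not current[1]:
        raise SelectionError("selector ends mid-clause")
    clauses.append(current)
    return clauses


def _clause_matches(atom: Atom, keyword: str, values: list[str]) -> bool:
    if keyword == "resid":
        for v in values:
            if ":" in v:
                lo, hi = v.split(":", 1)
                if int(lo) <= atom.residue_id <= int(hi):
                    return True
            elif atom.residue_id == int(v):
                return True
        return False
    attr = {
        "name": atom.name,
        "resname": atom.residue_name,
        "chain": atom.chain,
        "element": atom.element,
    }[keyword]
    return attr.upper() in {v.upper() for v in values}


def resolve_selection(topology: Topology, selector: str) -> list[int]:
    """Resolve a selection expression to topology-ordered atom indices.

    Grammar: clauses ``name|resname|resid|chain|element VALUE...`` joined by
    ``and``; multiple values within a clause are OR-ed, ``resid`` accepts
    ``lo:hi`` ranges.  An empty result is allowed.
    """
    clauses = _parse_selector(selector)
    out = []
    for i, atom in enumerate(topology.atoms):
        if all(_clause_matches(atom, kw, vals) for kw, vals in clauses):
            out.append(i)
    return out


# ---------------------------------------------------------------------------
# site specification

_SINGLE_ROLES = ("c1", "c10", "c11", "c3")
_LIST_ROLES = ("c15_protons", "ppi_oxygens", "acid_atoms", "mg_ions")


def _as_tuple(value) -> tuple[str, ...]:
    if value is None:
        return ()
    if isinstance(value, str):
        return (value,) if value else ()
    return tuple(value)


@dataclass(frozen=True)
class SiteSpec:
    """Maps chemical roles in the active site to atom selectors.

    Roles follow farnesyl-diphosphate carbon numbering: c1/c10 for the ring
    closure, c11 as the hydration probe, c3 as the cationic centre with its
    three bonded substituents, c15 protons for the competing deprotonation,
    diphosphate (PPi) oxygens and engineered acid side-chain atoms as
    hydrogen-bond candidates, plus a water-oxygen pattern and optional Mg ions.
    """

    c1: str = "name C1"
    c10: str = "name C10"
    c11: str = "name C11"
    c3: str = "name C3"
    c3_substituents: tuple[str, ...] = ()
    c15_protons: tuple[str, ...] = ()
    ppi_oxygens: tuple[str, ...] = ()
    acid_atoms: tuple[str, ...] = ()
    water_oxygens: str = "resname HOH WAT TIP3 SOL and element O"
    mg_ions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("c3_substituents", "c15_protons", "ppi_oxygens",
                     "acid_atoms", "mg_ions"):
            object.__setattr__(self, name, _as_tuple(getattr(self, name)))
        if self.c3_substituents and len(self.c3_substituents) != 3:
            raise SiteSpecError("c3_substituents must name exactly 3 atoms")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SiteSpec":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SiteSpecError(f"unknown site roles: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SiteSpec":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "c1": self.c1, "c10": self.c10, "c11": self.c11, "c3": self.c3,
            "c3_substituents": list(self.c3_substituents),
            "c15_protons": list(self.c15_protons),
            "ppi_oxygens": list(self.ppi_oxygens),
            "acid_atoms": list(self.acid_atoms),
            "water_oxygens": self.water_oxygens,
            "mg_ions": list(self.mg_ions),
        }


class ResolvedSite:
    """Lazily resolves SiteSpec roles against one topology, with caching.

    Roles are validated on first access so partial topologies (e.g. a
    cyclization-only fixture without waters) work as long as only the roles
    they contain are requested.
    """

    def __init__(self, topology: Topology, site: SiteSpec):
        self.topology = topology
        self.site = site
        self._cache: dict[str, object] = {}

    def single(self, role: str) -> int:
        if role not in self._cache:
            if role not in _SINGLE_ROLES:
                raise SiteSpecError(f"{role!r} is not a single-atom role")
            sel = getattr(self.site, role)
            idx = resolve_selection(self.topology, sel)
            if len(idx) != 1:
                raise SiteSpecError(
                    f"role {role!r} ({sel!r}) resolves to {len(idx)} atoms, need 1"
                )
            self._cache[role] = idx[0]
        return self._cache[role]  # type: ignore[return-value]

    def many(self, role: str, require: bool = False) -> list[int]:
        key = f"many:{role}"
        if key not in self._cache:
            selectors = getattr(self.site, role)
            if isinstance(selectors, str):
                selectors = (selectors,) if selectors else ()
            out: list[int] = []
            for sel in selectors:
                hits = resolve_selection(self.topology, sel)
                if not hits and role != "water_oxygens":
                    raise SiteSpecError(f"role {role!r}: {sel!r} matches no atoms")
                out.extend(h for h in hits if h not in out)
            self._cache[key] = out
        out = list(self._cache[key])  # type: ignore[arg-type]
        if require and not out:
            raise SiteSpecError(f"role {role!r} resolved to no atoms")
        return out

    def substituents(self) -> tuple[int, int, int]:
        key = "c3_substituents"
        if key not in self._cache:
            sels = self.site.c3_substituents
            if not sels:
                raise SiteSpecError("site spec lists no c3_substituents")
            idx: list[int] = []
            for sel in sels:
                hits = resolve_selection(self.topology, sel)
                if len(hits) != 1:
                    raise SiteSpecError(
                        f"c3 substituent {sel!r} resolves to {len(hits)} atoms, need 1"
                    )
                idx.append(hits[0])
            if len(set(idx + [self.single("c3")])) != 4:
                raise SiteSpecError("c3 and its substituents must be 4 distinct atoms")
            self._cache[key] = tuple(idx)
        return self._cache[key]  # type: ignore[return-value]

    def waters(self) -> list[int]:
        return self.many("water_oxygens")


# ---------------------------------------------------------------------------
# periodic distances

_SHIFTS_27 = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=float,
)


def max_safe_cutoff(box: np.ndarray) -> float:
    """Half the shortest cell height: the largest cutoff for which the
    27-translate minimum-image search is exact."""
    box = np.asarray(box, dtype=float)
    vol = abs(np.linalg.det(box))
    heights = [
        vol / np.linalg.norm(np.cross(box[(i + 1) % 3], box[(i + 2) % 3]))
        for i in range(3)
    ]
    return 0.5 * min(heights)


def _min_image_lengths(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    s = d @ np.linalg.inv(box)
    s = s - np.round(s)
    cand = (s[:, None, :] + _SHIFTS_27[None, :, :]) @ box
    return np.sqrt(np.einsum("mkd,mkd->mk", cand, cand).min(axis=1))


def minimum_image_distance_array(
    frame: Frame, i: int, indices: Sequence[int] | np.ndarray
) -> np.ndarray:
    """Distances from atom *i* to each atom in *indices* (minimum-image when
    the frame carries a box, plain Euclidean otherwise)."""
    idx = np.asarray(indices, dtype=int)
    n = frame.n_atoms
    if not (0 <= i < n) or (idx.size and (idx.min() < 0 or idx.max() >= n)):
        raise IndexError("atom index out of range")
    d = frame.coordinates[idx] - frame.coordinates[i]
    if frame.box is None:
        return np.linalg.norm(d, axis=1)
    return _min_image_lengths(d, frame.box)


def minimum_image_distance(frame: Frame, i: int, j: int) -> float:
    """Minimum-image distance in Å between atoms *i* and *j* of one frame."""
    return float(minimum_image_distance_array(frame, i, [j])[0])
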