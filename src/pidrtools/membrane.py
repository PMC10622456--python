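"""Data model for peptide + bilayer systems and readers/writers.

The in-memory containers are deliberately small: a :class:`Topology` holding
per-atom metadata plus named atom-index groups, and a :class:`Trajectory`
holding a ``(n_frames, n_atoms, 3)`` coordinate array with per-frame
orthorhombic boxes.  The membrane normal is the +z axis throughout, and the
minimal-image convention is applied in x and y only (the bilayer is periodic
laterally; z never wraps in any analysis).

Two on-disk dialects are supported: multi-model PDB (MODEL/ENDMDL with a
CRYST1 box record, parsed and written through MDAnalysis) and a simple
plain-text XYZ-with-box format suitable for tiny fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np


class PidrError(Exception):
    """Base class for errors raised by this package."""


class ParseError(PidrError):
    """A structure file could not be parsed."""


class StructureError(PidrError):
    """Parsed input is internally inconsistent (e.g. atom-count mismatch)."""


class GroupError(PidrError, KeyError):
    """An atom group is unknown or ill-formed."""


class MoleculeKind(str, Enum):
    peptide = "peptide"
    lipid = "lipid"
    solvent = "solvent"
    ion = "ion"


class LipidSpecies(str, Enum):
    POPC = "POPC"
    POPS = "POPS"


#: Atomic masses (u) for the elements that occur in these systems.
ELEMENT_MASSES: Dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
    "S": 32.06,
    "NA": 22.98977,
    "CL": 35.45,
}

#: Default residue-name -> (molecule kind, lipid species) table.  Unknown
#: residue names are treated as peptide residues.
DEFAULT_RESIDUE_KINDS: Dict[str, Tuple[MoleculeKind, Optional[LipidSpecies]]] = {
    "POPC": (MoleculeKind.lipid, LipidSpecies.POPC),
    "POPS": (MoleculeKind.lipid, LipidSpecies.POPS),
    "TIP3": (MoleculeKind.solvent, None),
    "TIP": (MoleculeKind.solvent, None),
    "HOH": (MoleculeKind.solvent, None),
    "WAT": (MoleculeKind.solvent, None),
    "SOL": (MoleculeKind.solvent, None),
    "SOD": (MoleculeKind.ion, None),
    "NA": (MoleculeKind.ion, None),
    "POT": (MoleculeKind.ion, None),
    "K": (MoleculeKind.ion, None),
    "CLA": (MoleculeKind.ion, None),
    "CL": (MoleculeKind.ion, None),
}


def element_of(atom_name: str) -> str:
    """Infer the chemical element from an atom name.

    Names used by this package (and CHARMM-style lipid names) start with the
    element symbol followed by digits/locants; two-letter ions are looked up
    explicitly.
    """
    name = atom_name.strip().upper()
    if name in ("NA", "SOD"):
        return "NA"
    if name in ("CL", "CLA"):
        return "CL"
    for ch in name:
        if ch.isalpha():
            return ch
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass
class AtomRecord:
    atom_index: int
    atom_name: str
    residue_name: str
    residue_index: int
    molecule_id: int
    molecule_kind: MoleculeKind
    lipid_species: Optional[LipidSpecies] = None
    element: str = ""
    mass: float = 0.0
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not self.element:
            self.element = element_of(self.atom_name)
        if not self.mass:
            self.mass = ELEMENT_MASSES[self.element]
        if (self.lipid_species is not None) != (
            self.molecule_kind is MoleculeKind.lipid
        ):
            raise StructureError(
                f"atom {self.atom_index}: lipid_species must be set iff the "
                f"molecule is a lipid (kind={self.molecule_kind.value})"
            )


class Topology:
    """Ordered atom records plus named atom-index groups.

    Groups are stored as sorted integer arrays.  Hydrogen-bond donors carry
    their bonded hydrogens in :attr:`donor_hydrogens`.
    """

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: List[AtomRecord] = list(atoms)
        for i, a in enumerate(self.atoms):
            if a.atom_index != i:
                raise StructureError(
                    f"atom indices must be contiguous from 0; atom {i} has "
                    f"index {a.atom_index}"
                )
        self.groups: Dict[str, np.ndarray] = {}
        self.donor_hydrogens: Dict[int, Tuple[int, ...]] = {}
        # cached columns
        self.names = np.array([a.atom_name for a in self.atoms])
        self.residue_names = np.array([a.residue_name for a in self.atoms])
        self.residue_indices = np.array(
            [a.residue_index for a in self.atoms], dtype=int
        )
        self.molecule_ids = np.array([a.molecule_id for a in self.atoms], dtype=int)
        self.kinds = np.array([a.molecule_kind.value for a in self.atoms])
        self.species = np.array(
            [a.lipid_species.value if a.lipid_species else "" for a in self.atoms]
        )
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        self.chain_ids = np.array([a.chain_id for a in self.atoms])

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def peptide_ids(self) -> List[int]:
        mask = self.kinds == MoleculeKind.peptide.value
        return sorted(set(self.molecule_ids[mask].tolist()))

    @property
    def lipid_ids(self) -> List[int]:
        mask = self.kinds == MoleculeKind.lipid.value
        return sorted(set(self.molecule_ids[mask].tolist()))

    def lipid_species_of(self, molecule_id: int) -> LipidSpecies:
        idx = np.nonzero(self.molecule_ids == molecule_id)[0]
        if idx.size == 0 or self.kinds[idx[0]] != MoleculeKind.lipid.value:
            raise GroupError(f"molecule {molecule_id} is not a lipid")
        return LipidSpecies(self.species[idx[0]])

    # ------------------------------------------------------------------
    def register_group(self, name: str, indices: Sequence[int]) -> None:
        arr = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
        if arr.size and (arr[0] < 0 or arr[-1] >= self.n_atoms):
            raise GroupError(f"group {name!r} has out-of-range atom indices")
        self.groups[name] = arr

    def group(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise GroupError(
                f"unknown atom group {name!r}; registered groups: "
                f"{sorted(self.groups)}"
            ) from None

    def set_donor_hydrogens(self, mapping: Dict[int, Sequence[int]]) -> None:
        for d, hs in mapping.items():
            if len(hs) == 0:
                raise GroupError(f"donor atom {d} has no bonded hydrogen")
        self.donor_hydrogens = {int(d): tuple(int(h) for h in hs) for d, hs in mapping.items()}


def select_group(topology: Topology, name: str) -> np.ndarray:
    """Return the atom-index set registered under ``name``."""
    return topology.group(name)


@dataclass
class Frame:
    """A single set of coordinates with an orthorhombic box.

    Coordinates are in Angstrom, the box is (Lx, Ly, Lz) in Angstrom, time in
    nanoseconds.
    """

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructureError("coordinates must have shape (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise StructureError("box must be three positive lengths")


class Trajectory:
    """An ordered sequence of frames over a shared topology."""

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        boxes: np.ndarray,
        times: Optional[np.ndarray] = None,
        frame_interval: float = 0.1,
    ):
        coords = np.asarray(coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise StructureError("coordinates must have shape (F, N, 3)")
        if coords.shape[1] != topology.n_atoms:
            raise StructureError(
                f"coordinate atom count {coords.shape[1]} does not match "
                f"topology ({topology.n_atoms})"
            )
        if coords.shape[0] == 0:
            raise StructureError("a trajectory needs at least one frame")
        boxes = np.asarray(boxes, dtype=float)
        if boxes.shape != (coords.shape[0], 3):
            raise StructureError("boxes must have shape (F, 3)")
        self.topology = topology
        self.coordinates = coords
        self.boxes = boxes
        self.frame_interval = float(frame_interval)
        if times is None:
            # MD convention: the first stored frame is written one interval
            # into the run, so times are (i+1) * interval.
            times = np.arange(1, coords.shape[0] + 1, dtype=float) * self.frame_interval
        self.times = np.asarray(times, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise StructureError("frames must be time-ordered")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], self.boxes[i], float(self.times[i]))

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)


# ----------------------------------------------------------------------
# Leaflet assignment


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels.

    ``labels`` maps lipid molecule id -> ``"mixed"`` (the POPS-containing,
    peptide-hosting leaflet) or ``"pure"``.  ``upper_is_mixed`` records which
    side of the bilayer midplane the mixed leaflet occupies.
    """

    labels: Dict[int, str]
    upper_is_mixed: bool
    method: str = "P-z vs lipid COM"

    def lipids(self, leaflet: str) -> List[int]:
        return sorted(m for m, lab in self.labels.items() if lab == leaflet)

    def counts(self, topology: Topology) -> Dict[str, int]:
        """Lipid counts keyed by ``(leaflet, species)``, e.g. ``mixed_POPS``."""
        out: Dict[str, int] = {}
        for mol, lab in self.labels.items():
            sp = topology.lipid_species_of(mol).value
            key = f"{lab}_{sp}"
            out[key] = out.get(key, 0) + 1
        return out


def assign_leaflets(frame: Frame, topology: Topology) -> LeafletAssignment:
    """Assign each lipid to a leaflet from the sign of z(P) - z(bilayer COM).

    The leaflet containing POPS lipids is labelled ``mixed``; the other
    ``pure``.  Raises :class:`StructureError` if a lipid has no phosphorus
    atom or if POPS lipids occur in both leaflets.
    """
    lipid_mask = topology.kinds == MoleculeKind.lipid.value
    if not lipid_mask.any():
        raise StructureError("no lipids in topology")
    lipid_atoms = np.nonzero(lipid_mask)[0]
    masses = topology.masses[lipid_atoms]
    z_com = float(
        np.average(frame.coordinates[lipid_atoms, 2], weights=masses)
    )

    p_side: Dict[int, bool] = {}
    species: Dict[int, str] = {}
    for mol in topology.lipid_ids:
        sel = lipid_atoms[topology.molecule_ids[lipid_atoms] == mol]
        p_sel = sel[topology.names[sel] == "P"]
        if p_sel.size == 0:
            res = topology.residue_names[sel[0]]
            raise StructureError(
                f"lipid molecule {mol} ({res}) has no phosphorus atom"
            )
        zp = float(frame.coordinates[p_sel, 2].mean())
        p_side[mol] = zp > z_com
        species[mol] = topology.species[sel[0]]

    ps_sides = {side for mol, side in p_side.items() if species[mol] == "POPS"}
    if len(ps_sides) == 0:
        raise StructureError(
            "no POPS lipids found; cannot identify the mixed leaflet"
        )
    if len(ps_sides) == 2:
        raise StructureError("POPS lipids found in both leaflets")
    upper_is_mixed = ps_sides.pop()
    labels = {
        mol: ("mixed" if side == upper_is_mixed else "pure")
        for mol, side in p_side.items()
    }
    return LeafletAssignment(labels=labels, upper_is_mixed=upper_is_mixed)


# ----------------------------------------------------------------------
# Structure I/O


def _molecule_ids_from_metadata(
    kinds: Sequence[MoleculeKind], chain_ids: Sequence[str], resids: Sequence[int]
) -> List[int]:
    """Peptides get one molecule per chain; everything else one per residue."""
    ids: List[int] = []
    mapping: Dict[tuple, int] = {}
    for kind, chain, resid in zip(kinds, chain_ids, resids):
        key = (
            ("pep", chain)
            if kind is MoleculeKind.peptide
            else ("res", chain, resid)
        )
        if key not in mapping:
            mapping[key] = len(mapping)
        ids.append(mapping[key])
    return ids


def topology_from_metadata(
    names: Sequence[str],
    residue_names: Sequence[str],
    residue_indices: Sequence[int],
    chain_ids: Sequence[str],
    residue_kinds: Optional[Dict[str, Tuple[MoleculeKind, Optional[LipidSpecies]]]] = None,
) -> Topology:
    """Build a :class:`Topology` from per-atom metadata using the residue-name
    table to classify molecules."""
    table = DEFAULT_RESIDUE_KINDS if residue_kinds is None else residue_kinds
    kinds = []
    specs = []
    for rn in residue_names:
        kind, sp = table.get(rn.upper(), (MoleculeKind.peptide, None))
        kinds.append(kind)
        specs.append(sp)
    mol_ids = _molecule_ids_from_metadata(kinds, chain_ids, residue_indices)
    atoms = [
        AtomRecord(
            atom_index=i,
            atom_name=names[i],
            residue_name=residue_names[i],
            residue_index=int(residue_indices[i]),
            molecule_id=mol_ids[i],
            molecule_kind=kinds[i],
            lipid_species=specs[i],
            chain_id=chain_ids[i],
        )
        for i in range(len(names))
    ]
    return Topology(atoms)


def _read_pdb(path: Path, residue_kinds, frame_interval: float) -> Trajectory:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # noqa: BLE001 - normalise third-party errors
            raise _diagnose_pdb_error(path, exc) from exc
        names = [str(n) for n in u.atoms.names]
        resnames = [str(r) for r in u.atoms.resnames]
        resids = [int(r) for r in u.atoms.resids]
        try:
            chains = [str(c) for c in u.atoms.chainIDs]
        except AttributeError:
            chains = ["A"] * len(names)
        coords = []
        boxes = []
        try:
            for ts in u.trajectory:
                coords.append(ts.positions.astype(float).copy())
                if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
                    raise ParseError(
                        f"{path}: missing or invalid CRYST1 box record"
                    )
                boxes.append(np.asarray(ts.dimensions[:3], dtype=float))
        except ParseError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise _diagnose_pdb_error(path, exc) from exc
    topology = topology_from_metadata(names, resnames, resids, chains, residue_kinds)
    return Trajectory(
        topology,
        np.stack(coords),
        np.stack(boxes),
        frame_interval=frame_interval,
    )


def _diagnose_pdb_error(path: Path, exc: Exception) -> PidrError:
    """Map a reader failure to a ParseError/StructureError, locating the
    offending line where a cheap scan can find it."""
    counts = []
    n = 0
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                rec = line[:6].strip()
                if rec in ("ATOM", "HETATM"):
                    n += 1
                    try:
                        float(line[30:38])
                        float(line[38:46])
                        float(line[46:54])
                    except ValueError:
                        return ParseError(
                            f"{path}:{lineno}: malformed coordinate fields"
                        )
                elif rec == "ENDMDL":
                    counts.append(n)
                    n = 0
    except OSError as oserr:
        return ParseError(f"{path}: {oserr}")
    if n:
        counts.append(n)
    if len(set(c for c in counts if c)) > 1:
        return StructureError(
            f"{path}: inconsistent atom counts across models: {counts}"
        )
    return ParseError(f"{path}: {exc}")


def _write_pdb(trajectory: Trajectory, path: Path) -> None:
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    top = trajectory.topology
    n = top.n_atoms
    # residues: consecutive (chain, resid, resname) runs
    res_keys = list(zip(top.chain_ids, top.residue_indices, top.residue_names))
    resindex = np.zeros(n, dtype=int)
    seen: Dict[tuple, int] = {}
    order: List[tuple] = []
    for i, key in enumerate(res_keys):
        if key not in seen:
            seen[key] = len(seen)
            order.append(key)
        resindex[i] = seen[key]
    n_res = len(order)
    chains = [k[0] for k in order]
    seg_of_chain = {c: j for j, c in enumerate(dict.fromkeys(chains))}
    segindex = np.array([seg_of_chain[c] for c in chains], dtype=int)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=n_res,
            atom_resindex=resindex,
            residue_segindex=segindex,
            n_segments=len(seg_of_chain),
            trajectory=False,
        )
        u.add_TopologyAttr("ids", np.arange(1, n + 1))
        u.add_TopologyAttr("names", top.names.tolist())
        u.add_TopologyAttr("resnames", [k[2] for k in order])
        u.add_TopologyAttr("resids", [int(k[1]) for k in order])
        u.add_TopologyAttr("chainIDs", top.chain_ids.tolist())
        u.add_TopologyAttr("segids", list(seg_of_chain))
        u.add_TopologyAttr("elements", [a.element.capitalize() for a in top.atoms])
        u.add_TopologyAttr("occupancies", np.ones(n))
        u.add_TopologyAttr("tempfactors", np.zeros(n))
        dims = np.zeros((trajectory.n_frames, 6), dtype=np.float64)
        dims[:, :3] = trajectory.boxes
        dims[:, 3:] = 90.0
        u.load_new(
            trajectory.coordinates.astype(np.float32),
            format=MemoryReader,
            dimensions=dims,
        )
        with mda.Writer(str(path), n_atoms=n, multiframe=True, reindex=False) as w:
            for ts in u.trajectory:
                w.write(u.atoms)
    # repeat the CRYST1 record inside every MODEL block so each frame
    # carries its box (readers take per-frame dimensions from there)
    lines = path.read_text().splitlines(keepends=True)
    out_lines: List[str] = []
    frame_no = 0
    for line in lines:
        out_lines.append(line)
        if line.startswith("MODEL"):
            b = trajectory.boxes[frame_no]
            out_lines.append(
                f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
            frame_no += 1
    path.write_text("".join(out_lines))


def _write_xyz(trajectory: Trajectory, path: Path) -> None:
    top = trajectory.topology
    with open(path, "w") as fh:
        for i in range(trajectory.n_frames):
            box = trajectory.boxes[i]
            fh.write(f"{top.n_atoms}\n")
            fh.write(
                f"{box[0]:.6f} {box[1]:.6f} {box[2]:.6f} "
                f"{trajectory.times[i]:.6f}\n"
            )
            for j in range(top.n_atoms):
                x, y, z = trajectory.coordinates[i, j]
                fh.write(
                    f"{top.names[j]} {top.residue_names[j]} "
                    f"{top.chain_ids[j]} {top.residue_indices[j]} "
                    f"{x:.6f} {y:.6f} {z:.6f}\n"
                )


def _read_xyz(path: Path, residue_kinds, frame_interval: float) -> Trajectory:
    frames: List[np.ndarray] = []
    boxes: List[np.ndarray] = []
    times: List[float] = []
    meta: Optional[List[Tuple[str, str, str, int]]] = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count")
        parts = lines[i + 1].split()
        if len(parts) != 4:
            raise ParseError(f"{path}:{i + 2}: expected 'Lx Ly Lz time'")
        box = np.array([float(p) for p in parts[:3]])
        times.append(float(parts[3]))
        coords = np.empty((n, 3))
        this_meta: List[Tuple[str, str, str, int]] = []
        for j in range(n):
            lineno = i + 2 + j
            fields = lines[lineno].split()
            if len(fields) != 7:
                raise ParseError(
                    f"{path}:{lineno + 1}: expected "
                    "'name resname chain resid x y z'"
                )
            name, resname, chain, resid = fields[0], fields[1], fields[2], int(fields[3])
            this_meta.append((name, resname, chain, resid))
            coords[j] = [float(fields[4]), float(fields[5]), float(fields[6])]
        if meta is None:
            meta = this_meta
        elif meta != this_meta:
            raise StructureError(
                f"{path}: atom metadata differs between frames"
            )
        frames.append(coords)
        boxes.append(box)
        i += 2 + n
    if meta is None:
        raise ParseError(f"{path}: empty file")
    topology = topology_from_metadata(
        [m[0] for m in meta],
        [m[1] for m in meta],
        [m[3] for m in meta],
        [m[2] for m in meta],
        residue_kinds,
    )
    return Trajectory(
        topology,
        np.stack(frames),
        np.stack(boxes),
        times=np.array(times),
        frame_interval=frame_interval,
    )


def read_structure(
    path,
    dialect: str = "pdb",
    residue_kinds: Optional[dict] = None,
    frame_interval: float = 0.1,
) -> Trajectory:
    """Read a multi-model PDB or XYZ-with-box file into a :class:`Trajectory`.

    Unknown residue names are mapped to molecule kinds through the
    configurable ``residue_kinds`` table (defaults: POPC/POPS -> lipid,
    water names -> solvent, Na/Cl -> ion, everything else -> peptide).
    Atom groups are *not* populated; see :func:`pidrtools.groups.assign_groups`.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    if dialect == "pdb":
        return _read_pdb(path, residue_kinds, frame_interval)
    if dialect == "xyz":
        return _read_xyz(path, residue_kinds, frame_interval)
    raise ValueError(f"unknown dialect {dialect!r} (use 'pdb' or 'xyz')")


def write_structure(trajectory: Trajectory, path, dialect: str = "pdb") -> None:
    """Write a trajectory in the requested dialect.

    Round-tripping through :func:`read_structure` reproduces coordinates to
    the dialect's precision (1e-3 Angstrom for PDB).
    """
    path = Path(path)
    if trajectory.n_frames == 0:
        raise StructureError("refusing to write an empty frame list")
    if dialect == "pdb":
        _write_pdb(trajectory, path)
    elif dialect == "xyz":
        _write_xyz(trajectory, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (use 'pdb' or 'xyz')")


# ----------------------------------------------------------------------
# Geometry helpers shared across analysis modules


def minimum_image_xy(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimal-image convention in x and y only.

    ``delta`` is an array of displacement vectors (..., 3); ``box`` the
    orthorhombic box lengths.  z is never wrapped: the bilayer is periodic
    laterally, and wrapping z would create spurious interactions across the
    water slab.
    """
    out = np.array(delta, dtype=float, copy=True)
    for d in (0, 1):
        out[..., d] -= box[d] * np.round(out[..., d] / box[d])
    return out


def center_of_mass(
    coordinates: np.ndarray, indices: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """Mass-weighted centre of mass of the selected atoms."""
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise GroupError("cannot take the centre of mass of an empty selection")
    m = masses[idx]
    return np.average(coordinates[idx], axis=0, weights=m)
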