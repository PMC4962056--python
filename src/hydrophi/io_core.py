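"""Structures, trajectories and periodic-boundary primitives.

Containers are deliberately lightweight: a :class:`Topology` holds atoms and
residues, a :class:`Frame` holds coordinates plus an orthorhombic box, and an
:class:`Ensemble` is a weighted sequence of frames sharing one topology.
Coordinates are in nm throughout; the Å↔nm conversion happens inside the file
readers/writers (mdtraj does the format work).

Only orthorhombic boxes are supported: every cutoff-based analysis downstream
uses the simple minimum-image convention, which is exact only for rectangular
cells. Triclinic input is rejected rather than silently mistreated.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

WATER_RESNAMES = {"HOH", "SOL", "WAT", "TIP4", "TIP3", "H2O"}
ION_RESNAMES = {"NA", "CL", "K", "MG", "CA2", "ZN", "NA+", "CL-", "SOD", "CLA"}

# Average atomic masses (amu) for the elements this package handles.
MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "ZN": 65.38, "FE": 55.845, "SE": 78.971, "M": 0.0,  # M = massless virtual site
}


class ParseError(ValueError):
    """A structure or trajectory file could not be interpreted."""


@dataclass(frozen=True)
class WaterModel:
    """Rigid water geometry descriptor.

    ``r_OM`` is the O→virtual-site distance along the HOH bisector (0 for
    three-site models).  Charges/LJ parameters live in :mod:`.energetics`.
    """

    name: str
    r_OH: float          # nm
    theta_HOH: float     # degrees
    n_sites: int
    r_OM: float = 0.0    # nm

    @property
    def site_names(self) -> tuple[str, ...]:
        return ("O", "H1", "H2", "M")[: self.n_sites]


#: Four-site rigid model used throughout: planar, r_OH = 0.09572 nm,
#: HOH angle 104.52 deg, negative charge on the M site 0.01546 nm from O.
TIP4P2005 = WaterModel("TIP4P/2005", r_OH=0.09572, theta_HOH=104.52,
                       n_sites=4, r_OM=0.01546)

TIP3P_GEOMETRY = WaterModel("TIP3P-geometry", r_OH=0.09572, theta_HOH=104.52,
                            n_sites=3)


@dataclass(frozen=True)
class Atom:
    index: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    segment: str          # "protein" | "water" | "ion"
    mass: float
    charge: float | None = None

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "M")


@dataclass
class Topology:
    atoms: list[Atom]
    residues: list[tuple[str, range]]           # (name, atom index range)
    water_model: WaterModel = TIP4P2005

    def __post_init__(self) -> None:
        for k, a in enumerate(self.atoms):
            if a.index != k:
                raise ValueError(f"atom {k} carries index {a.index}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def select(self, segment: str) -> np.ndarray:
        """Indices of atoms belonging to the named segment."""
        return np.array([a.index for a in self.atoms if a.segment == segment],
                        dtype=int)

    @property
    def protein_atoms(self) -> np.ndarray:
        return self.select("protein")

    @property
    def water_oxygens(self) -> np.ndarray:
        return np.array([a.index for a in self.atoms
                         if a.segment == "water" and a.element == "O"], dtype=int)

    def water_molecules(self) -> list[range]:
        """Atom index ranges of the water residues, in order."""
        return [rng for name, rng in self.residues
                if self.atoms[rng.start].segment == "water"]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])


@dataclass
class Frame:
    coords: np.ndarray            # (n_atoms, 3) nm
    box: np.ndarray               # (3,) nm, orthorhombic edge lengths
    time: float = 0.0             # ps

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Ensemble:
    topology: Topology
    frames: list[Frame]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("no frames")
        n = self.topology.n_atoms
        for f in self.frames:
            if f.n_atoms != n:
                raise ValueError(
                    f"frame has {f.n_atoms} atoms, topology has {n}")
        if self.weights is None:
            self.weights = np.full(len(self.frames), 1.0 / len(self.frames))
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.frames),) or np.any(w < 0):
                raise ValueError("weights must be non-negative, one per frame")
            s = w.sum()
            if s <= 0:
                raise ValueError("weights sum to zero")
            self.weights = w / s

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# minimum-image geometry
# ---------------------------------------------------------------------------

def min_image_vectors(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``delta`` is (..., 3); ``box`` the orthorhombic edge lengths.
    """
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def min_image_distance(frame: Frame, i: int, j: int) -> float:
    """Minimum-image distance (nm) between atoms *i* and *j*."""
    n = frame.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range (n_atoms={n})")
    d = min_image_vectors(frame.coords[j] - frame.coords[i], frame.box)
    return float(np.linalg.norm(d))


def pair_distances(coords_a: np.ndarray, coords_b: np.ndarray,
                   box: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image distance matrix, shape (len(a), len(b))."""
    delta = coords_b[None, :, :] - coords_a[:, None, :]
    return np.linalg.norm(min_image_vectors(delta, box), axis=-1)


def wrap_coords(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, box) per axis (for periodic KD-trees)."""
    wrapped = np.mod(coords, box)
    # guard against coordinates landing exactly on the upper boundary
    return np.where(wrapped >= box, 0.0, wrapped)


# ---------------------------------------------------------------------------
# segment classification and element/mass inference
# ---------------------------------------------------------------------------

def classify_residue(resname: str) -> str:
    rn = resname.strip().upper()
    if rn in WATER_RESNAMES:
        return "water"
    if rn in ION_RESNAMES:
        return "ion"
    return "protein"


def infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        raise ParseError("empty atom name")
    if name.upper() in ("MW", "M", "EP", "LP", "DUM"):
        return "M"
    # strip leading digits (e.g. 1HB2)
    stripped = name.lstrip("0123456789")
    two = stripped[:2].upper()
    if two in ("NA", "CL", "MG", "ZN", "FE", "SE") and len(stripped) <= 2:
        return two
    return stripped[0].upper()


def mass_of(element: str) -> float:
    try:
        return MASSES[element]
    except KeyError:
        warnings.warn(f"unknown element {element!r}; assigning carbon mass")
        return MASSES["C"]


def build_topology(atom_names: Sequence[str],
                   residue_names: Sequence[str],
                   residue_ranges: Sequence[range],
                   water_model: WaterModel = TIP4P2005,
                   elements: Sequence[str] | None = None) -> Topology:
    """Assemble a :class:`Topology` from flat per-atom / per-residue data."""
    atoms: list[Atom] = []
    for ri, (rname, rng) in enumerate(zip(residue_names, residue_ranges)):
        seg = classify_residue(rname)
        if seg == "protein" and rname.strip().upper() not in _AA3:
            warnings.warn(
                f"residue {rname!r} not recognised; treating as protein")
        for ai in rng:
            el = elements[ai] if elements is not None else infer_element(
                atom_names[ai])
            atoms.append(Atom(index=ai, name=atom_names[ai].strip(),
                              element=el, residue_index=ri,
                              residue_name=rname.strip().upper(), segment=seg,
                              mass=mass_of(el)))
    residues = list(zip([r.strip().upper() for r in residue_names],
                        residue_ranges))
    return Topology(atoms=atoms, residues=residues, water_model=water_model)


_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "ACE", "NME", "NH2", "HSE", "HSD", "HID", "HIE",
}


# ---------------------------------------------------------------------------
# mdtraj bridge: file reading and writing
# ---------------------------------------------------------------------------

_DEFAULT_BOX = 999.0  # nm; stand-in for files without box information


def _check_orthorhombic(vectors: np.ndarray) -> np.ndarray:
    """Extract edge lengths from (3,3) box vectors; reject triclinic cells."""
    off = vectors - np.diag(np.diag(vectors))
    if np.max(np.abs(off)) > 1e-6:
        raise ParseError("triclinic boxes are unsupported; "
                         "only orthorhombic cells are handled")
    lengths = np.diag(vectors).copy()
    if np.any(lengths <= 0):
        lengths = np.full(3, _DEFAULT_BOX)
    return lengths


def _from_mdtraj_topology(mtop, water_model: WaterModel) -> Topology:
    atom_names, residue_names, residue_ranges = [], [], []
    elements = []
    for res in mtop.residues:
        idx = [a.index for a in res.atoms]
        residue_names.append(res.name)
        residue_ranges.append(range(idx[0], idx[-1] + 1))
        for a in res.atoms:
            atom_names.append(a.name)
            sym = a.element.symbol if a.element is not None else "M"
            elements.append("M" if sym in ("VS", "D") else sym.upper()
                            if len(sym) > 1 else sym)
    return build_topology(atom_names, residue_names, residue_ranges,
                          water_model=water_model, elements=elements)


def _to_mdtraj(topology: Topology, frames: Sequence[Frame]):
    import mdtraj as md
    from mdtraj.core import element as md_element

    mtop = md.Topology()
    chain = None
    prev_seg = None
    for rname, rng in topology.residues:
        seg = topology.atoms[rng.start].segment
        if chain is None or seg != prev_seg:
            chain = mtop.add_chain()
            prev_seg = seg
        res = mtop.add_residue(rname, chain)
        for ai in rng:
            a = topology.atoms[ai]
            if a.element == "M":
                el = md_element.virtual_site
            else:
                el = md_element.get_by_symbol(a.element.capitalize())
            mtop.add_atom(a.name, el, res)
    xyz = np.stack([f.coords for f in frames])
    traj = md.Trajectory(xyz, mtop,
                         time=np.array([f.time for f in frames]))
    traj.unitcell_lengths = np.stack([f.box for f in frames])
    traj.unitcell_angles = np.full((len(frames), 3), 90.0)
    return traj


def read_structure(path: str, format: str | None = None,
                   water_model: WaterModel = TIP4P2005) -> tuple[Topology, Frame]:
    """Read a single-conformation PDB or GRO file.

    Returns the topology and the first frame; multi-model files are read with
    :func:`read_trajectory`.
    """
    import mdtraj as md

    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt not in ("pdb", "gro"):
        raise ParseError(f"unsupported structure format {fmt!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        traj = md.load(path)
    except Exception as exc:  # mdtraj raises assorted types
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if traj.n_frames == 0:
        raise ParseError("no frames")
    top = _from_mdtraj_topology(traj.topology, water_model)
    if traj.unitcell_vectors is not None:
        box = _check_orthorhombic(traj.unitcell_vectors[0])
    else:
        box = np.full(3, _DEFAULT_BOX)
    t = float(traj.time[0]) if traj.time is not None else 0.0
    return top, Frame(coords=traj.xyz[0].astype(float), box=box, time=t)


def read_trajectory(path: str, topology: Topology | None = None,
                    format: str | None = None,
                    water_model: WaterModel = TIP4P2005) -> Ensemble:
    """Read an XTC/DCD trajectory (needs *topology*) or a multi-model PDB.

    Frames keep file order and get uniform weights.
    """
    import mdtraj as md

    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt in ("xtc", "dcd"):
        if topology is None:
            raise ValueError(f"{fmt} trajectories require a topology")
        mtop = _to_mdtraj(topology, [Frame(np.zeros((topology.n_atoms, 3)),
                                           np.ones(3))]).topology
        try:
            traj = md.load(path, top=mtop)
        except ValueError as exc:
            raise ParseError(str(exc)) from exc
    elif fmt == "pdb":
        traj = md.load(path)
    else:
        raise ParseError(f"unsupported trajectory format {fmt!r}")

    if traj.n_frames == 0:
        raise ParseError("no frames")
    if topology is not None and traj.n_atoms != topology.n_atoms:
        raise ParseError(f"trajectory has {traj.n_atoms} atoms but topology "
                         f"has {topology.n_atoms}")
    top = topology or _from_mdtraj_topology(traj.topology, water_model)
    frames = []
    for k in range(traj.n_frames):
        if traj.unitcell_vectors is not None:
            box = _check_orthorhombic(traj.unitcell_vectors[k])
        else:
            box = np.full(3, _DEFAULT_BOX)
        t = float(traj.time[k]) if traj.time is not None else float(k)
        frames.append(Frame(coords=traj.xyz[k].astype(float), box=box, time=t))
    return Ensemble(topology=top, frames=frames)


def write_structure(path: str, topology: Topology, frame: Frame) -> None:
    """Write a single frame as PDB or GRO (format from the extension)."""
    _to_mdtraj(topology, [frame]).save(path)


def write_ensemble(path: str, ensemble: Ensemble) -> None:
    """Write all frames: multi-model PDB, XTC or DCD by extension."""
    _to_mdtraj(ensemble.topology, ensemble.frames).save(path)
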