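"""Water-structure analyses: hydrogen bonds, hydration shells, anisotropy.

A hydrogen bond is detected geometrically: donor–acceptor heavy-atom
minimum-image distance ≤ 0.35 nm and hydrogen–donor–acceptor angle ≤ 30° (a
widespread MD-analysis convention; both thresholds are configurable).  Each
bond is counted once geometrically, but contributes +1 to the per-molecule
tally of *both* partners (donated plus accepted), which is the convention
under which bulk water shows ≈ 3.5–3.8 bonds per molecule.

Interface waters are those whose oxygen lies within a shell cutoff
(default 0.4 nm) of the nearest protein heavy atom; everything else is bulk.

The rotational anisotropy profile is A(r) = ⟨3cos²ϑ(r) − 1⟩ · RDF(r), where
ϑ is the angle between a water's plane normal and the vector from its oxygen
to a protein atom, averaged over all water–protein-atom pairs in the distance
bin, and RDF is the unnormalised water-oxygen→protein-atom pair histogram.
A vanishes for isotropically oriented water; its absolute integral summarises
the total rotational ordering (entropy loss) induced by the protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io_core import (Ensemble, Frame, Topology, min_image_vectors,
                      wrap_coords)

DONOR_ACCEPTOR_ELEMENTS = ("N", "O", "S")
_H_BOND_MAX = 0.125   # nm, hydrogen-to-heavy covalent attachment threshold


@dataclass(frozen=True)
class HBondCriterion:
    max_da_distance: float = 0.35   # nm
    max_hda_angle: float = 30.0     # degrees

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.max_hda_angle < 90:
            raise ValueError("angle cutoff must lie in (0, 90) degrees")


@dataclass(frozen=True)
class HBond:
    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    category: str                   # "ww" | "wp" | "pp"


@dataclass
class HydrationReport:
    n_interface_waters: float
    n_bulk_waters: float
    hb_ww_interface: float
    hb_wp_interface: float
    hb_total_interface: float
    hb_bulk: float
    hb_pp_total: float
    hb_pw_total: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class AnisotropyProfile:
    bin_edges: np.ndarray           # (n_bins+1,) nm
    A: np.ndarray                   # (n_bins,)
    rdf: np.ndarray                 # (n_bins,) unnormalised pair counts

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> float:
        widths = np.diff(self.bin_edges)
        return float(np.sum(np.abs(self.A) * widths))


# ---------------------------------------------------------------------------
# donor / acceptor bookkeeping
# ---------------------------------------------------------------------------

def _heavy_hydrogen_pairs(frame: Frame, topology: Topology) -> dict[int, list[int]]:
    """Map each N/O/S heavy atom to its covalently attached hydrogens.

    Water hydrogens attach to their own molecule's oxygen by construction;
    protein hydrogens attach to the nearest heavy atom within 0.125 nm in the
    given frame (no bonded topology is required).
    """
    attached: dict[int, list[int]] = {}
    for mol in topology.water_molecules():
        oxy = next(i for i in mol if topology.atoms[i].element == "O")
        hyds = [i for i in mol if topology.atoms[i].element == "H"]
        attached[oxy] = hyds
    prot = topology.protein_atoms
    if len(prot):
        prot_heavy = np.array([i for i in prot if topology.atoms[i].is_heavy])
        prot_h = np.array([i for i in prot
                           if topology.atoms[i].element == "H"])
        if len(prot_h) and len(prot_heavy):
            box = frame.box
            tree = cKDTree(wrap_coords(frame.coords[prot_heavy], box),
                           boxsize=box)
            dist, nearest = tree.query(wrap_coords(frame.coords[prot_h], box))
            for h, d, k in zip(prot_h, dist, nearest):
                if d <= _H_BOND_MAX:
                    attached.setdefault(int(prot_heavy[k]), []).append(int(h))
    return attached


def detect_hbonds(frame: Frame, topology: Topology,
                  criterion: HBondCriterion = HBondCriterion()) -> list[HBond]:
    """All geometric hydrogen bonds of one frame, each reported once.

    Donors are N/O/S atoms with attached hydrogens, acceptors any N/O/S atom;
    donor–acceptor pairs inside the same water molecule or the same protein
    residue are never reported.
    """
    if not any(a.element == "H" for a in topology.atoms):
        raise ValueError("topology has no hydrogens; hydrogen-bond detection "
                         "needs all-atom (or at least polar-H) input")
    attached = _heavy_hydrogen_pairs(frame, topology)
    acceptors = np.array([a.index for a in topology.atoms
                          if a.element in DONOR_ACCEPTOR_ELEMENTS
                          and a.segment in ("water", "protein")], dtype=int)
    donors = np.array([i for i in acceptors if attached.get(i)], dtype=int)
    if len(acceptors) == 0 or len(donors) == 0:
        return []

    box = frame.box
    tree = cKDTree(wrap_coords(frame.coords[acceptors], box), boxsize=box)
    neighbours = tree.query_ball_point(wrap_coords(frame.coords[donors], box),
                                       criterion.max_da_distance)
    cos_max = np.cos(np.radians(criterion.max_hda_angle))
    atoms = topology.atoms
    bonds: list[HBond] = []
    for d_pos, d in enumerate(donors):
        d_res = atoms[d].residue_index
        d_seg = atoms[d].segment
        for a_pos in neighbours[d_pos]:
            a = int(acceptors[a_pos])
            if a == d:
                continue
            if atoms[a].residue_index == d_res:
                continue  # same water molecule / same protein residue
            da = min_image_vectors(frame.coords[a] - frame.coords[d], box)
            nda = np.linalg.norm(da)
            if nda > criterion.max_da_distance or nda == 0:
                continue
            for h in attached[int(d)]:
                dh = min_image_vectors(frame.coords[h] - frame.coords[d], box)
                cosang = float(dh @ da / (np.linalg.norm(dh) * nda))
                if cosang >= cos_max:
                    a_seg = atoms[a].segment
                    cat = {("water", "water"): "ww",
                           ("protein", "protein"): "pp"}.get(
                               (d_seg, a_seg), "wp")
                    bonds.append(HBond(int(d), int(h), a, cat))
                    break   # one bond per donor-acceptor pair
    return bonds


def classify_waters(frame: Frame, topology: Topology,
                    shell_cutoff: float = 0.4) -> np.ndarray:
    """Boolean array per water molecule: True = interface, False = bulk.

    A water is interface when its oxygen lies within *shell_cutoff* of the
    nearest protein *heavy* atom (minimum image).
    """
    mols = topology.water_molecules()
    oxy = topology.water_oxygens
    prot_heavy = np.array([a.index for a in topology.atoms
                           if a.segment == "protein" and a.is_heavy],
                          dtype=int)
    if len(prot_heavy) == 0 or len(mols) == 0:
        return np.zeros(len(mols), dtype=bool)
    box = frame.box
    tree = cKDTree(wrap_coords(frame.coords[prot_heavy], box), boxsize=box)
    dist, _ = tree.query(wrap_coords(frame.coords[oxy], box))
    return dist <= shell_cutoff


def hydration_report(ensemble: Ensemble,
                     criterion: HBondCriterion = HBondCriterion(),
                     shell_cutoff: float = 0.4) -> HydrationReport:
    """Weight-averaged hydrogen-bond bookkeeping split by hydration shell.

    Per-molecule counts are donated-plus-accepted; category means pool all
    waters of a frame, then weight-average across frames.  ``hb_pp_total``
    and ``hb_pw_total`` are whole-system per-frame bond counts.
    """
    top = ensemble.topology
    mols = top.water_molecules()
    oxy_to_mol = {}
    for m, rng_ in enumerate(mols):
        for i in rng_:
            oxy_to_mol[i] = m

    acc = {k: 0.0 for k in ("n_int", "n_blk", "ww_int", "wp_int",
                            "blk", "pp", "pw")}
    for w, frame in zip(ensemble.weights, ensemble.frames):
        bonds = detect_hbonds(frame, top, criterion)
        interface = classify_waters(frame, top, shell_cutoff)
        ww = np.zeros(len(mols))
        wp = np.zeros(len(mols))
        n_pp = n_pw = 0
        for b in bonds:
            if b.category == "pp":
                n_pp += 1
                continue
            partners = [oxy_to_mol[i] for i in (b.donor_atom, b.acceptor_atom)
                        if i in oxy_to_mol]
            if b.category == "ww":
                for m in partners:
                    ww[m] += 1.0
            else:
                n_pw += 1
                for m in partners:
                    wp[m] += 1.0
        n_int = int(np.sum(interface))
        n_blk = len(mols) - n_int
        acc["n_int"] += w * n_int
        acc["n_blk"] += w * n_blk
        if n_int:
            acc["ww_int"] += w * ww[interface].mean()
            acc["wp_int"] += w * wp[interface].mean()
        if n_blk:
            acc["blk"] += w * (ww[~interface] + wp[~interface]).mean()
        acc["pp"] += w * n_pp
        acc["pw"] += w * n_pw

    return HydrationReport(
        n_interface_waters=acc["n_int"], n_bulk_waters=acc["n_blk"],
        hb_ww_interface=acc["ww_int"], hb_wp_interface=acc["wp_int"],
        hb_total_interface=acc["ww_int"] + acc["wp_int"],
        hb_bulk=acc["blk"], hb_pp_total=acc["pp"], hb_pw_total=acc["pw"])


# ---------------------------------------------------------------------------
# water rotational anisotropy
# ---------------------------------------------------------------------------

def _pair_geometry(frame: Frame, topology: Topology):
    """Distances and orientation factors of all (water O, protein atom) pairs.

    Returns (r, s) flat arrays with s = 3cos²ϑ − 1, ϑ the angle between the
    water-plane normal and the O→protein-atom vector.
    """
    oxy = topology.water_oxygens
    prot = topology.protein_atoms
    if len(oxy) == 0 or len(prot) == 0:
        return np.empty(0), np.empty(0)
    mols = topology.water_molecules()
    h_pairs = []
    for rng_ in mols:
        hyds = [i for i in rng_ if topology.atoms[i].element == "H"]
        h_pairs.append(hyds[:2])
    h_pairs = np.array(h_pairs)

    o_xyz = frame.coords[oxy]
    oh1 = min_image_vectors(frame.coords[h_pairs[:, 0]] - o_xyz, frame.box)
    oh2 = min_image_vectors(frame.coords[h_pairs[:, 1]] - o_xyz, frame.box)
    normal = np.cross(oh1, oh2)
    norms = np.linalg.norm(normal, axis=1)
    if np.any(norms < 1e-10):
        raise ValueError("degenerate water geometry: collinear O–H vectors")
    normal /= norms[:, None]

    delta = min_image_vectors(
        frame.coords[prot][None, :, :] - o_xyz[:, None, :], frame.box)
    r = np.linalg.norm(delta, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("wpk,wk->wp", delta, normal) / r
    s = 3.0 * cos * cos - 1.0
    return r.ravel(), s.ravel()


def rdf_unnormalized(ensemble: Ensemble, bin_width: float = 0.01,
                     r_max: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Weight-averaged histogram of water-O → protein-atom pair distances.

    Returns (bin_edges, counts); counts are raw pair numbers per bin averaged
    over frames, not normalised by shell volume or density.
    """
    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for w, frame in zip(ensemble.weights, ensemble.frames):
        r, _ = _pair_geometry(frame, ensemble.topology)
        h, _ = np.histogram(r, bins=edges)
        counts += w * h
    return edges, counts


def anisotropy_profile(ensemble: Ensemble, bin_width: float = 0.01,
                       r_max: float = 1.5) -> AnisotropyProfile:
    """A(r) = ⟨3cos²ϑ − 1⟩ · RDF(r) over water–protein-atom pairs."""
    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    nb = len(edges) - 1
    rdf = np.zeros(nb)
    s_sum = np.zeros(nb)
    n_pairs = np.zeros(nb)
    for w, frame in zip(ensemble.weights, ensemble.frames):
        r, s = _pair_geometry(frame, ensemble.topology)
        sel = r < r_max
        idx = np.minimum((r[sel] / bin_width).astype(int), nb - 1)
        rdf += w * np.bincount(idx, minlength=nb)
        s_sum += np.bincount(idx, weights=w * s[sel], minlength=nb)
        n_pairs += np.bincount(idx, weights=np.full(sel.sum(), w),
                               minlength=nb)
    with np.errstate(invalid="ignore"):
        mean_s = np.where(n_pairs > 0, s_sum / n_pairs, 0.0)
    return AnisotropyProfile(bin_edges=edges, A=mean_s * rdf, rdf=rdf)


def total_anisotropy(profile: AnisotropyProfile) -> float:
    """∫|A(r)| dr by the rectangle rule over the profile's own bins."""
    return profile.total
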