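"""Pairwise nonbonded energies and their protein/water decomposition.

Lennard-Jones 12-6 with Lorentz–Berthelot combination rules plus truncated
Coulomb, both cut at 0.9 nm (minimum image, plain truncation — no Ewald
summation, so absolute electrostatics differ from mesh-based schemes; the
decomposition identity pp + pw + ww = total is scheme-independent).

Intra-molecular pairs are excluded: both atoms in the same water molecule,
or both in the same protein residue.  Ion pairs are filed under pw or ww
according to the ion's partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import Ensemble, Frame, Topology, min_image_vectors

#: Coulomb prefactor 1/(4πε0) in kJ·nm·mol⁻¹·e⁻².
COULOMB_CONSTANT = 138.935485

#: Default per-atom-type table for the synthetic systems: the four-site
#: rigid water model plus generic protein atom types.  σ in nm, ε in kJ/mol,
#: charge in e.  Keyed by (segment, element); water hydrogens/M carry the
#: rigid model's charges, protein types carry small generic charges.
DEFAULT_TYPES: dict[tuple[str, str], tuple[float, float, float]] = {
    ("water", "O"): (0.31589, 0.77490, 0.0),
    ("water", "H"): (0.0, 0.0, 0.5564),
    ("water", "M"): (0.0, 0.0, -1.1128),
    ("protein", "C"): (0.340, 0.360, 0.10),
    ("protein", "N"): (0.325, 0.711, -0.40),
    ("protein", "O"): (0.296, 0.879, -0.45),
    ("protein", "S"): (0.356, 1.046, -0.10),
    ("protein", "H"): (0.107, 0.065, 0.25),
    ("ion", "NA"): (0.2584, 0.4184, 1.0),
    ("ion", "CL"): (0.4045, 0.4184, -1.0),
}


@dataclass
class NonbondedParams:
    sigma: np.ndarray               # (n_atoms,) nm
    epsilon: np.ndarray             # (n_atoms,) kJ/mol
    charge: np.ndarray              # (n_atoms,) e
    cutoff: float = 0.9             # nm

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.charge = np.asarray(self.charge, dtype=float)
        if np.any(self.sigma < 0) or np.any(self.epsilon < 0):
            raise ValueError("sigma and epsilon must be non-negative")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @classmethod
    def from_topology(cls, topology: Topology, cutoff: float = 0.9,
                      table: dict | None = None) -> "NonbondedParams":
        """Assign parameters from the packaged (segment, element) table."""
        t = table or DEFAULT_TYPES
        sig, eps, chg = [], [], []
        for a in topology.atoms:
            key = (a.segment, a.element)
            if key not in t:
                raise KeyError(f"no nonbonded parameters for {key}")
            s, e, q = t[key]
            sig.append(s)
            eps.append(e)
            chg.append(q)
        return cls(np.array(sig), np.array(eps), np.array(chg), cutoff)

    @classmethod
    def from_tsv(cls, path: str, topology: Topology,
                 cutoff: float = 0.9) -> "NonbondedParams":
        """Per-atom-name table: columns atom_name, sigma, epsilon, charge."""
        df = pd.read_csv(path, sep=r"\s+")
        by_name = {str(r.atom_name): (r.sigma, r.epsilon, r.charge)
                   for r in df.itertuples()}
        sig, eps, chg = [], [], []
        for a in topology.atoms:
            if a.name not in by_name:
                raise KeyError(f"no parameters for atom name {a.name!r}")
            s, e, q = by_name[a.name]
            sig.append(s)
            eps.append(e)
            chg.append(q)
        return cls(np.array(sig), np.array(eps), np.array(chg), cutoff)


@dataclass
class EnergyDecomposition:
    vdw_pp: float
    vdw_pw: float
    vdw_ww: float
    coul_pp: float
    coul_pw: float
    coul_ww: float

    @property
    def total(self) -> float:
        return (self.vdw_pp + self.vdw_pw + self.vdw_ww
                + self.coul_pp + self.coul_pw + self.coul_ww)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["total"] = self.total
        return d


def _excluded(topology: Topology, i: int, j: int) -> bool:
    ai, aj = topology.atoms[i], topology.atoms[j]
    if ai.residue_index != aj.residue_index:
        return False
    return ai.segment in ("water", "protein")


def pairwise_nonbonded(frame: Frame, topology: Topology,
                       params: NonbondedParams, i: int, j: int
                       ) -> tuple[float, float]:
    """(vdW, Coulomb) energy of one atom pair in kJ/mol; zero beyond cutoff."""
    d = min_image_vectors(frame.coords[j] - frame.coords[i], frame.box)
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise ValueError(f"zero distance between atoms {i} and {j}")
    if r > params.cutoff or _excluded(topology, i, j):
        return 0.0, 0.0
    sig = 0.5 * (params.sigma[i] + params.sigma[j])
    eps = np.sqrt(params.epsilon[i] * params.epsilon[j])
    vdw = 0.0
    if eps > 0 and sig > 0:
        sr6 = (sig / r) ** 6
        vdw = 4.0 * eps * (sr6 * sr6 - sr6)
    coul = COULOMB_CONSTANT * params.charge[i] * params.charge[j] / r
    return float(vdw), float(coul)


def _category(topology: Topology, i: int, j: int) -> str:
    segs = {topology.atoms[i].segment, topology.atoms[j].segment}
    if segs == {"protein"}:
        return "pp"
    if "protein" in segs:
        return "pw"          # protein with water or ion
    return "ww"              # water-water, water-ion, ion-ion


def decompose_energy(ensemble: Ensemble,
                     params: NonbondedParams) -> EnergyDecomposition:
    """Weight-averaged pp/pw/ww split of the total pairwise nonbonded energy.

    Every in-range, non-excluded pair lands in exactly one category, so the
    six terms always sum to the total pairwise energy.
    """
    top = ensemble.topology
    n = top.n_atoms
    seg_code = np.array([{"protein": 0, "water": 1, "ion": 2}[a.segment]
                         for a in top.atoms])
    res_idx = np.array([a.residue_index for a in top.atoms])
    ii, jj = np.triu_indices(n, k=1)
    excl = (res_idx[ii] == res_idx[jj]) & (seg_code[ii] != 2)
    # category per pair: pp=0, pw=1, ww=2
    pair_cat = np.where((seg_code[ii] == 0) & (seg_code[jj] == 0), 0,
                        np.where((seg_code[ii] == 0) | (seg_code[jj] == 0),
                                 1, 2))
    sig = 0.5 * (params.sigma[ii] + params.sigma[jj])
    eps = np.sqrt(params.epsilon[ii] * params.epsilon[jj])
    qq = COULOMB_CONSTANT * params.charge[ii] * params.charge[jj]

    vdw_acc = np.zeros(3)
    coul_acc = np.zeros(3)
    for w, frame in zip(ensemble.weights, ensemble.frames):
        delta = min_image_vectors(frame.coords[jj] - frame.coords[ii],
                                  frame.box)
        r = np.linalg.norm(delta, axis=1)
        if np.any(r[~excl] == 0):
            raise ValueError("coincident atoms in a non-excluded pair")
        live = (r <= params.cutoff) & ~excl
        rl = r[live]
        with np.errstate(divide="ignore", invalid="ignore"):
            sr6 = np.where((sig[live] > 0) & (eps[live] > 0),
                           (sig[live] / rl) ** 6, 0.0)
        vdw = 4.0 * eps[live] * (sr6 * sr6 - sr6)
        coul = qq[live] / rl
        for c in range(3):
            sel = pair_cat[live] == c
            vdw_acc[c] += w * vdw[sel].sum()
            coul_acc[c] += w * coul[sel].sum()

    return EnergyDecomposition(
        vdw_pp=float(vdw_acc[0]), vdw_pw=float(vdw_acc[1]),
        vdw_ww=float(vdw_acc[2]), coul_pp=float(coul_acc[0]),
        coul_pw=float(coul_acc[1]), coul_ww=float(coul_acc[2]))
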