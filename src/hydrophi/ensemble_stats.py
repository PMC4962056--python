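"""Per-ensemble structural summaries: radius of gyration and dihedral-based
secondary-structure populations (α, β, polyproline II, coil).

Secondary structure is assigned per residue from backbone (φ, ψ) alone, by
membership in rectangular Ramachandran boxes.  A single dihedral-only scheme
is used for all three classes because polyproline II has no hydrogen-bond
signature; the boxes are configurable.  Chain termini (undefined φ or ψ) are
always coil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import Ensemble, Frame, Topology


@dataclass(frozen=True)
class RamachandranRegions:
    """Rectangular (φ, ψ) boxes in degrees.  β's ψ range wraps through 180°."""
    alpha_phi: tuple[float, float] = (-100.0, -30.0)
    alpha_psi: tuple[float, float] = (-80.0, -5.0)
    beta_phi: tuple[float, float] = (-180.0, -90.0)
    beta_psi: tuple[tuple[float, float], ...] = ((90.0, 180.0),
                                                 (-180.0, -170.0))
    ppii_phi: tuple[float, float] = (-90.0, -20.0)
    ppii_psi: tuple[float, float] = (120.0, 180.0)

    def classify(self, phi: float, psi: float) -> str:
        if self.alpha_phi[0] <= phi <= self.alpha_phi[1] \
                and self.alpha_psi[0] <= psi <= self.alpha_psi[1]:
            return "alpha"
        if self.beta_phi[0] <= phi <= self.beta_phi[1] \
                and any(lo <= psi <= hi for lo, hi in self.beta_psi):
            return "beta"
        # half-open in φ at −90 so β and PPII stay disjoint
        if self.ppii_phi[0] < phi <= self.ppii_phi[1] \
                and self.ppii_psi[0] <= psi <= self.ppii_psi[1]:
            return "ppii"
        return "coil"


SS_CLASSES = ("alpha", "beta", "ppii", "coil")


@dataclass
class SSPopulations:
    per_residue: pd.DataFrame       # columns f_alpha, f_beta, f_ppii, f_coil
    means: dict[str, float]         # ensemble-level means over residues


def radius_of_gyration(frame: Frame, topology: Topology) -> float:
    """Mass-weighted radius of gyration (nm) over protein atoms.

    Coordinates are taken as given (the protein is assumed whole, not
    wrapped across the periodic boundary).
    """
    idx = topology.protein_atoms
    if len(idx) < 2:
        raise ValueError("need at least two protein atoms")
    m = np.array([topology.atoms[i].mass for i in idx])
    x = frame.coords[idx]
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((x - com) ** 2).sum(axis=1)).sum() / m.sum()))


def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, IUPAC sign convention."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(frame: Frame, topology: Topology) -> np.ndarray:
    """(n_residues, 2) array of (φ, ψ) in degrees; NaN where undefined."""
    n_res = topology.n_residues
    names = {}
    for a in topology.atoms:
        if a.segment == "protein" and a.name in ("N", "CA", "C"):
            names[(a.residue_index, a.name)] = a.index

    def pos(res: int, name: str):
        key = (res, name)
        if key not in names:
            raise ValueError(f"missing backbone atom {name} in residue {res}")
        return frame.coords[names[key]]

    out = np.full((n_res, 2), np.nan)
    protein_res = sorted({a.residue_index for a in topology.atoms
                          if a.segment == "protein"})
    for r in protein_res:
        if r - 1 in protein_res:
            out[r, 0] = _dihedral(pos(r - 1, "C"), pos(r, "N"),
                                  pos(r, "CA"), pos(r, "C"))
        if r + 1 in protein_res:
            out[r, 1] = _dihedral(pos(r, "N"), pos(r, "CA"),
                                  pos(r, "C"), pos(r + 1, "N"))
    return out


def classify_secondary_structure(
        frame: Frame, topology: Topology,
        regions: RamachandranRegions = RamachandranRegions()) -> list[str]:
    """Per-residue α/β/PPII/coil label from (φ, ψ); termini are coil."""
    dihedrals = backbone_dihedrals(frame, topology)
    labels = []
    for phi, psi in dihedrals:
        if np.isnan(phi) or np.isnan(psi):
            labels.append("coil")
        else:
            labels.append(regions.classify(phi, psi))
    return labels


def ss_populations(ensemble: Ensemble,
                   regions: RamachandranRegions = RamachandranRegions()
                   ) -> SSPopulations:
    """Weight-averaged per-residue class frequencies and their means."""
    top = ensemble.topology
    counts = np.zeros((top.n_residues, len(SS_CLASSES)))
    for w, frame in zip(ensemble.weights, ensemble.frames):
        for r, lab in enumerate(classify_secondary_structure(frame, top,
                                                             regions)):
            counts[r, SS_CLASSES.index(lab)] += w
    df = pd.DataFrame(counts, columns=[f"f_{c}" for c in SS_CLASSES])
    df.insert(0, "residue", np.arange(1, top.n_residues + 1))
    means = {f"f_{c}": float(counts[:, k].mean())
             for k, c in enumerate(SS_CLASSES)}
    return SSPopulations(per_residue=df, means=means)
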