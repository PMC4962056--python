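"""Native contacts, Q, Φ-values, the Φ-restraint pseudo-energy and Brønsted
statistics.

Native contacts are atom pairs: for two residues that are not sequence
neighbours, every pair of heavy side-chain atoms within the cutoff
(default 0.65 nm) in the native structure is one contact.  The fraction of
native contacts Q of a conformation is the share of those atom pairs still
within the formation cutoff; the Φ-value of residue *i* is the same fraction
restricted to pairs involving *i*.  Experimentally, Φ = ΔΔG_TS-N / ΔΔG_D-N
per mutant, and a Brønsted plot regresses ΔΔG_TS-N on ΔΔG_D-N across
mutants: a tight line indicates a nucleation–condensation mechanism, scatter
indicates diffusion–collision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import Ensemble, Frame, Topology, pair_distances

# Backbone atom names; everything else that is heavy counts as side chain.
# Cβ belongs to the side chain (alanine's only side-chain heavy atom);
# glycine therefore contributes no contact atoms.
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "OT1", "OT2", "H", "HN", "HA"}


@dataclass
class NativeContactMap:
    atom_pairs: np.ndarray          # (n_pairs, 2) int atom indices
    residue_pairs: np.ndarray       # (n_pairs, 2) int residue indices
    cutoff: float                   # nm
    neighbour_exclusion: int
    n_residues: int

    @property
    def n_pairs(self) -> int:
        return len(self.atom_pairs)

    def pairs_per_residue(self) -> np.ndarray:
        """Number of native atom-pair contacts each residue participates in."""
        counts = np.zeros(self.n_residues, dtype=int)
        for i, j in self.residue_pairs:
            counts[i] += 1
            counts[j] += 1
        return counts


@dataclass
class PhiSet:
    phi: np.ndarray                 # per-residue (or per-entry) value
    valid: np.ndarray               # per-entry boolean
    residue_ids: np.ndarray | None = None   # 1-based ids for I/O surfaces

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.phi.shape != self.valid.shape:
            raise ValueError("phi and valid must align")

    def to_frame(self) -> pd.DataFrame:
        ids = (self.residue_ids if self.residue_ids is not None
               else np.arange(1, len(self.phi) + 1))
        return pd.DataFrame({"residue": ids, "phi": self.phi,
                             "valid": self.valid})


@dataclass
class DDGTable:
    """Per-mutant destabilisation free energies (kJ/mol, mutant − wild type)."""
    residue_ids: np.ndarray
    ddg_dn: np.ndarray              # ΔΔG_D-N
    ddg_tsn: np.ndarray             # ΔΔG_TS-N

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.ddg_dn = np.asarray(self.ddg_dn, dtype=float)
        self.ddg_tsn = np.asarray(self.ddg_tsn, dtype=float)
        if not (len(self.residue_ids) == len(self.ddg_dn) == len(self.ddg_tsn)):
            raise ValueError("columns must align")
        if not (np.all(np.isfinite(self.ddg_dn))
                and np.all(np.isfinite(self.ddg_tsn))):
            raise ValueError("non-finite ΔΔG values")

    @property
    def n(self) -> int:
        return len(self.residue_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residue_ids,
                             "ddG_DN": self.ddg_dn,
                             "ddG_TSN": self.ddg_tsn})

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "DDGTable":
        df = pd.read_csv(path, sep=r"\s+")
        return cls(df["residue"].to_numpy(), df["ddG_DN"].to_numpy(),
                   df["ddG_TSN"].to_numpy())


@dataclass
class BronstedResult:
    pearson_r: float
    slope: float
    intercept: float
    n: int


def sidechain_heavy_atoms(topology: Topology) -> np.ndarray:
    """Indices of protein heavy atoms outside the backbone."""
    return np.array([a.index for a in topology.atoms
                     if a.segment == "protein" and a.is_heavy
                     and a.name not in BACKBONE_NAMES], dtype=int)


def native_contacts(native: tuple[Topology, Frame], cutoff: float = 0.65,
                    neighbour_exclusion: int = 2) -> NativeContactMap:
    """Enumerate native side-chain heavy-atom contacts.

    Two residues at sequence separation ≥ *neighbour_exclusion* contribute one
    contact per heavy side-chain atom pair within *cutoff* in the native
    frame (minimum-image distances).
    """
    topology, frame = native
    sc = sidechain_heavy_atoms(topology)
    if len(sc) == 0:
        raise ValueError("native structure has no side-chain heavy atoms")
    res_of = np.array([topology.atoms[i].residue_index for i in sc])
    d = pair_distances(frame.coords[sc], frame.coords[sc], frame.box)
    ii, jj = np.triu_indices(len(sc), k=1)
    sep = np.abs(res_of[ii] - res_of[jj])
    keep = (d[ii, jj] <= cutoff) & (sep >= neighbour_exclusion)
    atom_pairs = np.column_stack([sc[ii[keep]], sc[jj[keep]]])
    residue_pairs = np.column_stack([res_of[ii[keep]], res_of[jj[keep]]])
    # order residue pairs (i < j) for a canonical multiset
    flip = residue_pairs[:, 0] > residue_pairs[:, 1]
    residue_pairs[flip] = residue_pairs[flip][:, ::-1]
    atom_pairs[flip] = atom_pairs[flip][:, ::-1]
    return NativeContactMap(atom_pairs=atom_pairs, residue_pairs=residue_pairs,
                            cutoff=cutoff,
                            neighbour_exclusion=neighbour_exclusion,
                            n_residues=topology.n_residues)


def _formed(frame: Frame, cmap: NativeContactMap,
            formation_cutoff: float | None) -> np.ndarray:
    cut = cmap.cutoff if formation_cutoff is None else formation_cutoff
    a = frame.coords[cmap.atom_pairs[:, 0]]
    b = frame.coords[cmap.atom_pairs[:, 1]]
    from .io_core import min_image_vectors
    d = np.linalg.norm(min_image_vectors(b - a, frame.box), axis=1)
    return d <= cut


def fraction_native_contacts(frame: Frame, cmap: NativeContactMap,
                             formation_cutoff: float | None = None) -> float:
    """Q of a single conformation: formed native atom pairs / total."""
    if cmap.n_pairs == 0:
        raise ValueError("empty contact map")
    return float(np.mean(_formed(frame, cmap, formation_cutoff)))


def contact_formation_map(ensemble: Ensemble, cmap: NativeContactMap,
                          formation_cutoff: float | None = None) -> np.ndarray:
    """Residue×residue matrix of weight-averaged contact-formation fractions.

    Entry (i, j) averages, over frames and over the native atom pairs linking
    residues i and j, the indicator that the pair is formed.  Symmetric; NaN
    where the residue pair has no native contacts.
    """
    if cmap.n_pairs == 0:
        raise ValueError("empty contact map")
    n = cmap.n_residues
    formed_mean = np.zeros(cmap.n_pairs)
    for w, frame in zip(ensemble.weights, ensemble.frames):
        formed_mean += w * _formed(frame, cmap, formation_cutoff)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for k, (i, j) in enumerate(cmap.residue_pairs):
        num[i, j] += formed_mean[k]
        den[i, j] += 1.0
    num += np.triu(num, 1).T
    den += np.triu(den, 1).T
    with np.errstate(invalid="ignore"):
        return num / den


def phi_from_ensemble(ensemble: Ensemble, cmap: NativeContactMap,
                      formation_cutoff: float | None = None) -> PhiSet:
    """Structure-based Φ: per residue, the weight-averaged fraction of its
    native atom-pair contacts that are formed.  Residues with no native
    contacts are flagged invalid (Φ = NaN)."""
    if cmap.n_pairs == 0:
        raise ValueError("empty contact map")
    n = cmap.n_residues
    per_res_total = cmap.pairs_per_residue().astype(float)
    per_res_formed = np.zeros(n)
    for w, frame in zip(ensemble.weights, ensemble.frames):
        formed = _formed(frame, cmap, formation_cutoff)
        for k, (i, j) in enumerate(cmap.residue_pairs):
            if formed[k]:
                per_res_formed[i] += w
                per_res_formed[j] += w
    valid = per_res_total > 0
    phi = np.full(n, np.nan)
    phi[valid] = per_res_formed[valid] / per_res_total[valid]
    return PhiSet(phi=phi, valid=valid)


def phi_restraint_energy(phi_sim: PhiSet, phi_exp: PhiSet, k: float) -> float:
    """Pseudo-energy E = k · Σ (Φ_sim − Φ_exp)² over commonly valid residues.

    Experimental entries outside [0, 1] are never restrained (they cannot be
    interpreted as a fraction of native contacts), regardless of their flag.
    """
    if phi_sim.phi.shape != phi_exp.phi.shape:
        raise ValueError("Φ sets must cover the same residues")
    exp_ok = phi_exp.valid & (phi_exp.phi >= 0) & (phi_exp.phi <= 1)
    common = phi_sim.valid & exp_ok
    if not np.any(common):
        raise ValueError("no commonly valid residues to restrain")
    diff = phi_sim.phi[common] - phi_exp.phi[common]
    return float(k * np.sum(diff * diff))


def phi_from_ddg(table: DDGTable, min_ddg: float = 2.5) -> PhiSet:
    """Experimental Φ = (ΔΔG_D-N − ΔΔG_TS-N) / ΔΔG_D-N per mutant.

    Mutants with |ΔΔG_D-N| below *min_ddg* (default 2.5 kJ/mol, the usual
    reliability floor) are flagged invalid, as are Φ outside [0, 1].
    Multiple mutants at one residue are averaged with a warning.
    """
    if table.n == 0:
        raise ValueError("empty ΔΔG table")
    ids, counts = np.unique(table.residue_ids, return_counts=True)
    if np.any(counts > 1):
        warnings.warn("multiple mutants at one residue; Φ values averaged")
    phi_list, valid_list = [], []
    for rid in ids:
        sel = table.residue_ids == rid
        dn, tsn = table.ddg_dn[sel], table.ddg_tsn[sel]
        ok = np.abs(dn) >= min_ddg
        if not np.any(ok):
            phi_list.append(np.nan)
            valid_list.append(False)
            continue
        phi = float(np.mean((dn[ok] - tsn[ok]) / dn[ok]))
        phi_list.append(phi)
        valid_list.append(bool(0.0 <= phi <= 1.0))
    return PhiSet(phi=np.array(phi_list), valid=np.array(valid_list),
                  residue_ids=ids)


def bronsted(table: DDGTable) -> BronstedResult:
    """Pearson correlation and least-squares line of ΔΔG_TS-N vs ΔΔG_D-N."""
    if table.n < 3:
        raise ValueError("Brønsted analysis needs at least 3 mutants")
    if np.std(table.ddg_dn) == 0 or np.std(table.ddg_tsn) == 0:
        raise ValueError("zero variance in a ΔΔG column")
    lr = stats.linregress(table.ddg_dn, table.ddg_tsn)
    return BronstedResult(pearson_r=float(lr.rvalue), slope=float(lr.slope),
                          intercept=float(lr.intercept), n=table.n)
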