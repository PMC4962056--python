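"""Synthetic inputs for every pipeline stage.

These generators stand in for the expensive parts of a solvated-protein MD
study: peptides with prescribed backbone dihedrals, water boxes with exact
rigid-model internal geometry, conformational ensembles in which each native
contact is formed with a prescribed probability, and mutational ΔΔG tables
with an exactly prescribed Brønsted correlation.  Everything is deterministic
under an explicit seed; there is no global random state.

The water boxes are jittered lattices with uniformly random molecular
orientations — valid geometry and exact rotational isotropy (the null case of
the anisotropy statistic), but no claim of a liquid-state radial distribution
function.  Equilibrated water comes from :mod:`.watermc` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contacts_phi import DDGTable, NativeContactMap, native_contacts
from .io_core import (TIP4P2005, Atom, Ensemble, Frame, Topology, WaterModel,
                      build_topology, min_image_vectors, pair_distances)

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

#: Canonical (φ, ψ) in degrees for the named backbone classes.
CANONICAL_DIHEDRALS = {
    "alpha": (-57.0, -47.0),
    "beta": (-135.0, 135.0),
    "ppii": (-75.0, 145.0),
}

# Ideal backbone internal coordinates (nm / degrees).
_B_NCA, _B_CAC, _B_CN = 0.1458, 0.1525, 0.1329
_B_CO, _B_CACB, _B_NH = 0.1231, 0.1521, 0.1010
_A_NCAC, _A_CACN, _A_CNCA = 111.0, 116.6, 121.9
_A_CACO, _A_NCACB = 120.5, 110.5
_T_NCCACB = 122.6          # improper fixing L-chirality of Cβ
_OMEGA = 180.0             # trans peptide bond


@dataclass(frozen=True)
class PeptideSpec:
    sequence: str
    dihedrals: str | list[tuple[float, float]] = "alpha"
    seed: int = 0

    def resolved_dihedrals(self, rng: np.random.Generator) -> list[tuple[float, float]]:
        n = len(self.sequence)
        if isinstance(self.dihedrals, str):
            name = self.dihedrals.lower()
            if name == "coil":
                basins = list(CANONICAL_DIHEDRALS.values()) + [(-150.0, 60.0)]
                out = []
                for _ in range(n):
                    phi0, psi0 = basins[rng.integers(len(basins))]
                    out.append((phi0 + rng.uniform(-15, 15),
                                psi0 + rng.uniform(-15, 15)))
                return out
            if name not in CANONICAL_DIHEDRALS:
                raise ValueError(f"unknown dihedral class {self.dihedrals!r}")
            return [CANONICAL_DIHEDRALS[name]] * n
        if len(self.dihedrals) != n:
            raise ValueError("need one (φ,ψ) pair per residue")
        return list(self.dihedrals)


@dataclass(frozen=True)
class WaterBoxSpec:
    n_molecules: int
    box: float | tuple[float, float, float] | None = None
    density: float | None = None        # g/cm³, used when box is None
    seed: int = 0
    model: WaterModel = TIP4P2005

    def box_lengths(self) -> np.ndarray:
        if self.box is not None:
            b = np.atleast_1d(np.asarray(self.box, dtype=float))
            return np.full(3, b[0]) if b.size == 1 else b
        rho = self.density if self.density is not None else 0.997
        # L³ = N · M_w / (ρ N_A)
        vol_nm3 = self.n_molecules * 18.01528 / (rho * 602.214076)
        return np.full(3, vol_nm3 ** (1.0 / 3.0))


@dataclass
class SynthEnsembleSpec:
    native: tuple[Topology, Frame]
    contact_formation_p: float | np.ndarray
    n_frames: int
    seed: int = 0
    contact_cutoff: float = 0.65
    neighbour_exclusion: int = 2


@dataclass(frozen=True)
class DDGSpec:
    n_mutants: int
    target_r: float
    scale: float = 2.5                  # kJ/mol spread of ΔΔG_D-N
    seed: int = 0


# ---------------------------------------------------------------------------
# peptide construction
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from reference atoms A–B–C via internal coordinates."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-math.cos(ang),
                               math.sin(ang) * math.cos(tor),
                               math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(spec: PeptideSpec) -> tuple[Topology, Frame]:
    """Build an all-atom chain (backbone + amide H + Cβ) with exact dihedrals.

    Backbone φ/ψ torsions match the spec targets to machine precision by
    construction (internal-coordinate chain building); glycine gets no Cβ.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.sequence.upper()
    if len(seq) < 2:
        raise ValueError("sequence must have at least 2 residues")
    for letter in seq:
        if letter not in AA1TO3:
            raise ValueError(f"unknown residue letter {letter!r}")
    dihedrals = spec.resolved_dihedrals(rng)

    N = np.zeros((len(seq), 3))
    CA = np.zeros_like(N)
    C = np.zeros_like(N)
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_NCA, 0.0, 0.0)
    ang = math.radians(_A_NCAC)
    C[0] = CA[0] + _B_CAC * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, len(seq)):
        psi_prev = dihedrals[i - 1][1]
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], _B_CN, _A_CACN, psi_prev)
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], _B_NCA, _A_CNCA, _OMEGA)
        C[i] = _nerf(C[i - 1], N[i], CA[i], _B_CAC, _A_NCAC, dihedrals[i][0])

    atom_names: list[str] = []
    residue_names: list[str] = []
    residue_ranges: list[range] = []
    coords: list[np.ndarray] = []
    for i, letter in enumerate(seq):
        start = len(atom_names)
        names = ["N", "CA", "C", "O"]
        O = _nerf(N[i], CA[i], C[i], _B_CO, _A_CACO, dihedrals[i][1] + 180.0)
        res_coords = [N[i], CA[i], C[i], O]
        if letter != "G":
            names.append("CB")
            res_coords.append(_nerf(C[i], N[i], CA[i], _B_CACB, _A_NCACB,
                                    _T_NCCACB))
        if i > 0:
            # planar amide H on the C(prev)–N–CA bisector
            u = (N[i] - CA[i]) / np.linalg.norm(N[i] - CA[i])
            v = (N[i] - C[i - 1]) / np.linalg.norm(N[i] - C[i - 1])
            h_dir = (u + v) / np.linalg.norm(u + v)
            names.append("H")
            res_coords.append(N[i] + _B_NH * h_dir)
        atom_names.extend(names)
        residue_names.append(AA1TO3[letter])
        residue_ranges.append(range(start, start + len(names)))
        coords.extend(res_coords)

    xyz = np.array(coords)
    xyz -= xyz.min(axis=0) - 1.0           # keep everything positive
    top = build_topology(atom_names, residue_names, residue_ranges)
    box = np.maximum(xyz.max(axis=0) + 1.0, 5.0)
    return top, Frame(coords=xyz, box=box)


# ---------------------------------------------------------------------------
# water boxes and solvation
# ---------------------------------------------------------------------------

def water_template(model: WaterModel) -> np.ndarray:
    """Site coordinates of one molecule, O at the origin, bisector along +z."""
    half = math.radians(model.theta_HOH / 2.0)
    h1 = model.r_OH * np.array([math.sin(half), 0.0, math.cos(half)])
    h2 = model.r_OH * np.array([-math.sin(half), 0.0, math.cos(half)])
    sites = [np.zeros(3), h1, h2]
    if model.n_sites == 4:
        sites.append(np.array([0.0, 0.0, model.r_OM]))
    return np.array(sites)


def random_rotations(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform rotation matrices on SO(3) via Shoemake random quaternions."""
    u1, u2, u3 = rng.random(n), rng.random(n), rng.random(n)
    q = np.stack([np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
                  np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
                  np.sqrt(u1) * np.sin(2 * np.pi * u3),
                  np.sqrt(u1) * np.cos(2 * np.pi * u3)], axis=1)
    x, y, z, w = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - z * w)
    R[:, 0, 2] = 2 * (x * z + y * w)
    R[:, 1, 0] = 2 * (x * y + z * w)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - x * w)
    R[:, 2, 0] = 2 * (x * z - y * w)
    R[:, 2, 1] = 2 * (y * z + x * w)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


MIN_OO_SEPARATION = 0.25   # nm, hard floor for generated oxygen positions


def build_water_box(spec: WaterBoxSpec) -> tuple[Topology, Frame]:
    """Water molecules on a jittered cubic lattice with random orientations.

    Internal geometry is the exact rigid-model geometry; oxygens are
    guaranteed ≥ 0.25 nm apart (raises if the requested packing cannot
    honour that).
    """
    rng = np.random.default_rng(spec.seed)
    box = spec.box_lengths()
    n = spec.n_molecules
    cells = int(math.ceil(n ** (1.0 / 3.0)))
    spacing = box / cells
    jitter = np.minimum(0.04, (spacing.min() - MIN_OO_SEPARATION - 0.01) / 2.0)
    if jitter <= 0:
        raise ValueError(
            f"cannot pack {n} molecules in box {box} at ≥ "
            f"{MIN_OO_SEPARATION} nm O–O separation")
    grid = np.array(np.meshgrid(*[np.arange(cells)] * 3,
                                indexing="ij")).reshape(3, -1).T
    chosen = rng.choice(len(grid), size=n, replace=False)
    oxygens = (grid[chosen] + 0.5) * spacing
    oxygens += rng.uniform(-jitter, jitter, size=(n, 3))

    template = water_template(spec.model)
    rot = random_rotations(rng, n)
    sites = oxygens[:, None, :] + np.einsum("nij,sj->nsi", rot, template)

    d = pair_distances(oxygens, oxygens, box)
    np.fill_diagonal(d, np.inf)
    if d.min() < MIN_OO_SEPARATION:
        raise ValueError("O–O separation floor violated; reduce density")

    site_names = list(spec.model.site_names)
    elements = {"O": "O", "H1": "H", "H2": "H", "M": "M"}
    atom_names = site_names * n
    residue_names = ["HOH"] * n
    k = len(site_names)
    residue_ranges = [range(i * k, (i + 1) * k) for i in range(n)]
    top = build_topology(atom_names, residue_names, residue_ranges,
                         water_model=spec.model,
                         elements=[elements[s] for s in atom_names])
    return top, Frame(coords=sites.reshape(-1, 3), box=box)


def solvate(protein: tuple[Topology, Frame] | None,
            spec: WaterBoxSpec,
            clearance: float = 0.24) -> tuple[Topology, Frame]:
    """Centre the protein in a generated water box, deleting clashing waters.

    A water molecule is removed when its oxygen lies within *clearance*
    (default 0.24 nm) of any protein heavy atom.  The combined topology is
    ordered protein first, then the surviving waters.
    """
    wtop, wframe = build_water_box(spec)
    if protein is None:
        return wtop, wframe
    ptop, pframe = protein
    box = wframe.box
    shift = box / 2.0 - pframe.coords.mean(axis=0)
    pcoords = pframe.coords + shift

    heavy = np.array([a.index for a in ptop.atoms if a.is_heavy], dtype=int)
    n_sites = spec.model.n_sites
    oxy = wframe.coords[::n_sites]
    keep = np.ones(spec.n_molecules, dtype=bool)
    if len(heavy):
        d = pair_distances(oxy, pcoords[heavy], box)
        keep = d.min(axis=1) > clearance

    atom_names = [a.name for a in ptop.atoms]
    residue_names = [name for name, _ in ptop.residues]
    residue_ranges = [rng_ for _, rng_ in ptop.residues]
    elements = [a.element for a in ptop.atoms]
    coords = [pcoords]
    offset = ptop.n_atoms
    for m in np.flatnonzero(keep):
        atom_names.extend(spec.model.site_names)
        residue_names.append("HOH")
        residue_ranges.append(range(offset, offset + n_sites))
        elements.extend({"O": "O", "H1": "H", "H2": "H", "M": "M"}[s]
                        for s in spec.model.site_names)
        coords.append(wframe.coords[m * n_sites:(m + 1) * n_sites])
        offset += n_sites
    top = build_topology(atom_names, residue_names, residue_ranges,
                         water_model=spec.model, elements=elements)
    return top, Frame(coords=np.concatenate(coords), box=box)


# ---------------------------------------------------------------------------
# conformational ensembles with prescribed contact statistics
# ---------------------------------------------------------------------------

#: Turn dihedrals giving hairpins whose cross-strand Cα distances fall in
#: the window where Cβ re-orientation can both form and break every contact.
#: The optimal turn depends on the strand registry, hence on chain length.
_HAIRPIN_TURNS = {
    14: ((90.0, -120.0), (-100.0, -40.0)),
    16: ((60.0, -120.0), (-110.0, 40.0)),
}
_HAIRPIN_TURN_DEFAULT = _HAIRPIN_TURNS[14]


def build_hairpin(sequence: str = "KLVFFAEDVGSNKG",
                  seed: int = 0) -> tuple[Topology, Frame]:
    """Two-stranded hairpin native used as the reference contact fixture.

    Cross-strand Cβ contacts sit mid-range between their formation and
    breakage distances, so :func:`generate_ensemble` can modulate each one
    independently (verified for lengths 14 and 16, which carry tuned turn
    geometries).  The sequence must have at least 10 residues; the two
    central residues form the turn.
    """
    n = len(sequence)
    if n < 10:
        raise ValueError("hairpin needs at least 10 residues")
    s = (n - 2) // 2
    strand = CANONICAL_DIHEDRALS["beta"]
    turn = _HAIRPIN_TURNS.get(n, _HAIRPIN_TURN_DEFAULT)
    dih = ([strand] * s + list(turn) + [strand] * (n - 2 - s))
    return build_peptide(PeptideSpec(sequence, dih, seed=seed))

def _solve_sidechain_directions(ca, bond, u_native, pair_res, desired,
                                cut, rng, n_restarts=16, n_steps=500):
    """Find unit side-chain directions realising a formed/broken pattern.

    Projected gradient descent on the unit sphere per residue, minimising
    hinge losses: formed pairs are pushed below the cutoff, broken pairs
    above it (with a small margin).  Returns the direction array or None.
    """
    n_res = len(ca)
    pi, pj = pair_res[:, 0], pair_res[:, 1]
    lo = cut - 0.005          # formed pairs must end below the cutoff
    hi = cut + 0.02           # broken pairs must end above it

    def positions(u):
        return ca + bond[:, None] * u

    def satisfied(u):
        d = np.linalg.norm(positions(u)[pi] - positions(u)[pj], axis=1)
        return np.all(np.where(desired, d <= cut, d > cut + 0.005))

    for restart in range(n_restarts):
        if restart == 0:
            v = u_native.copy()
        else:
            v = u_native + rng.normal(scale=0.3 + 0.2 * restart,
                                      size=u_native.shape)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        lr = 0.2
        for _ in range(n_steps):
            x = positions(v)
            delta = x[pi] - x[pj]
            d = np.linalg.norm(delta, axis=1)
            # hinge gradients: positive coef pulls the pair apart
            coef = np.where(desired,
                            2.0 * np.maximum(d - lo, 0.0),
                            -2.0 * np.maximum(hi - d, 0.0))
            if np.all(coef == 0.0) and satisfied(v):
                return v
            g_x = np.zeros_like(x)
            unit = delta / np.maximum(d, 1e-12)[:, None]
            np.add.at(g_x, pi, coef[:, None] * unit)
            np.add.at(g_x, pj, -coef[:, None] * unit)
            g_u = bond[:, None] * g_x
            v = v - lr * g_u
            v /= np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)
        if satisfied(v):
            return v
    # fallback: vectorised random search over whole orientation sets
    for _ in range(40):
        batch = rng.normal(size=(1000,) + u_native.shape)
        batch /= np.linalg.norm(batch, axis=2, keepdims=True)
        x = ca[None] + bond[None, :, None] * batch
        d = np.linalg.norm(x[:, pi, :] - x[:, pj, :], axis=2)
        ok = np.all(np.where(desired[None, :], d <= cut, d > cut + 0.005),
                    axis=1)
        hits = np.flatnonzero(ok)
        if len(hits):
            return batch[hits[0]]
    return None


def generate_ensemble(spec: SynthEnsembleSpec) -> Ensemble:
    """Frames in which each native contact is formed with its own probability.

    Per frame, the formed/broken state of every native atom-pair contact is an
    independent Bernoulli draw; the geometry is then realised by re-orienting
    side chains about their Calpha (bond lengths preserved) with a projected
    gradient solver until every drawn state is satisfied.  Raises if a drawn
    pattern cannot be realised — dense contact networks (e.g. the core of an
    ideal helix) may be geometrically unable to break every contact at once.

    Only Cbeta-level side chains (one heavy side-chain atom per residue) are
    supported; richer side chains would need rigid-block rotamer moves.
    """
    top, nframe = spec.native
    cmap = native_contacts((top, nframe), cutoff=spec.contact_cutoff,
                           neighbour_exclusion=spec.neighbour_exclusion)
    if cmap.n_pairs == 0:
        raise ValueError("native structure has no contacts to modulate")
    p = np.broadcast_to(np.asarray(spec.contact_formation_p, dtype=float),
                        (cmap.n_pairs,)).copy()
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("contact formation probabilities must lie in [0,1]")
    rng = np.random.default_rng(spec.seed)

    ca_idx: dict[int, int] = {}
    sc_idx: dict[int, list[int]] = {}
    for a in top.atoms:
        if a.segment != "protein":
            continue
        if a.name == "CA":
            ca_idx[a.residue_index] = a.index
        elif a.is_heavy and a.name not in ("N", "C", "O", "OXT"):
            sc_idx.setdefault(a.residue_index, []).append(a.index)
    involved = sorted({int(r) for pair in cmap.residue_pairs for r in pair})
    for r in involved:
        if r not in ca_idx:
            raise ValueError(f"residue {r} lacks a Calpha anchor")
        if len(sc_idx.get(r, [])) != 1:
            raise ValueError(
                "generate_ensemble supports Cbeta-level side chains only "
                f"(residue {r} has {len(sc_idx.get(r, []))} side-chain "
                "heavy atoms)")

    res_pos = {r: k for k, r in enumerate(involved)}
    sc_atoms = np.array([sc_idx[r][0] for r in involved])
    ca = np.array([nframe.coords[ca_idx[r]] for r in involved])
    bond = np.linalg.norm(nframe.coords[sc_atoms] - ca, axis=1)
    u_native = (nframe.coords[sc_atoms] - ca) / bond[:, None]
    atom_to_pos = {int(a): k for k, a in enumerate(sc_atoms)}
    pair_res = np.array([[atom_to_pos[int(i)], atom_to_pos[int(j)]]
                         for i, j in cmap.atom_pairs])
    cut = spec.contact_cutoff

    frames = []
    for _ in range(spec.n_frames):
        desired = rng.random(cmap.n_pairs) < p
        u = _solve_sidechain_directions(ca, bond, u_native, pair_res,
                                        desired, cut, rng)
        if u is None:
            raise RuntimeError(
                "could not realise a drawn contact pattern by side-chain "
                "re-orientation; the native contact network is too dense "
                "for independent per-contact modulation")
        coords = nframe.coords.copy()
        coords[sc_atoms] = ca + bond[:, None] * u
        frames.append(Frame(coords=coords, box=nframe.box.copy()))
    return Ensemble(topology=top, frames=frames)


def expected_q(spec: SynthEnsembleSpec) -> float:
    """Closed-form E[Q] of :func:`generate_ensemble`: the mean of the
    per-contact formation probabilities."""
    cmap = native_contacts(spec.native, cutoff=spec.contact_cutoff,
                           neighbour_exclusion=spec.neighbour_exclusion)
    p = np.broadcast_to(np.asarray(spec.contact_formation_p, dtype=float),
                        (cmap.n_pairs,))
    return float(np.mean(p))


# ---------------------------------------------------------------------------
# ΔΔG tables with exact correlation
# ---------------------------------------------------------------------------

def generate_ddg_table(spec: DDGSpec) -> DDGTable:
    """Mutant table whose sample Pearson r(ΔΔG_D-N, ΔΔG_TS-N) is exact.

    Built constructively: draw two Gaussian vectors, orthogonalise the second
    against the first (and the constant), then mix as
    y = r·x̂ + √(1−r²)·ê, which fixes the sample correlation at *r* up to
    floating-point rounding.
    """
    n, r = spec.n_mutants, spec.target_r
    if n < 3:
        raise ValueError("need at least 3 mutants")
    if not -1.0 <= r <= 1.0:
        raise ValueError("target correlation must lie in [-1, 1]")
    rng = np.random.default_rng(spec.seed)
    for _ in range(100):
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        xc = x - x.mean()
        nx = np.linalg.norm(xc)
        ec = e - e.mean()
        if nx < 1e-12:
            continue
        xhat = xc / nx
        ec = ec - (ec @ xhat) * xhat
        ne = np.linalg.norm(ec)
        if ne < 1e-12:
            continue
        ehat = ec / ne
        break
    else:  # pragma: no cover
        raise RuntimeError("degenerate random draws")
    yhat = r * xhat + math.sqrt(max(0.0, 1.0 - r * r)) * ehat
    amp = spec.scale * math.sqrt(n - 1)
    ddg_dn = 6.0 + amp * xhat
    ddg_tsn = 3.0 + 0.6 * amp * yhat
    return DDGTable(residue_ids=np.arange(1, n + 1),
                    ddg_dn=ddg_dn, ddg_tsn=ddg_tsn)
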