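"""Equilibrium sampler for rigid four-site water (TIP4P/2005).

A single-particle Metropolis Monte Carlo chain in the NVT ensemble: each move
translates and rotates one rigid molecule.  Interactions are Lennard-Jones on
the oxygens plus Coulomb among the three charged sites (H, H, M), truncated
molecule-wise at the oxygen–oxygen distance (default 0.9 nm) under the
minimum-image convention.  The box edge follows the experimental liquid
density at the requested temperature, where the rigid model's own equation of
state is accurate to ~0.1%.

This produces correctly Boltzmann-distributed configurations — the quantity
hydrogen-bond statistics depend on — without any dynamical information.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .io_core import TIP4P2005, Ensemble, Frame
from .synthetic_data import WaterBoxSpec, build_water_box

KB = 0.008314462618        # kJ/(mol·K)
_F = 138.935485            # Coulomb prefactor, kJ·nm/(mol·e²)
_SIG_OO = 0.31589          # nm
_EPS_OO = 0.77490          # kJ/mol
_Q = np.array([0.0, 0.5564, 0.5564, -1.1128])   # e, sites O,H1,H2,M

#: Liquid water density (g/cm³) at 1 bar vs temperature (K); linear
#: interpolation in between.
_DENSITY_TABLE = np.array([
    [270.0, 0.99977], [272.0, 0.99981], [277.0, 0.99997], [283.0, 0.99970],
    [293.0, 0.99821], [298.0, 0.99705], [303.0, 0.99565], [313.0, 0.99222],
    [323.0, 0.98804], [333.0, 0.98320], [343.0, 0.97776],
])


def water_density(temperature: float) -> float:
    """Experimental liquid density (g/cm³) at 1 bar, interpolated."""
    t = _DENSITY_TABLE[:, 0]
    if not t[0] <= temperature <= t[-1]:
        raise ValueError(f"temperature {temperature} K outside density table")
    return float(np.interp(temperature, t, _DENSITY_TABLE[:, 1]))


@njit(cache=False)
def _mol_energy(sites, box, rc2, i):
    """Interaction energy of molecule *i* with all others (kJ/mol)."""
    n = sites.shape[0]
    e = 0.0
    oxi = sites[i, 0, 0]
    oyi = sites[i, 0, 1]
    ozi = sites[i, 0, 2]
    for j in range(n):
        if j == i:
            continue
        dx = sites[j, 0, 0] - oxi
        dy = sites[j, 0, 1] - oyi
        dz = sites[j, 0, 2] - ozi
        sx = -box[0] * round(dx / box[0])
        sy = -box[1] * round(dy / box[1])
        sz = -box[2] * round(dz / box[2])
        dx += sx
        dy += sy
        dz += sz
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        sr2 = _SIG_OO * _SIG_OO / r2
        sr6 = sr2 * sr2 * sr2
        e += 4.0 * _EPS_OO * (sr6 * sr6 - sr6)
        for a in range(1, 4):
            ax = sites[i, a, 0]
            ay = sites[i, a, 1]
            az = sites[i, a, 2]
            qa = _Q[a]
            for b in range(1, 4):
                bx = sites[j, b, 0] + sx
                by = sites[j, b, 1] + sy
                bz = sites[j, b, 2] + sz
                rx = bx - ax
                ry = by - ay
                rz = bz - az
                r = math.sqrt(rx * rx + ry * ry + rz * rz)
                e += _F * qa * _Q[b] / r
    return e


@njit(cache=False)
def _run_mc(sites, box, beta, rc, n_sweeps, disp, rot, seed,
            sample_every, samples_out):
    np.random.seed(seed)
    n = sites.shape[0]
    rc2 = rc * rc
    n_acc = 0
    n_try = 0
    n_sampled = 0
    trial = np.empty((4, 3))
    for sweep in range(n_sweeps):
        for _ in range(n):
            i = np.random.randint(n)
            e_old = _mol_energy(sites, box, rc2, i)
            # rigid-body proposal: rotate about O, then translate
            ang = (np.random.random() - 0.5) * 2.0 * rot
            ux = np.random.normal()
            uy = np.random.normal()
            uz = np.random.normal()
            un = math.sqrt(ux * ux + uy * uy + uz * uz) + 1e-300
            ux /= un
            uy /= un
            uz /= un
            c = math.cos(ang)
            s = math.sin(ang)
            tx = (np.random.random() - 0.5) * 2.0 * disp
            ty = (np.random.random() - 0.5) * 2.0 * disp
            tz = (np.random.random() - 0.5) * 2.0 * disp
            ox = sites[i, 0, 0]
            oy = sites[i, 0, 1]
            oz = sites[i, 0, 2]
            for a in range(4):
                px = sites[i, a, 0] - ox
                py = sites[i, a, 1] - oy
                pz = sites[i, a, 2] - oz
                dot = ux * px + uy * py + uz * pz
                crx = uy * pz - uz * py
                cry = uz * px - ux * pz
                crz = ux * py - uy * px
                rxp = px * c + crx * s + ux * dot * (1.0 - c)
                ryp = py * c + cry * s + uy * dot * (1.0 - c)
                rzp = pz * c + crz * s + uz * dot * (1.0 - c)
                trial[a, 0] = ox + rxp + tx
                trial[a, 1] = oy + ryp + ty
                trial[a, 2] = oz + rzp + tz
            saved = sites[i].copy()
            sites[i] = trial
            e_new = _mol_energy(sites, box, rc2, i)
            n_try += 1
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < math.exp(-beta * de):
                n_acc += 1
            else:
                sites[i] = saved
        if sample_every > 0 and (sweep + 1) % sample_every == 0 \
                and n_sampled < samples_out.shape[0]:
            samples_out[n_sampled] = sites
            n_sampled += 1
    return n_acc / max(n_try, 1), n_sampled


def simulate_bulk_water(n_molecules: int = 360, temperature: float = 298.0,
                        seed: int = 0, n_equil_sweeps: int = 4000,
                        n_prod_sweeps: int = 4000, sample_every: int = 100,
                        density: float | None = None, cutoff: float = 0.9,
                        displacement: float = 0.012,
                        rotation: float = 0.25) -> Ensemble:
    """Sample equilibrium configurations of bulk four-site water.

    Starts from a jittered lattice with random orientations, equilibrates for
    *n_equil_sweeps* Monte Carlo sweeps (one attempted rigid-body move per
    molecule per sweep), then records a frame every *sample_every* production
    sweeps.  Returns an :class:`Ensemble` with uniform weights.
    """
    rho = density if density is not None else water_density(temperature)
    spec = WaterBoxSpec(n_molecules=n_molecules, density=rho, seed=seed,
                        model=TIP4P2005)
    top, frame = build_water_box(spec)
    box = frame.box
    rc = min(cutoff, 0.499 * float(box.min()))
    sites = frame.coords.reshape(n_molecules, 4, 3).copy()
    beta = 1.0 / (KB * temperature)

    dummy = np.empty((0, n_molecules, 4, 3))
    _run_mc(sites, box, beta, rc, n_equil_sweeps, displacement, rotation,
            seed & 0x7FFFFFFF, 0, dummy)
    n_samples = n_prod_sweeps // sample_every
    out = np.empty((n_samples, n_molecules, 4, 3))
    acc, n_got = _run_mc(sites, box, beta, rc, n_prod_sweeps, displacement,
                         rotation, (seed + 1) & 0x7FFFFFFF, sample_every, out)
    if n_got == 0:
        raise RuntimeError("no frames sampled; increase n_prod_sweeps")
    # frames keep raw (unwrapped) coordinates so molecules stay intact;
    # downstream analyses apply the minimum-image convention themselves
    frames = [Frame(coords=out[k].reshape(-1, 3), box=box.copy(),
                    time=float(k)) for k in range(n_got)]
    return Ensemble(topology=top, frames=frames)
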