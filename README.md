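# hydrophi

Analysis toolkit for studying the hydrophobic effect in protein folding
through the lens of water structure: hydrogen-bond accounting in the
hydration shell versus the bulk, water rotational anisotropy near a protein
surface, native-contact and Φ-value analysis, Φ-restrained transition-state
ensemble (TSE) sampling, secondary-structure populations, and a
protein/water nonbonded energy decomposition.

It is aimed at researchers analysing solvated-protein conformational
ensembles — cold/hot denatured states in particular — who need the
water-side bookkeeping (how many hydrogen bonds does an interface water
lose, how much rotational entropy does the first shell give up) next to the
protein-side folding coordinates (Q, Φ, Brønsted statistics).

## The quantities at the core

- **Hydrogen bonds per water molecule** — geometric criterion
  (donor–acceptor ≤ 0.35 nm, H–donor–acceptor ≤ 30°), counted donated plus
  accepted, split into water–water and water–protein contributions for
  *interface* waters (oxygen within 0.4 nm of a protein heavy atom) and
  *bulk* waters. In bulk liquid water this count decreases with
  temperature; at a protein surface the water–protein term makes up what
  the water–water term loses.
- **Rotational anisotropy** A(r) = ⟨3cos²ϑ(r) − 1⟩·RDF(r), ϑ the angle
  between a water's plane normal and its oxygen→protein-atom vector;
  ∫|A(r)|dr summarises the solvent's orientational ordering (rotational
  entropy loss) induced by the protein.
- **Q and Φ** — native contacts are heavy side-chain atom pairs within
  0.65 nm in the native structure (sequence separation ≥ 2); Q is the
  fraction formed in a conformation, Φᵢ the same restricted to residue i.
  Experimentally Φ = (ΔΔG_D-N − ΔΔG_TS-N)/ΔΔG_D-N, and the Brønsted plot
  (ΔΔG_TS-N against ΔΔG_D-N across mutants) is linear under
  nucleation–condensation and scattered under diffusion–collision.
- **TSE sampling** — simulated-annealing Monte Carlo on a Cα Gō model with
  a pseudo-energy k·Σᵢ(Φᵢ_sim − Φᵢ_exp)² driving the retained ensemble's
  Φ to experimental values.

Every input the pipeline needs can be generated synthetically (peptides
with prescribed dihedrals, rigid four-site water boxes, ensembles with
prescribed per-contact formation probabilities, ΔΔG tables with exactly
prescribed correlation), and bulk water is sampled by a built-in rigid-body
Monte Carlo chain — no external simulation engine is required.
See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
import hydrophi as hp

# equilibrium bulk water at two temperatures
for T in (272.0, 323.0):
    ens = hp.simulate_bulk_water(n_molecules=256, temperature=T, seed=1,
                                 n_equil_sweeps=4000, n_prod_sweeps=3000)
    rep = hp.hydration_report(ens)
    print(f"{T:.0f} K: {rep.hb_bulk:.2f} H-bonds per molecule")

# a Bronsted plot with a prescribed correlation
table = hp.generate_ddg_table(hp.DDGSpec(n_mutants=30, target_r=0.77, seed=1))
res = hp.bronsted(table)
print(f"Bronsted r = {res.pearson_r:.2f}, slope = {res.slope:.2f}")

# Phi-restrained TSE on a synthetic hairpin
from hydrophi.synthetic_data import build_hairpin
from hydrophi.tse_sampler import AnnealingSchedule, anneal, build_go_model
native = build_hairpin("KLVFFAEDVGSNKGAI", seed=0)
cmap = hp.native_contacts(native)
phi_exp = hp.phi_from_ensemble(
    hp.generate_ensemble(hp.SynthEnsembleSpec(native, 0.5, 150, seed=3)), cmap)
res = anneal(build_go_model(native, cmap), phi_exp, k=50.0,
             schedule=AnnealingSchedule(n_cycles=100, steps_per_cycle=1000),
             seed=4)
mask = phi_exp.valid & res.phi_sim.valid
print(f"retained {len(res.q_values)} structures, mean Q = "
      f"{res.q_values.mean():.2f}, Phi deviation = "
      f"{np.mean(np.abs(res.phi_sim.phi[mask] - phi_exp.phi[mask])):.3f}")
```

Output:

```
272 K: 3.72 H-bonds per molecule
323 K: 3.54 H-bonds per molecule
Bronsted r = 0.77, slope = 0.46
retained 300 structures, mean Q = 0.45, Phi deviation = 0.098
```

Colder water hydrogen-bonds more (3.72 vs 3.54 per molecule); the ΔΔG
generator hits its target correlation exactly; and the TSE sampler's
retained ensemble reproduces the reference Φ profile to ~0.1 while sitting
near the half-formed Q its targets imply.

The same stages are available from the shell:

```sh
hydrophi synth waterbox --n 216 --seed 7 --out box.gro
hydrophi hydration --traj box.gro --out report.json
hydrophi bronsted --ddg table.tsv
hydrophi tse --native native.pdb --phi phi.tsv --k 50 --out tse.pdb
```

Every run writes a `.manifest.json` with the parameters, seed and version
needed to reproduce it.

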