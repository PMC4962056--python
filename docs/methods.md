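# Methods

`hydrophi` re-implements, at desk scale, the ensemble analyses used to
characterise how water structure shapes protein cold and hot denaturation:
hydrogen-bond accounting split by hydration shell, water rotational
anisotropy, native-contact/Φ-value machinery, a Φ-restrained
transition-state-ensemble (TSE) sampler on a coarse-grained model, secondary
structure populations, and a nonbonded energy decomposition.  This note
records the models, the defaults and why they were chosen, and what the
synthetic data do and do not emulate.

## Containers and geometry

Structures are held as a `Topology` (atoms with element, residue, segment
and mass) plus `Frame`s (coordinates in nm, an orthorhombic box, time in
ps); an `Ensemble` adds per-frame weights that always normalise to one.
File I/O (PDB, GRO, XTC, DCD, multi-model PDB) goes through mdtraj; the
Å↔nm conversion lives entirely at that boundary.  Only orthorhombic boxes
are supported because every cutoff in the pipeline uses the plain
minimum-image convention; triclinic cells are rejected rather than silently
mishandled.  Internally atoms and residues are 0-based; report surfaces and
TSV files use 1-based residue numbering.

## Hydrogen bonds and hydration shells

A hydrogen bond is geometric: donor–acceptor (N/O/S) distance ≤ 0.35 nm and
hydrogen–donor–acceptor angle ≤ 30°.  This is a widespread MD-analysis
convention, not a universal constant, and both thresholds are arguments
everywhere.  Hydrogens are attached to the nearest heavy atom within
0.125 nm (water hydrogens to their own oxygen by construction), so no
bonded topology file is needed.  Donor–acceptor pairs inside one water
molecule or one protein residue are never reported.

Per-molecule counts are *donated plus accepted*: each geometric bond
increments both partners.  Under this convention bulk liquid water shows
≈3.5–3.8 bonds per molecule, the scale on which the temperature trend
(more bonds when colder) is usually quoted.  Shell splitting: a water is
*interface* when its oxygen is within 0.4 nm (configurable) of the nearest
protein heavy atom, otherwise *bulk*.  Shell averages are computed per
frame over the molecules in the shell, then weight-averaged across frames;
the identity `total_interface = ww_interface + wp_interface` holds exactly
on every input because the two categories partition each molecule's bonds.

## Water rotational anisotropy

For every (water oxygen, protein atom) pair at distance r the quantity
3cos²ϑ−1 is accumulated, where ϑ is the angle between the water-plane
normal (normalised cross product of the two O–H vectors) and the O→atom
vector.  The profile is A(r) = ⟨3cos²ϑ−1⟩·RDF(r), with RDF the raw
(unnormalised) pair-distance histogram, and the scalar summary is
∫|A(r)|dr by the rectangle rule on the histogram's own bins (default
width 0.01 nm out to 1.5 nm).  A vanishes for isotropically oriented
water; per pair the orientation factor is bounded in [−1, 2], so
|A(r)| ≤ 2·RDF(r).  All protein atoms (not only heavy ones) enter the
pair loop, matching the all-atom definition of the distance histogram;
the shell classification above deliberately differs (heavy atoms only)
because hydrogens inflate a surface definition.

## Equilibrium bulk water

No molecular-dynamics engine is part of the package; bulk water is sampled
with a rigid-body Metropolis Monte Carlo chain (`watermc`).  Each move
translates (±0.012 nm per axis) and rotates (±0.25 rad) one four-site
molecule; interactions are Lennard-Jones on oxygen (σ = 0.31589 nm,
ε = 0.7749 kJ/mol) plus Coulomb on the two hydrogens and the M site
(q_H = +0.5564 e), truncated molecule-wise at 0.9 nm oxygen–oxygen
distance.  Sampling is NVT with the box edge set from the experimental
liquid density at the requested temperature, where this water model's
equation of state is accurate to ~0.1%; hydrogen-bond counts are
insensitive to density errors of that size.  Starting from a jittered
lattice with random orientations, ~4000 sweeps suffice to converge the
hydrogen-bond count; production frames are taken every 100 sweeps.
A correctly weighted equilibrium ensemble is all the hydrogen-bond
statistics require — the chain carries no dynamical information, and the
simple truncation slightly perturbs long-range structure but not the
short-range (<0.35 nm) geometry that defines a hydrogen bond.
The benchmark runs use 714 molecules (the acceptance script) or 256
(the test suite); both sizes give shell-free bulk boxes whose counts
agree within the sampling noise of a few hundredths of a bond.

## Native contacts, Q and Φ

Native contacts are heavy side-chain atom pairs (Cβ included, glycine
contributes none) between residues at sequence separation ≥ 2, within
0.65 nm in the native frame.  Q of a conformation is the fraction of those
atom pairs within the formation cutoff, which defaults to the same
0.65 nm — a hard-cutoff Q, with no smoothing and no tolerance inflation;
both cutoffs are arguments.  Φ of residue i is the same fraction
restricted to pairs involving i, weight-averaged over the ensemble;
residues with no native contacts are flagged invalid rather than given a
number.  The residue-pair contact-formation matrix marginalises exactly
onto Φ, which the tests assert.

Experimental Φ = (ΔΔG_D-N − ΔΔG_TS-N)/ΔΔG_D-N per mutant, with mutants
below 2.5 kJ/mol (≈0.6 kcal/mol, the usual reliability floor) of
equilibrium destabilisation flagged invalid, multi-mutant residues
averaged with a warning, and only Φ in [0, 1] ever used as restraints.
Brønsted statistics are the Pearson correlation and least-squares line of
ΔΔG_TS-N against ΔΔG_D-N (scipy.stats.linregress).

## Φ-restrained TSE sampling on a Gō model

The TSE protocol is re-realised on a one-bead-per-residue native-centric
model: harmonic bonds at native virtual Cα–Cα lengths (k = 8000
kJ·mol⁻¹·nm⁻²), harmonic angles (40 kJ·mol⁻¹·rad⁻²) and cosine dihedrals
(2 kJ/mol) centred on native values, a 12-10 well per native residue pair
with depth ε·(atom-pair count) and minimum at the native bead distance,
and r⁻¹² repulsion (σ = 0.4 nm) for non-native pairs.  ε = 10 kJ/mol per
atom-pair contact puts the toy hairpin's folding midpoint slightly above
272 K: natively folded at low temperature, disordered at the 500 K
annealing ceiling.  A bead-level contact counts as formed within 1.2× its
native distance, the usual coarse-grained convention.

Annealing cycles ramp the temperature t_low → 500 K → t_low (40% up, 40%
down, 20% plateau); structures are retained only from the plateau.  "Cycle
length" is measured in MC sweeps (default 5000) because MC has no physical
clock — cycle count and retained-ensemble size are the quantities honoured.
Moves are single-bead displacements (70%) and crankshaft rotations about
the (i−1, i+1) axis (30%), with amplitudes giving ≈40–50% acceptance at
the reference temperature.

The restraint adds k·Σᵢ(Φᵢ_sim − Φᵢ_exp)² (default k = 50 kJ/mol) over
residues with valid experimental Φ in [0, 1].  Two modes exist.  The
*structure* mode restrains each conformation's own Φ.  On a coarse-grained
toy this mode cannot represent fractional targets: a residue with a single
bead-level contact has per-structure Φ ∈ {0, 1}, the quadratic penalty is
then symmetric between the two states, and the retained average drifts to
the Gō equilibrium instead of the target (measured deviation ≈0.18 at
target 0.5).  The default *ensemble* mode therefore restrains a running
time-average of Φ over the reference-temperature sampling (exponential
memory, default 1000 sweeps), in the replica/time-averaged-restraint
tradition: the retained ensemble's mean Φ is driven to the target while
individual structures remain free, and fractional Φ are recovered to a
mean absolute deviation ≤0.05 on the 16-residue toy.  With all-atom
contact counts (tens of atom pairs per residue) the two modes coincide in
practice; the structure mode remains available as an option.

## Secondary structure and compactness

Classification is per residue from (φ, ψ) alone, by rectangular boxes:
α φ∈[−100,−30], ψ∈[−80,−5]; β φ∈[−180,−90], ψ∈[90,180]∪[−180,−170];
PPII φ∈(−90,−20], ψ∈[120,180]; everything else (and chain termini) coil.
One dihedral-only scheme is used for all three classes because
polyproline II has no hydrogen-bond signature; the boxes are standard
Ramachandran conventions and are configurable, so populations should be
read as definition-dependent quantities.  The β/PPII boundary at φ = −90°
is half-open to keep the boxes disjoint.  Radius of gyration is
mass-weighted over protein atoms, computed on the coordinates as given
(the protein is assumed whole, not wrapped).

## Energy decomposition

Lennard-Jones 12-6 with Lorentz–Berthelot combination plus Coulomb
f·q_iq_j/r (f = 138.935485 kJ·nm·mol⁻¹·e⁻²), both plainly truncated at
0.9 nm at the minimum-image site–site distance.  There is no Ewald
summation: absolute electrostatic values differ from mesh-based schemes,
and only the decomposition contract is claimed — every in-range,
non-excluded pair lands in exactly one of pp/pw/ww (ions file under their
partner's water-side category), so the six terms sum to the total pairwise
energy to 10⁻⁸ kJ/mol.  Exclusions are intra-water-molecule and
intra-protein-residue pairs.  A small packaged (segment, element) parameter
table covers the synthetic systems; force-field import is out of scope.

## Synthetic data: what it emulates, what it does not

`build_peptide` constructs backbone + amide-H + Cβ chains by
internal-coordinate (NeRF) building; backbone dihedrals hit their targets
to machine precision, verified against mdtraj's dihedral computation.
`build_water_box` places exact rigid-model molecules on a jittered lattice
with orientations uniform on SO(3) (random unit quaternions) — valid
geometry and an exactly isotropic null case for the anisotropy statistic,
but *not* liquid structure; equilibrated water comes from `watermc`.
`solvate` centres the protein and deletes waters whose oxygen is within
0.24 nm of a protein heavy atom.

`generate_ensemble` draws each native contact's formed/broken state as an
independent Bernoulli variable per frame and realises the pattern by
re-orienting Cβ atoms about their Cα (bond lengths exactly preserved),
using projected gradient descent on the sphere with a randomised fallback
search.  This supports Cβ-level side chains only, and not every native is
usable: a pattern is realisable only if every contact's Cα–Cα distance
leaves the Cβ–Cβ distance room on both sides of the cutoff.  Ideal-helix
(i, i+3) networks are geometrically unable to break all contacts at once;
the packaged `build_hairpin` fixtures (lengths 14 and 16, with tuned turn
dihedrals) were verified to realise every one of the 2^n patterns.
Because the drawn states are exact Bernoulli samples, E[Q] equals the mean
contact probability and per-contact frequencies obey binomial statistics —
the closed forms the recovery tests check.

`generate_ddg_table` fixes the sample Pearson correlation *exactly*
(orthogonalise-then-mix construction), so Brønsted recovery can be
asserted to 10⁻¹⁰ rather than statistically.  Scales: ΔΔG_D-N centred on
6 kJ/mol with 2.5 kJ/mol spread, ΔΔG_TS-N on 3 kJ/mol — typical magnitudes
for single-point mutations.

None of the generators model solvent-mediated cooperativity, rotamer
libraries, or physically equilibrated water; tests passing on them show
the *analysis* code is correct and self-consistent, not that any
particular protein behaves this way.

## Problem sizes and numerical choices

The packaged benchmarks run on one CPU core: bulk-water boxes of 256–714
molecules with 4000–4500 equilibration and 3000–3500 production sweeps;
TSE runs of 60–100 cycles × 800–1000 sweeps on 14–16-residue toys.
Histogram bins are half-open with the top edge clamped into the last bin;
empty anisotropy bins contribute A = 0; weights renormalise on
construction so frame duplication never changes any reported average.
Degenerate inputs fail loudly: collinear O–H vectors, hydrogen-free
topologies, empty contact maps, zero-variance ΔΔG columns and r = 0 atom
pairs all raise with specific messages.

## Known limitations

- Hydrogen-bond counts depend on the chosen geometric criterion; values
  quoted above assume the 0.35 nm / 30° default.
- The coarse-grained TSE sampler reproduces Φ statistics, not all-atom
  structural detail; its temperature scale is nominal (Boltzmann weights
  against kJ/mol energies), not calibrated to a real folding transition.
- Plain-cutoff electrostatics make absolute energies scheme-dependent.
- `generate_ensemble` is restricted to Cβ-level side chains and raises on
  natives whose contact geometry cannot be modulated independently.
- Water sampling is NVT at tabulated experimental densities (270–343 K);
  no pressure coupling is implemented.
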