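# Methods

`resmap` maps the residues that contribute substantially to a protein–protein
interface by combining continuum electrostatics, buried-surface estimates,
threshold classification with replicate consensus, and structural-family
analysis. This note records the model, the numerical choices, and what the
synthetic test systems do and do not establish.

## Rigid-body binding model

Binding is treated rigidly: monomer coordinates are taken unchanged from the
complex, with no conformational relaxation between bound and unbound states.
All energies are therefore *interaction* energies of the crystallographic
(or generated) pose. Structures are read from PDB text, alternate locations
resolved to the highest-occupancy conformer, waters and (by default)
non-protein heteroatoms removed.

Protonation is minimal by design: only backbone amide hydrogens are placed,
1.0 Å from N along the external bisector of the C(prev)–N–CA angle (in the
peptide plane, anti to the preceding carbonyl). Pre-protonated files pass
through unchanged. Full force-field protonation and energy minimization are
out of scope; this shifts absolute energies somewhat, but the pipeline's
currency is the threshold classification of *differences*, which is far less
sensitive.

Charges and radii come from a bundled PARSE-style table (united polar
hydrogens; element radii C 1.70, N 1.50, O 1.40, S 1.85, H 1.00 Å; backbone
dipole N −0.40/H +0.40 and C +0.55/O −0.55 e; full ±1 e on Asp/Glu
carboxylates and Lys/Arg basic groups; Asn/Gln/His side-chain dipoles on
heavy atoms). Termini are neutral (N-terminal N and OXT uncharged) so every
residue's net charge is its nominal integer value. The table is a
configuration hook (`parameter_table_path`) for users who prefer another
PB-oriented set.

## Electrostatics: finite-difference linearized Poisson–Boltzmann

The linearized PB equation is discretized on a regular lattice with the
standard 7-point stencil; dielectric values live on the lattice edges, the
Debye term on nodes. Each edge is sampled at 5 points against the
(radius + `surface_probe`) atom spheres and assigned the harmonic mean of
protein and solvent dielectrics weighted by the inside fraction — the
harmonic mean is the exact series composition in 1-D and reduces the
staircase discretization error by roughly an order of magnitude compared
with a midpoint rule (Born-ion error 0.7% vs 4.6% at the default grids).
Ions are excluded from nodes within radius + Stern layer.

Environment defaults (all configurable): ε_protein = 2, ε_solvent = 80,
ionic strength 0.145 M (1:1 salt, linearized), Stern layer 2.0 Å,
T = 298.15 K, van der Waals dielectric surface (`surface_probe = 0`).
κ² is derived from first principles; the Debye length evaluates to 3.07 Å at
1 M, 298.15 K, ε = 80.

**Focusing.** Two grid levels: a coarse grid (1.0 Å spacing, molecule
filling ~40% of the box) with Debye–Hückel boundary potentials superposed
from the atomic charges, then a focused grid (0.5 Å spacing, molecule plus a
4 Å margin) whose boundary is interpolated from the coarse solution. Charges
spread to nodes trilinearly; potentials are read back at atom positions with
the same trilinear weights, so the singular grid self-energy is identical
across runs that share grid geometry and charge positions, and cancels in
differences.

**Solvers.** The discrete operator is symmetric positive definite. The
default solver is Jacobi-preconditioned conjugate gradients run *blockwise*:
all right-hand sides that share a dielectric geometry (the full charge set
plus every residue-deletion charge set) are iterated together, and the fine
level warm-starts from the interpolated coarse solution. A red–black SOR
backend (`backend="sor"`, over-relaxation factor from the Jacobi spectral
radius estimate, max-node-update convergence test) is provided and verified
against CG; it is the classical FDPB iteration but is much slower for the
many-right-hand-side scans this package performs. Non-convergence raises.

**Binding energy and per-residue decomposition.** For a replicate with sides
A and B,

    ΔG_elec_bind = G(complex) − G(A) − G(B),   G = ½ Σ q φ,

with all three terms solved on identical grids. A residue's net
electrostatic contribution is a charge-deletion difference with the
dielectric cavity left unchanged (the hypothetical uncharged residue):

    ΔΔG_elec(r) = ΔG_elec_bind(charges of r deleted) − ΔG_elec_bind(full),

so residues whose charges favor binding score positive. Whole-residue and
side-chain-only deletions are solved independently; the main-chain value is
their difference by construction (never solved separately). Because the
operator is linear, each deletion needs only two extra solves (the deleted
charge set in the complex geometry and in its host monomer geometry); the
implementation evaluates

    ΔΔG(r) = −½ d·(u_dC − u_dH) − (q_cx − d)·u_dC + (q_host − d)·u_dH

where d is the deleted charge vector and u_dC, u_dH its potentials in the
complex and host-monomer geometries. Records are computed for every residue
with a heavy atom within 15 Å (inclusive) of a partner heavy atom — the
interface shell.

The declared numerical error scale is 0.5 kcal/mol; shifting the grid by
half a spacing relative to the molecule moves per-residue values by less
than this (measured ~0.4 kcal/mol worst case on the synthetic dimer), which
is why the substantiality threshold sits at twice that scale.

## Non-polar term

Solvent-accessible surface area uses the Shrake–Rupley construction on a
deterministic Fibonacci sphere lattice (default 960 points, probe 1.4 Å,
hydrogens excluded — united-surface convention). A residue's non-polar
contribution is

    ΔΔG_np = (SASA in its isolated monomer − SASA in the complex) × γ,

γ = 0.05 kcal/mol/Å², so the 0.5 kcal/mol substantiality threshold equals
10 Å² of buried area. Small negative burials (< 0.1 Å², lattice noise) are
clipped to zero; larger negatives are reported with a warning. Doubling the
lattice density moves per-residue areas by < 2%.

## Classification and consensus

Three flags per residue, inclusive thresholds: side-chain electrostatics
ΔΔG_sc ≥ 1.0 kcal/mol, main-chain ΔΔG_mc ≥ 1.0 kcal/mol, non-polar
ΔΔG_np ≥ 0.5 kcal/mol. The flag triple maps bijectively onto seven
contributing categories (np; sc_elec; mc_elec; sc+mc_elec; sc_elec+np;
mc_elec+np; sc+mc_elec+np) plus `none`, with the conventional viewer palette
(green, red, yellow, orange, magenta, cyan, purple).

Consensus across biological replicates (copies of the complex in an
asymmetric unit, or independent crystal structures) is flag-wise majority
voting: a flag is retained when supported in ≥ 50% (configurable) of the
replicates in which the position is resolved; unresolved positions leave the
denominator. Flag-wise voting is the weakest operator that still yields a
single consensus category; per-category voting and error-bar overlap are
plausible alternatives, and the fraction is exposed for that reason.

## Families and dissimilar motifs

Residue correspondence between chains comes from global sequence alignment
(BLOSUM62, gap open −10, extend −0.5); superposition is least-squares
(Kabsch) on corresponding Cα with up to 5 rounds of outlier trimming (drop
pairs beyond 2× the current RMSD). Families are single-linkage components
under RMSD ≤ 1.5 Å and coverage ≥ 0.9 (defaults). This replaces
combinatorial-extension style structural alignment, which is unnecessary at
the sequence identities where family analysis is meaningful (≳50%).

For a family, every member is superposed onto a reference in an
*iterated-core* frame: the fit starts from all commonly aligned positions
and is restricted, iteratively, to positions whose max pairwise Cα deviation
is ≤ 1.5 Å — so a genuinely dissimilar motif cannot bias the frame that
detects it. The deviation profile is the per-position maximum pairwise Cα
distance; a position is flagged when at least `min_pairs` member pairs
(default 1, i.e. two structures) exceed the threshold (default 1.5 Å,
strict), and motif regions are maximal contiguous flagged runs. Whether the
published deviations were measured family-wide or pairwise is not stated in
the sources this design follows; the iterated-core frame is this package's
documented choice.

Cross-interface attribution (which side-A contributors engage which named
side-B region) uses the nearest contributing side-B residue by minimum
heavy-atom distance, flagged long-range above 5 Å. Region spans are
user-supplied in reference numbering (optionally seeded from detected
motifs); secondary structure is not computed.

## Synthetic study systems

The generators produce every fixture the pipeline needs, so the whole
pipeline is testable without downloads:

* **Point-charge systems** — bare charged spheres for the analytic oracles
  (Coulomb pair, Born ion, Debye screening).
* **Helix dimers** — two ideal poly-Ala α-helices (rise 1.5 Å, twist 100°,
  Cα radius 2.3 Å), antiparallel at 14 Å axis separation, 10 residues per
  chain (kept small so a full FDPB scan of every interface residue stays a
  desk-scale computation). Planted features: salt bridges (facing positions
  mutated to Lys/Asp pseudo side chains, charged groups ~2.9 Å apart across
  the interface) and burial-only contributors (facing Leu pseudo side chains
  in mutual van der Waals contact). A seeded 0.05 Å jitter makes distinct
  seeds distinct structures. The planted geometry is part of the generator's
  contract: it is built so salt bridges clear the 1 kcal/mol side-chain
  threshold (measured ~2.2–2.3 kcal/mol, comfortable margin over replicate
  noise) and burial pairs clear 10 Å² (~30–35 Å²), while unplanted poly-Ala
  positions stay below every threshold.
* **Replicates** — i.i.d. Gaussian heavy-atom noise (default σ = 0.2 Å),
  amide hydrogens re-placed, seeds derived deterministically.
* **Motif families** — copies of a 45-residue helix with residues 20–30
  displaced (default 3 Å, smooth ramp: full displacement mid-span, 0.7× at
  the edges, zero outside) in 2 of 5 members along a shared direction
  (optionally spread directions).

What the synthetic systems do **not** emulate: real packing density and
shape complementarity, polar/charged residue crowding, buried waters,
conformational strain, crystallographic disorder. Passing the recovery tests
therefore demonstrates that the machinery (energies → thresholds →
consensus → maps) is correct and well-conditioned, not that the defaults
reproduce any particular experimental system; for real complexes the unstated
upstream choices (protonation, charge set, dielectric constants) dominate
the residual uncertainty, and published per-residue values can be expected
to be reproduced only approximately.

## Numerical details and degenerate inputs

* CG tolerance 1e-6 (relative residual; SOR: max node update in kcal/mol/e),
  max 10,000 iterations; both deterministic.
* Charges within one grid spacing of a boundary, atoms outside the grid, or
  non-convergence raise errors rather than degrade silently.
* Residues with no charges in the deleted set give exact zeros (no solve).
* An empty interface shell (separated chains) produces an empty map cleanly.
* Alternate-location ties resolve to the first conformer listed; missing
  backbone atoms skip hydrogen placement with a warning; unknown atoms are
  an error in strict mode, zero-charge/default-radius with a warning
  otherwise.
* Reports are byte-stable for equal configurations.

## Known limitations

Linearized PB only (no nonlinear term, membranes, or explicit ions); rigid
binding (no relaxation or rotamer repacking); vdW dielectric surface rather
than a molecular (reentrant) surface; minimal protonation model; no
statistical test on contributor calls; sequence-guided superposition assumes
alignable sequences and will not recover remote structural homology.
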