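# Methods

This note documents the models behind `permeakit`: what each component
computes, the assumptions and unit conventions it relies on, the defaults
and why they were chosen, and what the synthetic systems do and do not
capture about real membrane-channel simulations.

## Problem setting

The package models a positively charged antibiotic-like ligand passing
through the pore of a pentameric mechanosensitive channel (MscL-like),
driven by an external electric field (EEF) applied to the ligand only, and
provides the downstream statistics used to characterize such a passage:
the ΔZ permeation coordinate, crossing and stage analysis, ion
displacement, lipid contact numbers, two-selection RMSDs, axis-angle helix
rotations, pore-radius profiles, and implicit-membrane MM-PB energies.
The dynamics engine is deliberately coarse-grained — it generates
permeation trajectories with controllable ground truth for exercising the
analysis operators, not all-atom kinetics.

## Units and coordinate conventions

All quantities use one unit system: Å, ps, kcal/mol, elementary charge e,
Kelvin, amu.  Conversion constants (in `permeakit.constants`):

| constant | value | meaning |
|---|---|---|
| Coulomb constant | 332.0636 kcal·Å/(mol·e²) | electrostatic prefactor |
| EEF conversion | 23.0609 kcal/(mol·Å) per e·(V/Å) | field→force |
| k_B | 0.0019872041 kcal/(mol·K) | Boltzmann constant |
| acceleration | 418.4 Å/ps² per (kcal/mol/Å)/amu | force→acceleration |

Axes are right-handed Cartesian; the membrane normal is +Z and the
periplasmic side is +Z, so a cation entering from the periplasm and
exiting to the cytoplasm moves toward −Z.  This orientation is a package
convention chosen so that the ΔZ sign rule and "clockwise as seen from the
periplasm" are well-defined, testable statements.  Residue numbers follow
the concatenated pentamer convention: residue *r* of monomer *m* is stored
as *r* + 136·*m* (configurable offset), so the cytoplasmic lysine ring
residue 106 appears as 106/242/378/514/650.  The selection key `resnum`
matches monomer-local numbers, which is what makes `"resnum 106 and name
CA"` mean "one ring Cα per monomer".

## Synthetic system

`synthetic_system` builds the study system at desk scale:

* **Channel** — ideal α-helices (1.5 Å rise, 100° twist per residue, 2.3 Å
  Cα helix radius), two pseudo-atoms per residue (Cα, radius 1.9 Å, and a
  side-chain bead, radius 2.0 Å), four helices per monomer (S1, pore-lining
  TM1, lipid-facing TM2 whose cytoplasmic end carries the K106 lysine
  ring, and a C-terminal bundle helix), linkers interpolated between helix
  ends, replicated with exact n-fold symmetry about Z.  The side-chain
  beads of the constriction residue (the TM1 residue nearest the
  constriction z, −13 Å by default) are pinned at exactly
  `pore_constriction_radius + bead radius` from the axis, so the minimum
  pore radius equals the requested value; the builder verifies by an
  independent axial scan that no other atom intrudes.  The open-pore
  radius during passage is not a measured quantity, so it is a free
  parameter; the default of 6 Å admits the 10 Å ligand with clearance,
  while 1 Å gives a sterically closed control.
* **Ligand** — a rigid, symmetric bead cluster (3 beads of radius 2 Å by
  default) whose extent (max pairwise distance + 2 bead radii) equals the
  nominal 10 Å diameter and whose +3 e charge is split uniformly.  No
  internal torsions: the analyses only need a labeled charged body.
* **Ion bath** — 95 K⁺ and 95 Cl⁻ by default, placed by seeded rejection
  sampling with a 3 Å minimum separation, excluded from a cylinder around
  the pore axis (the permeation path, which the explicit-solvent system
  keeps water-filled).  The ligand's +3 is deliberately not neutralized;
  the net system charge is reported in the build log.
* **Membrane** — a slab recorded as z-bounds (±9 Å by default, 18 Å thick)
  plus deterministic "headgroup" marker rings on both faces (used by the
  membrane-thickness estimator and as mctrdz markers), and optional
  three-residue lipid surrogates (polar PC at the face, hydrophobic PA and
  OL reaching inward, two beads each) for the contact statistics.

What the generator does **not** emulate: explicit water, realistic lipids,
side-chain chemistry, protein flexibility (the scaffold is static during
the demo dynamics), and channel gating energetics.  Tests passing on these
systems therefore validate the *operators* — their definitions, unit
conversions, invariances, and numerical accuracy — not any biological
claim about a real channel.

## Dynamics engine

`toy_dynamics` integrates Langevin dynamics with the BAOAB splitting at a
0.01 ps default timestep (appropriate for beads of ~50–200 amu; an
all-atom 1–2 fs timestep has no meaning at this granularity).  The
friction (collision frequency) default is 5 ps⁻¹ and snapshots default to
every 4 ps.  Force terms:

* **EEF**: `f_i = c_i · E` componentwise for atoms in the mask, converted
  at 23.0609 kcal/(mol·Å) per e·(V/Å); exactly zero outside the mask.  In
  the permeation protocol the field acts on the ligand only, pointing
  along −Z.
* **Coulomb**: plain 1/r, no cutoff (systems are tiny; Ewald summation is
  out of scope).  An optional uniform relative dielectric screens the
  term; the default is 1 (bare charges).  The demo protocol sets it to 80:
  with no explicit water, a bare-charge ion bath would impose
  electrostatic barriers of hundreds of kcal/mol on the permeation path
  that a solvated system does not have, and a uniform solvent dielectric
  is the standard implicit-solvent remedy.
* **WCA repulsion**: purely repulsive Lennard-Jones truncated and shifted
  at its minimum, with σ_ij = r_i + r_j and ε = 0.2 kcal/mol.  Pairs
  within one residue or within two residues along a chain are excluded
  (the coarse analog of 1-2/1-3 exclusions).
* **Positional restraints**: `E = k·d²` per atom — the convention without
  the ½ factor, matching the engine family in which restraint constants
  like 20/15/10/5/2/1 kcal/mol/Å² are quoted; the equipartition variance
  of a restrained coordinate is accordingly k_BT/(2k).

Scaffold atoms are static by default (the analog of a strongly restrained
secondary structure); the ligand is kept rigid by constraint projection —
after each position update its bead cloud is snapped back onto the
reference internal geometry by a least-squares fit, and velocities are
projected onto the rigid-body subspace.  Pairwise distances are conserved
to machine precision.  The integrator aborts when the mobile subsystem's
energy drifts beyond a threshold (1e8 kcal/mol) from its starting value.

Closed-form checks used in the tests: at T = 0 a constant force F on a
free bead reaches terminal drift F/(mγ); at T > 0 a bead restrained with
`E = k·d²` has positional variance k_BT/(2k) per coordinate; trajectories
are bitwise reproducible per seed on one platform.

The permeation protocol runs one trajectory per (field, seed) pair and
tabulates first downward-passage times.  Run lengths are set per field to
a small multiple of the expected drift time (200/100/60 ps at 0.05/0.1/0.2
V/Å in the shipped studies), which keeps the full 30-run field-response
study around a few minutes on one core.

## Permeation statistics

* **ΔZ** — Z difference between the geometric centers (unweighted means;
  the reference quantity is "geometrical", not mass-weighted) of the
  ligand and of the five ring lysines.  ΔZ ≥ 0 on/above the ring plane.
  Which lysine atoms define the plane is configurable; ring Cα is the
  default.  ΔZ is invariant under rigid translations of a frame and flips
  sign under z-mirroring.
* **Crossings** — two-threshold hysteresis: a downward passage is recorded
  when the series, having most recently been ≥ z_upper, first reaches
  ≤ z_lower; t_start is the last sample in the origin zone and t_end the
  first in the destination zone.  Defaults z_upper = +10 Å, z_lower = −5 Å
  (no published thresholds exist; excursions in permeation traces go far
  beyond these, so the events are insensitive to the exact values).
* **Stages** — frames are labeled by explicit ΔZ bands (band edges are
  always user configuration, never inferred: the underlying criterion in
  the literature — residence time plus energies — is qualitative); runs
  shorter than `min_dwell` are merged into the longer neighbor (ties to
  the earlier one), shortest-run first, which is deterministic.  Stages
  are half-open intervals whose union is the analyzed window.
* **Ion displacement** — per-ion ΔZ, endpoint difference by default, with
  a time-averaged mode as an option (the phrase "average shift during the
  simulation" admits both readings; the mode is logged).  Negative values
  mean motion toward −Z, the cytoplasmic exit side.
* **Contact numbers** — hydrophobic lipid residues (PA/OL flags) whose
  geometric center lies within an inclusive threshold (6.5 Å default) of a
  target residue's geometric center, per frame, with per-target averages.
  Counts are exact integers, monotone in the threshold.

## Structure geometry

* **Kabsch superposition** — weighted SVD solution with the reflection
  branch corrected to det = +1; degenerate (collinear) inputs error.
* **Two-selection RMSD** — fit on one selection (all Cα typically),
  measure another without re-fitting; this isolates internal domain motion
  from global rigid motion.
* **Axis-angle** — angle from the trace in [0°, 180°]; axis from the
  antisymmetric part away from the branch points and from the symmetrized
  matrix (cosθ·I + (1−cosθ)·nnᵀ) near 180°, which is exact up to rounding.
  The reported axis is canonicalized (largest-magnitude component
  positive); since that erases handedness, `helix_rotation` reports
  handedness separately from the raw antisymmetric part: the sign of
  sinθ·n_z, negative meaning clockwise as seen from the periplasm (+Z).
  Helix rotations are per-helix direct fits of the reference helix onto
  the conformation (no global pre-alignment; a global-prefit variant is
  provided), uniform weights on Cα.
* **Pore profile** — at each z, the largest clearance
  min_i(‖c − x_i‖ − r_i) over probe centers c confined to the slice plane.
  The maximization is local Nelder-Mead ascent from two deterministic
  seeds, the axis and the previous slice's center, so the probe follows
  the channel instead of escaping into the bulk through wall gaps; this is
  the channel-following behavior of pore-profiling tools, with the probe
  center constrained to the plane (a deliberate, documented divergence
  from tools that let it wobble in 3D — adequate for near-axial pores and
  fully deterministic).  Radii are capped at r_max and capped slices
  flagged.  Bottlenecks are strict local minima of the sampled profile,
  leftmost sample of a flat minimum.
* **Membrane thickness** — mean z of upper face markers minus mean z of
  lower face markers.

## Implicit-membrane Poisson energies

`electrostatics_pb` solves the linearized, zero-ionic-strength (pure
Poisson) problem on a regular grid: 7-point finite-difference stencil,
edge dielectrics by harmonic mean of adjacent nodes, Dirichlet boundary
from an analytic Coulomb sum screened by the local boundary dielectric,
and diagonally preconditioned conjugate gradients to a 1e−8 relative
residual.  The dielectric map is three-valued: ε = 1 inside any solute
sphere (the interior default of the engine family this emulates; the
named external constants are 80 for water and 4 for the membrane slab),
ε = 4 inside the 18 Å slab, ε = 80 elsewhere.  Because the solute's
geometric center need not coincide with the membrane midplane, a
per-conformation z offset (the mctrdz convention: membrane-marker center
minus solute center) shifts the slab.

The polar solvation energy uses the standard two-solve reaction-field
definition E_PB = ½ Σ q_i (φ_env − φ_ref), with φ_ref from a uniform-ε_in
solve on the identical grid, so the grid self-energy cancels.  Grid
defaults are 0.5 Å spacing with a 10 Å buffer; the Born benchmark (q = 1 e,
R = 2 Å in water) is within ~1.7% of the closed form at 0.25 Å spacing and
the error falls by ~2.5× per halving of the spacing.  The MM-PB total is
E_MM + E_PB with no nonpolar/surface-area term (deliberately excluded).

Known limitations: abrupt (unsmoothed) dielectric boundaries make
absolute energies grid-sensitive at coarse spacings; salt (a linearized
Debye term) is not enabled by default; energies of the coarse-grained demo
system are internally consistent but not comparable to all-atom values.

## Pipeline and reproducibility

The `permeakit` CLI chains build → simulate → analyze; a single YAML
config with per-stage sections drives every stage, is schema-validated
before any computation, and every run writes a manifest (config hash,
seed, package version, artifact list, status — including a FAILED marker
on error, with partial artifacts retained).  All randomness funnels
through per-stage generators seeded from one global seed; identical
config+seed reproduce every artifact byte for byte on one platform.  The
demo runs the open channel at 0.2 V/Å for 40 ps, long enough for one full
passage, and computes the MM-PB series on three subsampled frames at 2 Å
grid spacing (a coarse setting chosen for the demo's scale; analyses of
record should refine the grid).

## Scope limits

Homology modeling, docking, all-atom force fields and their derivation,
explicit-solvent electrostatics (PME), constraint algorithms beyond the
rigid ligand, nonlinear or salt-dependent PB, and any reproduction of
published trajectory-specific numbers (stage durations, rotation angles,
contact averages, bottleneck positions) are out of scope: those require
the original all-atom trajectories, which are not available.  The package
reproduces the *machinery* and validates it against closed forms and
brute-force oracles.
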