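# Methods

`abtwist` analyses conformational interconversion in a double-layer
amyloid-β(20–34) β-sheet: how a torsion about a single backbone bond
detaches the N-terminal part of the upper strand (a *twisted*
conformation), which hydrogen bonds that breaks, and what barrier
separates the twisted state from the flat, fully stacked one.  This note
records the model, the geometry the synthetic builder emulates, the
numerical choices, and what the package's results do and do not say
about the real system.

## The system and its synthetic stand-in

The object of study is two copies of the Aβ fragment spanning positions
20–34 (sequence FAEDVGSNKGAIIGL) stacked as a parallel in-register
β-sheet.  The builder (`synthetic` module) creates this from first
principles rather than from crystal coordinates:

* Each monomer is an ideal extended strand.  Heavy-atom geometry comes
  from RDKit (sequence → 3-D embedding with standard bond lengths and
  angles, hydrogens added), after which every backbone dihedral is set
  exactly: ω = 180°, (φ, ψ) = (−120°, +120°) by default, and sidechains
  in a single extended rotamer (χ = 180° along the main arm).
* The default (φ, ψ) lies in the parallel-β region of the Ramachandran
  map.  ψ = +120° (rather than a more textbook +130–135°) was chosen
  because the double layer here is built by *pure translation* along the
  sheet's hydrogen-bonding axis, and at +120° consecutive carbonyls align
  with that axis well enough that the translated copy forms a complete
  ladder under the hydrogen-bond criteria: exactly one intermolecular
  mainchain bond per i–(i+1) segment (14 rungs for the 15-mer),
  alternating donation direction.  This was fixed once, at design time,
  from the geometry; it is a property of the idealised builder, not a fit
  to any result.
* The two layers are exact translates 4.8 Å apart (the amyloid
  cross-β stacking distance; experimentally ≈ 4.78–4.82 Å).  An integer
  `registry_shift` and seeded Gaussian jitter are available for test
  ensembles.
* The builder's geometry is fully deterministic: the RDKit embedding
  uses a fixed internal seed (every dihedral is forced afterwards, so
  the embedding only supplies bond lengths/angles), and
  `BuilderParams.seed` controls nothing but the optional jitter.

What the builder does **not** reproduce: the fragment's meandering
(bent) strand shape, the crystal's sidechain rotamers and registry
details, or any solvent.  Consequences: the ideal ladder has ~14 rungs
where the optimized structure of the real dimer has 12 mainchain bonds
(with uneven spacing near the termini, e.g. only one bond N-terminal of
the ψ-E22 axis), so per-axis broken-bond counts here are correct
*relative to this ladder*, not numerically equal to the real system's.
Relations that depend only on the torsion kinematics — which rungs a
given axis detaches, and the φ-breaks-one-more-than-ψ rule within a
segment — transfer; absolute counts do not.

## Hydrogen-bond model

A bond is a donor–H⋯acceptor triple with donor–acceptor distance
≤ 3.6 Å and D–H⋯A angle ≥ 120° (both boundaries inclusive).  Donors are
N/O bearing at least one hydrogen; acceptors are any O plus N atoms
with no hydrogen; triples within one residue are excluded; a bond is
*mainchain* only when both heavy partners are mainchain atoms.  Glycine's
second α-hydrogen is classed as its sidechain, so "sidechain near the
axis" is meaningful for glycine too.  ΔN_HB between two conformations
counts intermolecular mainchain bonds present in the reference and
absent in the comparison, keyed by (donor, acceptor) identity so a bond
that merely switches hydrogens is unchanged.

The interlayer distance is defined as the mean over residue positions of
the corresponding upper/lower Cα–Cα distance — the simplest
registry-respecting measure; the source data's operational definition is
unknown, so agreement is only asserted within ±0.15 Å.

## Surrogate energy

A coarse, analytic stand-in for the quantum-chemical oracle, in
arbitrary "surrogate units" (≈ one hydrogen bond ≡ 1 unit).  It is
designed to rank conformations by the qualitative drivers of β-ladder
stability, not to reproduce eV-scale numbers:

| term | form | defaults |
| --- | --- | --- |
| steric/vdW | 12-6 Lennard-Jones, per-class (C, N, O, polar H, apolar H), Lorentz–Berthelot; pairs within 3 bonds excluded | σ = 3.2/3.0/2.9/1.0/2.4 Å, ε = 0.06/0.05/0.05/0.005/0.015; cutoff 10 Å |
| overlap core | below 0.8 Å the 12-6 term is frozen at its 0.8 Å value and a quadratic penalty (k = 50) takes over | finite at r → 0 |
| hydrogen bond | −depth · exp(−(d−d₀)²/2w²) · s(θ), with s the squared alignment factor vanishing at the 120° criterion boundary | depth 1.0, d₀ 2.9 Å, w 0.35 Å |
| covalent restraints | harmonic on 1-2 and 1-3 distances to the reference topology | k = 100, 20 unit/Å² |

Torsions are deliberately unrestrained — torsional motion is the subject
of the analysis.  Excluding 1-4 pairs from the nonbonded term removes
the large intrinsic strain an ideal extended chain would otherwise carry
and leaves steric barriers to be dominated by through-space contacts
(near-axis sidechain against the other layer), which is the effect under
study.  All terms depend only on internal distances and angles, so the
energy is exactly invariant under rigid motion; gradients are analytic
(verified against finite differences).

## Twisted-endpoint preparation

Because torsions are free and the detached chain is floppy, a twisted
conformation is generally *not* a local minimum of the surrogate — left
alone it can re-dock onto the lower layer (for glycine axes this is
exactly the low-barrier return the analysis is about).  Endpoints are
therefore prepared as constrained optima:

1. Both torsion directions are scanned over a 10°-spaced grid (to 180°).
   A rigid rotation of an in-register stack always grazes something, so
   only catastrophic overlaps (non-bonded heavy atoms < 0.5 Å — inside
   the finite core, irrecoverable by relaxation) disqualify an angle.
   This screen is what expresses the steric limitation on torsion
   direction: the direction that drives the near-axis sidechain through
   a layer is eliminated.
2. Candidates are ranked by how many ladder rungs they detach (the set
   of flat intermolecular mainchain bonds carried by the moving set),
   then by segment lift.
3. The winner is relaxed with the lifted segment's *mainchain atoms
   tethered* to their rigid-rotation positions (k = 25 unit/Å²) —
   consistent with the observation that the β-strand conformation is
   nearly preserved in the detached region — while sidechain rotamers,
   the ladder and covalent geometry relax freely.  A candidate whose
   relaxed form fails to keep exactly the target rungs broken is
   discarded and the next is tried (up to 8).

Internal-coordinate pinning alone was found insufficient: soft 1-3
restraints let a chain of small bond-angle flexes undo the orientation a
pinned torsion implies.

## Pathways and barriers

Initial paths sweep the axis dihedral linearly (shortest arc) from flat
to twisted, applying rigid torsion per image, which preserves covalent
bond lengths exactly along the path; Cartesian interpolation is provided
only as a documented contrast.  Because rigid intermediate rotations
graze the layers, production paths (`prepare_twist_path`) additionally
give every interior image a brief tethered relaxation — the same
backbone-tethered protocol as the endpoint — so the band starts free of
core overlaps.  The band (default 8 images, spring
k = 1.0) is relaxed by nudged-elastic-band iteration: improved
(energy-weighted uphill) tangent, true force projected perpendicular to
the tangent plus spring force along it, optional climbing image,
projected steepest descent with adaptive step and a 0.1 Å per-coordinate
displacement cap.  Endpoints never move.  The core is
dimension-agnostic and recovers the saddle of the analytic double well
V(x, y) = (x²−1)² + 5y² to better than 0.01 with 11 images.

Barriers are read off the relaxed profile: top = argmax;
twisted→flat barrier = E(top) − E(last); flat→twisted = E(top) −
E(first); endothermic energy = E(last) − E(first).  The identity
(flat→twisted) − (twisted→flat) = endothermic holds exactly by
construction.  Because the twisted endpoint is a constrained (not free)
optimum, the twisted→flat barrier can legitimately be small or zero for
axes with no steric obstruction — the glycine-axis behavior.

Production runs use 8 images and a few hundred NEB iterations with the
band typically still slowly tightening at the force tolerance; profile
maxima are stable well before full convergence, and the reported
`converged` flag records the honest state.  Problem sizes (a 424-atom
dimer, 8-image bands, ≈2000 L-BFGS steps for the flat reference) were
chosen so a complete six-axis analysis runs in minutes on one CPU.

## What the package reproduces, and what it cannot

Reproduced qualitatively on the synthetic system (and tested):

* a complete intermolecular mainchain ladder holding the flat layer,
  with the interlayer distance in the experimental cross-β band;
* per-axis ladder detachment: every rung N-terminal of the axis breaks,
  the C-terminal ladder persists, and φ breaks exactly one more rung
  than ψ within the same segment;
* the φ-D23 mechanism: the 22–23 segment carbonyl O–O pair is compressed
  from the stacking distance (~4.8–4.9 Å) to ≈ 3.0 Å by the φ twist and
  left untouched by the ψ-E22 twist;
* endothermic cost monotone in the number of broken bonds when other
  terms are frozen; and a strictly larger twisted→flat barrier when a
  bulky sidechain sits adjacent to the axis (matched poly-glycine pair
  differing by one valine).

Not reproducible here by design: quantum-chemical energies (eV-scale
endothermic energies and barrier heights), the deposited structures'
exact coordinates and distances, solvent effects, full-length Aβ, and
fibril-elongation kinetics.  Checks defined against the study's
deposited pathway ensembles (exact hydrogen-bond census 13/12, the
4.7783 → 2.9932 Å carbonyl approach, the 3.1348 Å G25 Hα⋯H contact)
run only when a user supplies those files; the CLI verb
`analyze-deposited` computes per-image ladders and near-axis contacts
for exactly that purpose.

## Known limitations

* The ideal ladder has more rungs than the real dimer's 12; absolute
  ΔN_HB values are ladder-relative.
* The surrogate's vdW treatment is crude; relative endothermic energies
  across axes with very different sidechain environments should not be
  over-interpreted.
* The flat reference is relaxed by bounded L-BFGS (default 2000
  iterations) and may carry a small residual gradient; endpoint and
  reference share one energy model so differences are consistent.
* `make_hb_fixture` breaks surplus rungs by swinging acceptor carbonyls /
  donor hydrogens out of the criteria; the resulting geometry is valid
  for detector tests but not a physical conformation.
* XYZ input carries no topology and always requires a template
  structure.
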