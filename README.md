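# abtwist

Torsional interconversion analysis of an amyloid-β(20–34) β-sheet double
layer: generation of *twisted* conformations by backbone φ/ψ torsion,
hydrogen-bond accounting between flat and twisted states, minimum-energy
paths by the nudged elastic band, and barrier / steric-contact analysis
on a coarse surrogate energy.

## The problem

Amyloid fibrils of the Aβ peptide grow by monomers locking onto fibril
ends as parallel in-register β-sheets, strand stacked on strand ~4.8 Å
apart and held by a ladder of mainchain hydrogen bonds
N–H(i)⋯O=C(i−1).  A monomer at a fibril end can partially detach: a
rotation about one backbone single bond — ψ (about Cα–C) or φ (about
N–Cα) at residue *i* — lifts everything N-terminal of that bond off the
layer below while the C-terminal part stays sheet-bound.  Which bonds
does a given torsion break?  How costly is the detachment, and how
easily does the twisted state revert?  For residues 20–34
(FAEDVGSNKGAIIGL, the fragment studied here) the interesting axes are
ψ-E22, φ-D23, ψ-D23, φ-V24, ψ-G25 and φ-S26.

The package answers these questions at desk scale.  A synthetic builder
replaces crystal-derived coordinates with an ideal parallel in-register
dimer; a coarse surrogate energy (Lennard-Jones sterics + smooth
hydrogen-bond wells + covalent restraints, analytic gradients) replaces
the quantum-chemical oracle.  Quantitative energies are out of scope;
torsion kinematics, hydrogen-bond ledgers (ΔN_HB = intermolecular
mainchain bonds broken by a twist), barrier *orderings* and
steric-contact geometry are the deliverables.  See `docs/methods.md` for
the model in full.

## Worked example

```python
import abtwist as ab

# flat double layer: two translated ideal strands, 4.8 A apart
dimer = ab.build_parallel_dimer(ab.BuilderParams())
mc = ab.count_hbonds(dimer, scope="intermolecular", class_filter="mainchain")
print(mc, round(ab.interlayer_distance(dimer), 3))
# -> 14 4.8   (one mainchain rung per i-(i+1) segment; builder separation)

# relax the flat reference, then twist about psi of G25
flat = ab.minimize(dimer, max_iter=2000).structure
tw = ab.generate_twisted(flat, ab.TorsionAxis(25, "psi"))
print(ab.delta_hb(flat, tw.structure).delta_n_hb)
# -> 5   (every rung N-terminal of the axis breaks; the rest persist)

# the phi-D23 mechanism: segment 22-23 carbonyl oxygens approach
tw23 = ab.generate_twisted(flat, ab.TorsionAxis(23, "phi"))
print(round(ab.segment_oo_distance(flat, 22), 2),
      round(ab.segment_oo_distance(tw23.structure, 22), 2))
# -> 4.92 3.0   (O-O compression that destabilises the phi-D23 twist)

# minimum-energy path and barrier for the glycine axis
path = ab.neb_relax(
    ab.prepare_twist_path(flat, tw.structure, ab.TorsionAxis(25, "psi"),
                          n_images=8),
    max_iter=250)
rep = ab.barrier(path)
print(rep.top_index, round(rep.barrier_twisted_to_flat, 2))
# -> 6 1.5   (surrogate units; glycine's small sidechain gives the
#             smallest return barrier of the six axes)
```

Across the six studied axes the twist ledger on the ideal ladder is
ΔN_HB = 2, 3, 3, 4, 5, 6 for ψ-E22, φ-D23, ψ-D23, φ-V24, ψ-G25, φ-S26 —
within each segment the φ torsion breaks exactly one more bond than the
ψ torsion, because φ additionally lifts the segment's C=O/N–H pair.

The same pipeline is scriptable from a shell:

```bash
abtwist build -o dimer.pdb                       # synthetic flat dimer
abtwist hbonds -i dimer.pdb                      # ladder census
abtwist report --builder --axis G25:psi --axis S26:phi --out run/
abtwist analyze-deposited --path-file path.pdb --axis S26:phi --out out/
```

`report` writes `report.json` plus tidy CSVs (`hbonds.csv`,
`ledger.csv`, `profile_<axis>.csv`, `contacts.csv`) and per-axis
multi-model PDB pathways; `analyze-deposited` computes per-image
hydrogen-bond counts and near-axis contacts for an externally supplied
pathway ensemble (multi-model PDB, or XYZ with a topology template).

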