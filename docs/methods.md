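# Methods

## The model

`ropespace` maps an ensemble of structures of one protein into a
low-dimensional conformational space built from torsion angles rather than
atomic coordinates.  The underlying assumption is physical: proteins move by
rotating about bonds, while bond lengths and angles are stiff.  Torsions are
therefore the natural coordinates of conformational change, they require no
superposition onto a reference structure, and linear interpolation between
torsion states never violates covalent geometry.

The pipeline, per protein *entity* (defined by a reference sequence):

1. **Chains as molecules.** Every polymer chain of every input structure is
   one molecule.  Hydrogens are dropped; alternate conformations collapse to
   the highest-occupancy one (ties break to the lexicographically first
   altloc); only the first MODEL block of multi-model files is read.
2. **Membership.** Each chain is globally aligned to the reference sequence
   (Needleman–Wunsch, match +1, mismatch −1, gap open −5, gap extend −1) and
   admitted if it has ≥ 10 residues and ≥ 80% identity.  Identity is counted
   over chain residues aligned to a reference position, so a fragment of a
   long reference is judged on what it covers.  The recorded mapping fixes
   the register across point mutations and indels.
3. **Internal coordinates.** Each chain becomes a spanning tree of its heavy
   atoms; every atom beyond the root trio carries (bond length, bond angle,
   torsion).  Lengths and angles are *reset to ideal values* from an
   embedded Engh & Huber-style table; only torsions describe conformation.
   Torsion identity is the atom-name quadruple read in either direction,
   anchored to the reference-sequence residue of the middle two atoms (the
   earlier residue when they span a peptide or disulfide bond).  A lysine
   and an arginine at the same position share columns exactly while atom
   names stay congruent — through Cδ.
4. **Refinement.** Rebuilding a chain from measured torsions on ideal
   geometry drifts along the chain (small local-geometry errors integrate
   into Ångström-scale displacement).  Refinement optimises the torsions so
   the rebuild matches the deposited coordinates: torsions are initialised
   from dihedrals measured on the deposit, then improved by damped
   Gauss–Newton with an analytic Jacobian (∂position/∂torsion is the
   rotation axis crossed with the lever arm), scored as all-heavy-atom RMSD
   after per-segment Kabsch superposition.  Every accepted step decreases
   the objective; a per-torsion analytic coordinate-descent sweep is the
   fallback when a Gauss–Newton step fails.
5. **Ordination.**  Per torsion column, the circular mean is subtracted and
   the wrapped difference *t* ∈ (−180°, 180°] embedded as (sin *t*, cos *t*);
   a missing torsion is the zero vector.  A molecules × molecules Pearson
   correlation matrix is computed over the embedded components matched in
   both members of each pair, then eigendecomposed.  Molecule *m*'s
   coordinate on axis *k* is its eigenvector loading × √λ<sub>k</sub>, so
   per-axis variance equals the eigenvalue.  Each axis also maps back to a
   per-torsion angular delta (the loading-weighted sum of raw differences),
   which is what makes axes interpretable as motions.
6. **Comparator.**  The same correlation → SVD pipeline run on superposed
   atomic coordinates (features: x, y, z of atoms matched to a reference
   member by name and alignment; reference = the member with the most
   modelled residues not exceeding the sequence length).  Unlike the torsion
   space this depends on the reference choice.
7. **Axis exploration.**  An axis delta applied to a reference structure at
   slider positions s ∈ [−1, 1] and rebuilt on ideal geometry gives
   physically sensible frames; per-residue |Δφ| + |Δψ| scores highlight
   hinge residues; atom-to-atom marker distances annotate the space with an
   interpretable structural coordinate.

## Numerical and design choices

**Per-component centering before the correlation.**  The cosine half of the
embedding is ≈ 1 for every small difference, which makes all pairwise
correlations saturate near 1 and the leading eigenvector degenerate to the
constant vector (eigenvalue ≈ N).  Each embedded component is therefore
centered across the molecules that possess it before the pairwise Pearson;
the correlation then reflects only how molecules co-vary around the ensemble
mean, and planted motions surface on the top axes.  (The alternative —
kernel-style double-centering of the correlation matrix itself — gives
near-identical spaces on our fixtures.)

**Zero-variance molecules.**  A molecule whose centered feature vector is
exactly zero sits at the ensemble mean.  Two such molecules are
indistinguishable and are assigned correlation 1 (not 0), so an ensemble of
rigid-body copies collapses to a single point rather than to an arbitrary
orthonormal scatter.  Pairs with fewer than 3 matched torsions, or with one
flat vector out of two, get correlation 0 with a logged warning.

**Null axes.**  Eigenvalues below 10⁻¹⁰ of the spectral radius are given
exactly zero projection extent; otherwise duplicate molecules would pick up
√ε-sized junk coordinates on degenerate axes.

**Axis sign and determinism.**  Each axis is flipped so its
largest-magnitude loading is positive; all randomness flows from a single
integer seed; the PDB writer and all JSON serialisations are canonical, so a
fixed seed reproduces every artifact byte for byte.

**Refinement optimiser.**  Pure per-torsion coordinate descent (with any
line search) converges too slowly here: torsions couple through lever arms,
and the resulting zig-zag leaves ~0.1 Å residuals on problems the
Gauss–Newton step solves to machine precision.  The measured-dihedral
initialisation is both the natural starting point (the deposit is the data)
and a guard against the wrapped-angle local minima that plague far-from-truth
starts.  Defaults: convergence at < 10⁻⁴ Å RMSD improvement per iteration,
50 iterations maximum, initial Levenberg damping 10⁻⁴.

**Ideal geometry.**  The embedded table (`data/ideal_geometry.tsv`) carries
explicit backbone constants (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°, …) and fills side chains from
bond-class rules (sp³ C–C 1.530 Å, aromatic 1.390 Å, sp³ angles 110.5°, sp²
120°, five-ring 108°, plus residue-specific overrides).  Proline's ring and
the aromatic rings are placed along a spanning tree; the ring-closing bond
is not re-closed by least squares, a deliberate approximation.  ω torsions
are real degrees of freedom and are included.  Disulfides are detected
geometrically (SG–SG < 2.5 Å) and contribute an off-tree CB–SG–SG–CB torsion
assigned to the earlier residue.

**Atom tree.**  Root trio N–CA–C of the first residue of each ordered
segment; children N → CA → C → O → side chain in topology order; chain
breaks (C–N > 2.0 Å or missing backbone atoms) split the tree, and no
torsion spans a break.  The first residue's CB is placed from an improper
frame (C, N, CA) and is excluded from cross-structure torsion identities.

## The synthetic generator

`synthetic.generate_ensemble` emulates the statistical structure the method
assumes: a base chain (default α-helical poly-alanine, φ = −57°, ψ = −47°)
whose conformers differ by a small number of independent linear torsion
modes plus wrapped-normal angular noise, with optional two-group coefficient
splits (the cryo/room-temperature analogue), point mutations, sequence
deletions and unmodelled loops.  Ground truth — mode definitions,
per-molecule coefficients, group labels, every generated torsion — is
recorded alongside.

Default study conditions used by the tests and the acceptance script,
chosen once at design time:

- *Planted-mode recovery*: 40 molecules, 24 residues, two modes of 20
  Ramachandran torsions at 25° and 17° with independent ±1 (two-group)
  coefficients, 2° ambient noise.  Binary coefficients are used because the
  unit-diagonal correlation matrix caps the top-axis eigenvalue share at
  the per-molecule signal fraction, and driving continuous-coefficient
  amplitudes high enough to meet that share warps the loadings (row-norm
  normalisation) and feeds cos → c² horseshoe components; ± splits have
  constant row norms and no quadratic component, so recovery is crisp.
- *Two-group separation*: 20+20 molecules, 10° between groups spread over
  20 torsions, 2° noise.
- *Small-motion equivalence*: one mode of 2° over 20 torsions, uniform
  coefficients, 30 molecules, 0.05° noise.  With two simultaneous modes the
  torsion- and coordinate-derived spaces weight the modes differently —
  coordinate space scales each torsion by its downstream lever arm — so the
  relative axis scaling differs between the spaces even at zero noise.
  That is a real difference between the representations, not an artifact;
  the small-angle equivalence claim is per-direction and is tested with a
  single mode.

What the generator does **not** emulate: sterics and packing, realistic
Ramachandran statistics, crystal-contact-correlated motions, B-factor and
occupancy heterogeneity, experimental restraint noise structure.  Passing
tests therefore demonstrate the machinery is correct under the model's own
assumptions, not that real crystallographic ensembles will separate as
cleanly.

Problem sizes in the test-suite and acceptance runs (chains of 5–200
residues, ensembles of 14–40 molecules of 14–24 residues) are chosen as the
smallest sizes at which each phenomenon is unambiguous — drift needs a long
chain, ordination needs tens of molecules; nothing in the method is
size-specific.

## Known limitations

- The correlation-matrix normalisation compresses large-amplitude molecules
  (a molecule's loading is bounded by its row norm), so projections are a
  monotone but nonlinear image of an underlying continuous coordinate.
- Large torsion differences feed quadratic cos components into the
  correlation — the classic horseshoe; the paper-scale phenomenon is
  reproduced rather than corrected.
- Proline ring closure and the CB placement at segment starts are
  approximate (see above).
- Identity-based admission with one reference sequence per entity; no
  multi-entity chimera handling.
- The coordinate comparator matches atoms through the same residue mapping
  as the torsion pipeline; atoms in unaligned insertions are invisible to
  both spaces.
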