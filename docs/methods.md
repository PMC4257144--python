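# Methods

## The model

`escapist` treats the database of native protein structures as a thermodynamic
ensemble: features that are narrowly distributed across natives are assumed to be
energetically constrained, and a candidate model is judged by how far its features
deviate from the native means. The feature is the electrostatic potential difference
(EPD) between named atoms of sequence-consecutive residues, in dimensionless kT/e.
Cβ–Cβ is the default mode because the Cβ atom — present in all standard residues
except glycine — summarizes the sidechain moiety; the C–N (peptide bond) and Cα–Cα
modes exist chiefly to demonstrate that backbone EPDs do *not* separate residue types
(nearly invariant backbone geometry makes their distributions overlap, with the known
exception of proline-containing pairs in Cα mode, whose means are shifted).

Pair types are order-independent. An observation of types (a, b) is stored under the
sorted key; if sorting swapped the order, the sign of the difference is flipped
(`multfactor = −1`). The involution property — either presentation of the same
physical pair yields the same (key, value) — is enforced by tests.

Learning pools observations per pair type over all structures and reduces them to a
mean (MLV) and sample SD (n−1 denominator; the choice is a convention, the data never
has n = 1 in practice). Entries with SD above `sdThresh` or fewer than `minSamples`
observations are dropped. The alternative estimator — average of per-structure means,
which weights structures equally rather than observations — is available via
`FeatureConfig(perProteinAveraging=True)`; the two differ only when structures
contribute unequal pair counts.

The PDscore of a structure is the mean absolute deviation of its observed canonical
EPDs from the template means, normalized by the number of pairs actually compared.
Pairs without a template entry (filtered types, glycine in Cβ mode, missing atoms,
chain breaks) neither add deviation nor inflate the denominator; a structure with zero
comparable pairs is *unscorable*, a distinct error rather than a perfect score.
Specificity of a decoy set is the fraction of decoys scored strictly worse than the
native; a tie counts against the native, since the score failed to separate the pair.

## Electrostatics backends

* **`coulomb`** (default): φ at each atom center is the uniform-dielectric
  (solvent ε) Coulomb sum over all other charges, scaled by
  e²/(4πε₀kT) ≈ 560.74 Å at 298 K so the result is kT/e. The atom's own charge is
  excluded (its self-term is infinite and type-independent). Exact, linear, and
  rotation-invariant to machine precision — properties the tests exploit as oracles.
  An exp(−κr) factor implements Debye screening when the ionic strength is nonzero.
* **`fd`**: linearized finite-difference Poisson–Boltzmann on a regular grid. At the
  default zero ionic strength this is the pure Poisson equation, so linear and
  nonlinear PB coincide. Charges are spread to the 8 nearest nodes (cloud-in-cell);
  the dielectric is the solute value (default 2) inside the probe-inflated (1.4 Å)
  van der Waals envelope and the solvent value (78) outside, with harmonic-mean face
  dielectrics in the 7-point stencil and no surface smoothing — the simplest boundary
  consistent with the continuum setup. Boundary nodes take Dirichlet values from the
  analytic solvent-dielectric Coulomb field, which is exact for the Born ion and
  asymptotically correct otherwise. The symmetric positive-definite system is solved
  by Jacobi-preconditioned conjugate gradients to relative residual 1e−8;
  non-convergence raises an error reporting the residual. Grid: 0.5 Å spacing, box =
  molecular extent × 1.7 with an 8 Å minimum margin. Against closed forms the solver
  is well inside its acceptance bands: 0.25 % error vs Coulomb at r = 5 Å (uniform
  dielectric) and 1.9 % vs the Born-ion exterior at r = 4 Å.
* **`external`**: writes an APBS input file carrying the standard parameters (pdie 2,
  sdie 78, srad 1.4, temp 298, lpbe, sdh boundary), runs the binary, reads the OpenDX
  grid, and interpolates at atom centers. Absent binaries raise a
  missing-executable error that tests treat as a skip. Absolute potentials depend on
  grid setup, so templates record their backend in provenance and should only score
  structures processed with the same backend.

Atom-center readout from any grid is trilinear interpolation of the 8 surrounding
nodes; it reproduces linear fields exactly, which the tests assert at 1e−12.

Charge assignment defaults to a bundled coarse "bead" model over the heavy-atom
backbone + Cβ representation: fixed amide and carbonyl partial charges (N −0.45,
CA +0.25, C +0.55, O −0.55), a residue-type-dependent polarity charge on Cβ
(compensated on Cα so neutral residues sum to exactly 0 e), and the formal charges of
D/E/K/R placed on Cβ. Recognizable full-atom sidechain names get zero charge and an
element radius so real PDB files remain scorable; truly unknown atom names raise an
error naming the atom. The bead values are a deliberately simple chemically-ordered
assignment — adequate for pair-type statistics, not for energetics. Structures parsed
from PQR files keep their own charges and radii untouched.

## Structure handling

PDB parsing (via gemmi) keeps the 20 standard amino acids only: HETATM, waters and
nonstandard residues (MSE, ...) are dropped, not remapped, because the template has no
keys for them. Alternate locations keep the highest-occupancy conformer (ties: altloc
"A", then lexicographic). Residue indices are 1-based. Consecutive pairs for a chain
of length N run from position 1 + `ignoreNTerm` to N − `ignoreCTerm` − 1 — terminal
residues carry perturbing charged groups, and the default of 3 on each side is this
package's choice, configurable on every CLI command. Pairs with an author-numbering
gap ≠ 1 (chain breaks, insertion codes) are skipped, and pairs never cross chains.
Multi-chain structures are scored over all chains together (a flag restricts scoring
to the first chain).

## Synthetic data

The fixture generator builds peptides from ideal internal geometry (frozen constants:
N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, CA–CB 1.521 Å, trans peptide
bond, default α-helical φ/ψ of −57°/−47°, Cβ placed tetrahedrally with the
L-configuring improper of 122.6°) plus seeded Gaussian coordinate jitter. Decoy
families add i.i.d. isotropic Gaussian noise at chosen σ to a native; the mean RMSD of
such a family approaches σ√3. All generators are pure functions of (spec, seed).

What this emulates: the *layout* and *statistics* of a learning set and of
noise-graded decoy sets, with exactly known ground truth. What it does not emulate:
real conformational diversity (decoys from fragment assembly or MD occupy physically
plausible basins, not isotropic noise), full sidechains, crystallographic artifacts,
or the charge detail of a real force field. Passing the self-consistency tests
therefore shows the pipeline is correct and self-consistent, not that the bead-model
template matches the published one — scoring real decoy databases still requires the
reference electrostatics toolchain and the published template.

Tests that need exact statistical oracles bypass the solver entirely and inject
per-residue-type base potentials with i.i.d. noise (a callable backend), under which
every pair type's expected EPD is the base-value difference and its SD is σ√2. The
parameter-recovery check (50 peptides of length 30, σ = 10 kT/e) and the
SD-vs-sequence-distance flatness check use this model. Problem sizes throughout the
suite (5 targets × 10 decoys for self-consistency, 30-mers, 0.5 Å grids) were chosen
as the smallest at which the statistical assertions are stable.

## Known limitations and open choices

* The published template excerpt ships 16 of the full pair set; the complete learned
  template must be regenerated (or fetched from the original source) before scoring
  real structures comprehensively.
* Pooled-observation statistics are the default estimator; whether the published
  template was pooled or per-protein-averaged is not documented, so both are
  implemented.
* Cysteine-containing pairs are handled mechanically by the SD filter (their spread,
  ≈90 kT/e, removes them; the tight "CC" pair survives). `--exclude-cysteine` drops
  them all for strict conservatism.
* The misfold-style layout adapter takes the first incorrect structure when a target
  provides several.
* Scores from different electrostatics backends are not comparable; provenance
  metadata is attached to templates and reports to prevent silent mixing.
* Physically non-viable decoys (steric clashes) still yield finite potentials and can
  score arbitrarily; a steric pre-filter is outside this package's scope, and scores
  for such inputs should not be interpreted.
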