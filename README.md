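# escapist

Model quality assessment for protein structures from the electrostatic profile of
sidechain atoms.

Structure-prediction pipelines emit many closely ranked candidate models; a model
quality assessment program (MQAP) picks the one most likely to be native. `escapist`
implements a knowledge-based MQAP built on a single physical feature: the
**electrostatic potential difference (EPD)**, in units of kT/e, between the Cβ atoms of
sequence-consecutive residues. The Cβ atom is a single-atom proxy for the sidechain,
present in every standard amino acid except glycine, so the EPD of a consecutive pair
carries a signature of the two residue types. Across native structures these EPDs are
tightly distributed per pair type, while backbone features (the C–N peptide bond, or
Cα–Cα) are not — which is what makes the Cβ profile a discriminator.

## The score

**Learning phase.** For a set of native structures, every consecutive pair
(Res<sub>n</sub>, Res<sub>n+1</sub>) contributes one observation

> EPD = φ(Cβ of Res<sub>n</sub>) − φ(Cβ of Res<sub>n+1</sub>)

where φ is the continuum-electrostatics potential at the atom center. Pair types are
order-independent: observations are keyed by the alphabetically sorted type pair, with
the sign flipped when the observed order was swapped (so "CA" enters the "AC"
statistics negated). Per pair type the mean learnt value (MLV) and standard deviation
are computed; pair types with SD above `sdThresh` (50 kT/e by default — this removes
the loosely constrained cysteine-containing pairs) are dropped. The surviving means
form the template.

**Assessment phase.** For a candidate structure,

> PDscore = (1 / N<sub>compared</sub>) · Σ |EPD<sub>observed</sub> − MLV(pair type)|

summed over consecutive pairs that have a template entry. Lower is better: by the
Boltzmann view of structure databases and the thermodynamic hypothesis that the native
state minimizes free energy, the native structure should minimize the deviation from
the learned means. For a decoy set (one native + N decoys), **specificity** is the
fraction of decoys scored strictly worse than the native.

Potentials come from one of three backends: an analytic uniform-dielectric Coulomb sum
(default; fast and exact), a built-in finite-difference Poisson solver with the
standard two-dielectric boundary (solute ε=2, solvent ε=78, probe 1.4 Å, 298 K, zero
salt), or the external PDB2PQR + APBS toolchain when installed.

## Worked example

Everything below runs on synthetic data generated by the package itself — idealized
peptides with seeded Gaussian-noise decoys:

```sh
$ escapist fixtures --out-dir demo/decoys --n-targets 3 --count-per-level 10 --seed 7
wrote 3 targets under demo/decoys

$ escapist learn demo/decoys/*/native.pdb -o demo/template.tsv --min-samples 1
retained 46 pair types (dropped 164 of 210 possible)

$ escapist score demo/decoys/target00/native.pdb -t demo/template.tsv --min-samples 1
PDscore 0.1159 numberCompared 17

$ escapist score demo/decoys/target00/decoy_2_000.pdb -t demo/template.tsv --min-samples 1
PDscore 1.4159 numberCompared 17

$ escapist evaluate demo/decoys -t demo/template.tsv --min-samples 1
PDB     NRes    NStructures     Specificity
target00        30      11      1
target01        30      11      1
target02        30      11      1
mean specificity 1.0000
```

The native's PDscore (0.12 kT/e mean absolute deviation over 17 compared pairs) is an
order of magnitude below its 2 Å-noise decoy (1.42), and every decoy of every target is
ranked behind its native (specificity 1.0). The 46-of-210 retention reflects which pair
types actually occur in three 30-mers with enough samples and a tight enough spread.

The package also ships the published 16-pair Cβ template excerpt
(`escapist.features.packaged_template()`), learned from 1000 non-homologous PISCES
chains with the APBS reference backend — e.g. pair DF: mean −108.9 kT/e, SD 29.5,
n = 481 — which can score real PDB files directly.

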