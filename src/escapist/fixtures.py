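"""Synthetic structures with known ground truth.

Idealized peptides are built from standard internal geometry (bond lengths and angles
from small-molecule peptide surveys, frozen below) at caller-chosen backbone dihedrals,
with the C-beta placed tetrahedrally; decoy families add seeded isotropic Gaussian
coordinate noise to a native.  Everything is a pure function of (spec, seed), so every
stage of the learning/scoring pipeline can be exercised without downloading a single
structure.  These generators emulate the geometry and layout of real learning and decoy
sets, not their conformational diversity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from escapist.electrostatics import ChargedStructure
from escapist.structure_io import (
    AtomRecord,
    Chain,
    ProteinStructure,
    Residue,
    STANDARD_AA,
    write_pdb,
)

__all__ = [
    "PeptideSpec",
    "DecoyFamilySpec",
    "IDEAL_GEOMETRY",
    "generate_peptide",
    "generate_decoy_family",
    "synthetic_charge_system",
]

# Ideal peptide internal geometry (A, degrees); trans peptide bond throughout.
IDEAL_GEOMETRY = {
    "bond_N_CA": 1.458,
    "bond_CA_C": 1.525,
    "bond_C_N": 1.329,
    "bond_C_O": 1.231,
    "bond_CA_CB": 1.521,
    "angle_N_CA_C": 111.2,
    "angle_CA_C_N": 116.2,
    "angle_C_N_CA": 121.7,
    "angle_CA_C_O": 120.8,
    "angle_C_CA_CB": 110.1,
    "torsion_N_C_CA_CB": 122.6,  # improper fixing L-chirality of the C-beta branch
    "omega": 180.0,
}


@dataclass(frozen=True)
class PeptideSpec:
    """A synthetic peptide: sequence, backbone dihedrals, seeded coordinate jitter."""

    sequence: str
    phi: float = -57.0   # degrees; default alpha-helical
    psi: float = -47.0
    seed: int = 0
    jitter: float = 0.0  # A, SD of isotropic Gaussian noise per coordinate

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(f"unknown residue code(s) {sorted(bad)}")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D from A-B-C internal
    coordinates: |CD| = bond, angle(B,C,D), dihedral(A,B,C,D)."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def generate_peptide(spec: PeptideSpec, structure_id: str | None = None,
                     chain_id: str = "A") -> ProteinStructure:
    """Build an idealized peptide with N, CA, C, O and (except glycine) CB atoms.

    All residues share the spec's (phi, psi); the peptide bond is trans.  Gaussian
    jitter of SD ``spec.jitter`` is added per coordinate from a generator seeded with
    ``spec.seed``, so identical specs give identical coordinates.
    """
    g = IDEAL_GEOMETRY
    seq = spec.sequence
    coords: list[dict[str, np.ndarray]] = []
    for i, aa in enumerate(seq):
        atoms: dict[str, np.ndarray] = {}
        if i == 0:
            atoms["N"] = np.zeros(3)
            atoms["CA"] = np.array([g["bond_N_CA"], 0.0, 0.0])
            theta = math.radians(g["angle_N_CA_C"])
            atoms["C"] = atoms["CA"] + g["bond_CA_C"] * np.array(
                [-math.cos(theta), math.sin(theta), 0.0])
        else:
            prev = coords[i - 1]
            atoms["N"] = _place_atom(prev["N"], prev["CA"], prev["C"],
                                     g["bond_C_N"], g["angle_CA_C_N"], spec.psi)
            atoms["CA"] = _place_atom(prev["CA"], prev["C"], atoms["N"],
                                      g["bond_N_CA"], g["angle_C_N_CA"], g["omega"])
            atoms["C"] = _place_atom(prev["C"], atoms["N"], atoms["CA"],
                                     g["bond_CA_C"], g["angle_N_CA_C"], spec.phi)
        atoms["O"] = _place_atom(atoms["N"], atoms["CA"], atoms["C"],
                                 g["bond_C_O"], g["angle_CA_C_O"], spec.psi + 180.0)
        if aa != "G":
            atoms["CB"] = _place_atom(atoms["N"], atoms["C"], atoms["CA"],
                                      g["bond_CA_CB"], g["angle_C_CA_CB"],
                                      g["torsion_N_C_CA_CB"])
        coords.append(atoms)

    rng = np.random.default_rng(spec.seed)
    residues = []
    for i, aa in enumerate(seq):
        res = Residue(chainId=chain_id, seqIndex=i + 1, insertionCode="", aaType=aa)
        for name, pos in coords[i].items():
            p = pos + (rng.normal(0.0, spec.jitter, 3) if spec.jitter > 0 else 0.0)
            res.atoms[name] = AtomRecord(
                name=name, element=name[0], position=tuple(float(v) for v in p))
        residues.append(res)
    return ProteinStructure(
        id=structure_id or f"pep-{seq[:8]}-{spec.seed}",
        chains=[Chain(id=chain_id, residues=residues)])


@dataclass
class DecoyFamilySpec:
    """A native structure plus Gaussian-noise decoys at one or more noise levels."""

    native: ProteinStructure
    noiseLevels: list[float] = dc_field(default_factory=lambda: [2.0])
    countPerLevel: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.noiseLevels):
            raise ValueError("noise levels must be >= 0")
        if self.countPerLevel < 1:
            raise ValueError("countPerLevel must be >= 1")


def perturb_structure(structure: ProteinStructure, sigma: float,
                      rng: np.random.Generator,
                      structure_id: str | None = None) -> ProteinStructure:
    """Copy of the structure with i.i.d. Gaussian noise of SD ``sigma`` per coordinate."""
    chains = []
    for chain in structure.chains:
        residues = []
        for res in chain.residues:
            out = Residue(chainId=res.chainId, seqIndex=res.seqIndex,
                          insertionCode=res.insertionCode, aaType=res.aaType)
            for name, atom in res.atoms.items():
                p = np.asarray(atom.position) + rng.normal(0.0, sigma, 3)
                out.atoms[name] = AtomRecord(name=atom.name, element=atom.element,
                                             position=tuple(float(v) for v in p))
            residues.append(out)
        chains.append(Chain(id=chain.id, residues=residues))
    return ProteinStructure(id=structure_id or structure.id + "-decoy", chains=chains)


def generate_decoy_family(spec: DecoyFamilySpec, out_dir: str | Path) -> Path:
    """Write a native + noise-decoy target directory consumable by the evaluator.

    Layout: ``out_dir/<native.id>/native.pdb`` plus ``decoy_<level>_<k>.pdb`` files,
    and a ``manifest.json`` recording the seed and noise levels.
    """
    out_dir = Path(out_dir)
    target = out_dir / spec.native.id
    target.mkdir(parents=True, exist_ok=True)
    write_pdb(spec.native, target / "native.pdb")
    rng = np.random.default_rng(spec.seed)
    names = []
    for sigma in spec.noiseLevels:
        for k in range(spec.countPerLevel):
            decoy = perturb_structure(spec.native, sigma, rng,
                                      structure_id=f"{spec.native.id}-d{sigma}-{k}")
            name = f"decoy_{sigma:g}_{k:03d}.pdb"
            write_pdb(decoy, target / name)
            names.append(name)
    (target / "manifest.json").write_text(json.dumps({
        "native": spec.native.id,
        "seed": spec.seed,
        "noiseLevels": spec.noiseLevels,
        "countPerLevel": spec.countPerLevel,
        "decoys": names,
    }, indent=2))
    return target


def synthetic_charge_system(kind: str, **params) -> ChargedStructure:
    """Analytic test systems for the electrostatics solvers.

    ``point``:  one charge ``q`` (default +1) of radius ``radius`` (default 1.5 A).
    ``born``:   one charge ``q`` of radius ``radius`` (default 2.0 A) -- the Born ion.
    ``dipole``: charges +q and -q separated by ``separation`` (default 3.0 A) along x.
    """
    q = float(params.get("q", 1.0))
    if kind == "point":
        atoms = [("Q1", (0.0, 0.0, 0.0), q, float(params.get("radius", 1.5)))]
    elif kind == "born":
        atoms = [("Q1", (0.0, 0.0, 0.0), q, float(params.get("radius", 2.0)))]
    elif kind == "dipole":
        d = float(params.get("separation", 3.0))
        r = float(params.get("radius", 1.5))
        atoms = [("Q1", (-d / 2.0, 0.0, 0.0), q, r),
                 ("Q2", (d / 2.0, 0.0, 0.0), -q, r)]
    else:
        raise ValueError(f"unknown charge-system kind {kind!r}")
    res = Residue(chainId="A", seqIndex=1, insertionCode="", aaType="A")
    for name, pos, charge, radius in atoms:
        res.atoms[name] = AtomRecord(name=name, element="C", position=pos,
                                     charge=charge, radius=radius)
    structure = ProteinStructure(id=f"synthetic-{kind}",
                                 chains=[Chain(id="A", residues=[res])])
    return ChargedStructure(structure=structure, forcefieldName="synthetic")
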