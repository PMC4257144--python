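"""Reading and modelling protein structures for consecutive-residue feature extraction.

PDB files are read through :mod:`gemmi`; the PQR dialect (charge and radius in place of
occupancy/B-factor, whitespace-separated) is read by a small column parser.  The in-memory
model keeps only the 20 standard amino acids, ordered per chain, because the learned
template has keys only for those types.  Residue indices are 1-based throughout, matching
the summation bounds of the learning- and scoring-phase equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi

__all__ = [
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "AtomRecord",
    "Residue",
    "Chain",
    "ProteinStructure",
    "ResiduePairRef",
    "StructureParseError",
    "EmptyStructureError",
    "parse_structure",
    "consecutive_pairs",
    "write_pdb",
    "write_pqr",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
STANDARD_AA = frozenset(ONE_TO_THREE)


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed; message names the offending line."""


class EmptyStructureError(ValueError):
    """Raised when a file contains no standard amino-acid residues."""


@dataclass
class AtomRecord:
    """A single atom: name, element, Cartesian position in Angstrom.

    ``charge`` and ``radius`` are populated only when reading PQR files (otherwise None).
    """

    name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    charge: float | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0,1] for atom {self.name}")


@dataclass
class Residue:
    """One standard amino acid with its atoms keyed by atom name."""

    chainId: str
    seqIndex: int
    insertionCode: str
    aaType: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aaType not in STANDARD_AA:
            raise ValueError(f"non-standard amino-acid code {self.aaType!r}")

    def get_atom(self, name: str) -> AtomRecord | None:
        return self.atoms.get(name)

    def has_atom(self, name: str) -> bool:
        return name in self.atoms


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ProteinStructure:
    """Ordered chains of standard residues; the substrate of all feature extraction."""

    id: str
    chains: list[Chain] = field(default_factory=list)

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def iter_residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def get_chain(self, chainId: str) -> Chain:
        for chain in self.chains:
            if chain.id == chainId:
                return chain
        raise KeyError(f"no chain {chainId!r} in structure {self.id}")

    def get_residue(self, chainId: str, seqIndex: int) -> Residue:
        for res in self.get_chain(chainId).residues:
            if res.seqIndex == seqIndex:
                return res
        raise KeyError(f"no residue {seqIndex} in chain {chainId} of {self.id}")


@dataclass(frozen=True)
class ResiduePairRef:
    """A sequence-consecutive residue pair (n, n+1) within one chain.

    ``n`` is the author sequence number of the first residue; the second residue is its
    immediate chain successor (numbering gap exactly 1).
    """

    chainId: str
    n: int
    aaTypeFirst: str
    aaTypeSecond: str


def _choose_altloc(candidates: list[AtomRecord]) -> AtomRecord:
    # highest occupancy wins; ties broken by altloc "A", then lexicographically
    def rank(a: AtomRecord) -> tuple[float, int, str]:
        return (-a.occupancy, 0 if a.altloc in ("", "A") else 1, a.altloc)

    return sorted(candidates, key=rank)[0]


def _looks_like_pqr(path: Path) -> bool:
    if path.suffix.lower() == ".pqr":
        return True
    return False


def _parse_pqr(path: Path, structure_id: str) -> ProteinStructure:
    chains: dict[str, Chain] = {}
    raw: dict[tuple[str, int, str, str], list[AtomRecord]] = {}
    order: list[tuple[str, int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            fields = line.split()
            # with chain id: rec serial name resname chain resseq x y z q r  (11 fields)
            # without:       rec serial name resname resseq x y z q r       (10 fields)
            try:
                if len(fields) >= 11 and not fields[4].lstrip("-").isdigit():
                    name, resname, chain_id, resseq = fields[2], fields[3], fields[4], fields[5]
                    rest = fields[6:11]
                elif len(fields) >= 10:
                    name, resname, resseq = fields[2], fields[3], fields[4]
                    chain_id = "A"
                    rest = fields[5:10]
                else:
                    raise ValueError("too few columns")
                x, y, z, q, r = (float(v) for v in rest)
                seq = int(resseq)
            except (ValueError, IndexError) as exc:
                raise StructureParseError(f"{path}: malformed PQR record at line {lineno}: {exc}") from exc
            if line.startswith("HETATM") or resname not in THREE_TO_ONE:
                continue
            key = (chain_id, seq, "", resname)
            if key not in raw:
                raw[key] = []
                order.append(key)
            raw[key].append(
                AtomRecord(name=name, element=name[0], position=(x, y, z), charge=q, radius=r)
            )
    for chain_id, seq, icode, resname in order:
        res = Residue(chainId=chain_id, seqIndex=seq, insertionCode=icode,
                      aaType=THREE_TO_ONE[resname])
        for atom in raw[(chain_id, seq, icode, resname)]:
            res.atoms[atom.name] = atom
        chains.setdefault(chain_id, Chain(id=chain_id)).residues.append(res)
    structure = ProteinStructure(id=structure_id, chains=list(chains.values()))
    if structure.n_residues == 0:
        raise EmptyStructureError(f"{path}: no standard amino-acid residues found")
    return structure


def parse_structure(path: str | Path, model_index: int = 0) -> ProteinStructure:
    """Read a PDB (or PQR) file into a :class:`ProteinStructure`.

    Keeps standard amino acids only (HETATM, waters and nonstandard residues such as MSE
    are dropped, not remapped).  For alternate locations the highest-occupancy conformer
    is kept; ties go to altloc "A", then lexicographic order.  ``model_index`` selects a
    model from multi-model (e.g. NMR) files; default is the first.

    Raises
    ------
    StructureParseError
        if the file cannot be read (message names the offending line when known).
    EmptyStructureError
        if no standard residues remain after filtering.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if _looks_like_pqr(path):
        return _parse_pqr(path, path.stem)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: file contains no coordinate models")
    if model_index >= len(st):
        raise StructureParseError(
            f"{path}: model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    chains: list[Chain] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if res.het_flag != "A" or res.name not in THREE_TO_ONE:
                continue
            out = Residue(
                chainId=ch.name,
                seqIndex=res.seqid.num,
                insertionCode=(res.seqid.icode or "").strip(),
                aaType=THREE_TO_ONE[res.name],
            )
            by_name: dict[str, list[AtomRecord]] = {}
            for atom in res:
                rec = AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    position=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    altloc=atom.altloc.strip("\x00") if atom.altloc else "",
                )
                by_name.setdefault(atom.name, []).append(rec)
            for name, cands in by_name.items():
                out.atoms[name] = _choose_altloc(cands)
            residues.append(out)
        if residues:
            chains.append(Chain(id=ch.name, residues=residues))
    structure = ProteinStructure(id=st.name or path.stem, chains=chains)
    if structure.n_residues == 0:
        raise EmptyStructureError(f"{path}: no standard amino-acid residues found")
    return structure


def consecutive_pairs(
    structure: ProteinStructure,
    ignoreNTerm: int = 3,
    ignoreCTerm: int = 3,
) -> list[ResiduePairRef]:
    """Enumerate the (n, n+1) residue pairs the EPD features are computed on.

    Per chain of length N, pairs start at 1-based position ``1 + ignoreNTerm`` and end at
    position ``N - ignoreCTerm - 1`` (inclusive), excluding the charged termini from the
    statistics.  Pairs whose author numbering gap is not exactly 1 (chain breaks, insertion
    codes) are skipped, and pairs never cross chains.  A chain too short to contribute
    yields no pairs (not an error).
    """
    if ignoreNTerm < 0 or ignoreCTerm < 0:
        raise ValueError("ignoreNTerm and ignoreCTerm must be >= 0")
    pairs: list[ResiduePairRef] = []
    for chain in structure.chains:
        N = len(chain)
        # 1-based positions p = 1+ignoreNTerm ... N-ignoreCTerm-1 pair with p+1
        for p in range(1 + ignoreNTerm, N - ignoreCTerm):
            r1 = chain.residues[p - 1]
            r2 = chain.residues[p]
            if r2.seqIndex - r1.seqIndex != 1:
                continue
            pairs.append(ResiduePairRef(
                chainId=chain.id, n=r1.seqIndex,
                aaTypeFirst=r1.aaType, aaTypeSecond=r2.aaType,
            ))
    return pairs


_PDB_ATOM = ("{rec:<6}{serial:>5} {name:<4}{alt:1}{resname:<3} {chain:1}"
             "{resseq:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
             "          {element:>2}\n")


def _format_atom_name(name: str) -> str:
    # PDB convention: element right-justified in cols 13-14 for 1-letter elements
    return f" {name:<3}" if len(name) < 4 else name


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write the structure as fixed-column PDB ATOM records (one model, TER per chain)."""
    path = Path(path)
    serial = 0
    with open(path, "w") as fh:
        for chain in structure.chains:
            for res in chain.residues:
                for atom in res.atoms.values():
                    serial += 1
                    fh.write(_PDB_ATOM.format(
                        rec="ATOM", serial=serial,
                        name=_format_atom_name(atom.name), alt=atom.altloc or " ",
                        resname=ONE_TO_THREE[res.aaType], chain=chain.id[:1] or "A",
                        resseq=res.seqIndex, icode=res.insertionCode or " ",
                        x=atom.position[0], y=atom.position[1], z=atom.position[2],
                        occ=atom.occupancy, b=0.0, element=atom.element[:2],
                    ))
            fh.write("TER\n")
        fh.write("END\n")


def write_pqr(structure: ProteinStructure, path: str | Path) -> None:
    """Write a PQR file (whitespace-separated; charge and radius in the occ/B columns).

    Every atom must carry ``charge`` and ``radius``; use
    :func:`escapist.electrostatics.assign_charges_radii` first.
    """
    path = Path(path)
    serial = 0
    with open(path, "w") as fh:
        for chain in structure.chains:
            for res in chain.residues:
                for atom in res.atoms.values():
                    if atom.charge is None or atom.radius is None:
                        raise ValueError(
                            f"atom {atom.name} of {res.aaType}{res.seqIndex} has no charge/radius")
                    serial += 1
                    fh.write(
                        f"ATOM  {serial:>5} {atom.name:<4} {ONE_TO_THREE[res.aaType]:<3} "
                        f"{chain.id[:1] or 'A'} {res.seqIndex:>4}    "
                        f"{atom.position[0]:>8.3f} {atom.position[1]:>8.3f} "
                        f"{atom.position[2]:>8.3f} {atom.charge:>8.4f} {atom.radius:>7.4f}\n")
            fh.write("TER\n")
        fh.write("END\n")
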