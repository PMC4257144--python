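"""Per-atom electrostatic potentials in kT/e.

Two built-in backends cover testing and desk-scale use without external binaries:

* ``coulomb`` -- uniform-dielectric (screened-)Coulomb sums.  Exact closed form, fast,
  and linear in the charges; the default for learning and scoring synthetic structures.
* ``fd`` -- a finite-difference Poisson(-Boltzmann) solver on a regular grid with a
  two-dielectric boundary (solute dielectric inside the probe-inflated van der Waals
  envelope, solvent dielectric outside), Dirichlet boundary values from the analytic
  solvent-dielectric Coulomb field, solved with conjugate gradients.  At zero ionic
  strength the linearized Poisson-Boltzmann equation reduces to the pure Poisson
  equation, so the linear solve is exact physics for the default parameters.

An adapter to the external PDB2PQR + APBS toolchain is provided as the reference
backend; it writes APBS input with the standard continuum parameters (solute dielectric
2, solvent dielectric 78, probe 1.4 A, 298 K, zero salt) and reads the OpenDX grid that
APBS emits.

All potentials are dimensionless kT/e at the configured temperature.  The conversion
constant is the Bjerrum-type length e^2/(4 pi eps0 kT) ~ 560.74 A at 298 K, so a unit
charge in a uniform dielectric eps gives phi(r) = 560.74 / (eps * r) kT/e.
"""

from __future__ import annotations

import copy
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import numpy as np
from scipy import constants, sparse
from scipy.sparse.linalg import cg

from escapist.structure_io import ProteinStructure, Residue, AtomRecord, write_pqr

__all__ = [
    "ChargedStructure",
    "SolverParams",
    "PotentialField",
    "AtomPotentials",
    "assign_charges_radii",
    "solve_potential",
    "potential_at",
    "atom_potentials",
    "run_external_backend",
    "read_opendx",
    "write_apbs_input",
    "coulomb_constant_angstrom",
    "kt_over_e_to_millivolts",
    "millivolts_to_kt_over_e",
    "UnmappedAtomError",
    "MissingExecutableError",
    "BackendError",
    "ConvergenceError",
    "OutOfBoundsError",
]


class UnmappedAtomError(KeyError):
    """An atom has no entry in the bundled charge/radius table."""


class MissingExecutableError(RuntimeError):
    """An external backend binary was not found on PATH or in the configuration."""


class BackendError(RuntimeError):
    """The external backend exited with an error; stderr is included in the message."""


class ConvergenceError(RuntimeError):
    """The iterative solver failed to reach the residual tolerance."""


class OutOfBoundsError(ValueError):
    """A query position lies outside the potential grid."""


def coulomb_constant_angstrom(temperature: float = 298.0) -> float:
    """e^2 / (4 pi eps0 kT) in Angstrom: phi(kT/e) = C * q / (eps * r[A])."""
    e = constants.elementary_charge
    kT = constants.Boltzmann * temperature
    return e * e / (4.0 * math.pi * constants.epsilon_0 * kT) * 1e10


def kt_over_e_to_millivolts(phi: float | np.ndarray, temperature: float = 298.0):
    """kT/e -> mV; the inverse of :func:`millivolts_to_kt_over_e` to machine precision."""
    kT_over_e_volts = constants.Boltzmann * temperature / constants.elementary_charge
    return phi * kT_over_e_volts * 1e3


def millivolts_to_kt_over_e(mv: float | np.ndarray, temperature: float = 298.0):
    kT_over_e_volts = constants.Boltzmann * temperature / constants.elementary_charge
    return mv / (kT_over_e_volts * 1e3)


# ---------------------------------------------------------------------------
# Charge / radius assignment
# ---------------------------------------------------------------------------

# Coarse single-bead sidechain model for the heavy-atom backbone + C-beta representation:
# the amide unit carries a fixed dipole, the carbonyl another, and each residue type puts
# a polarity-dependent partial charge on C-beta (compensated on C-alpha so every neutral
# residue sums to exactly 0 e); formal charges of D/E/K/R sit on C-beta.  Values are a
# deliberately simple, chemically-ordered stand-in for a full forcefield assignment --
# adequate for the statistics, not for energetics.
_BACKBONE_CHARGE = {"N": -0.45, "CA": 0.25, "C": 0.55, "O": -0.55}
_CB_BASE = 0.20
_SIDECHAIN_DELTA = {
    "A": 0.00, "C": -0.12, "D": -0.25, "E": -0.22, "F": 0.04,
    "H": 0.10, "I": 0.00, "K": 0.08, "L": 0.00, "M": 0.04,
    "N": -0.28, "P": 0.02, "Q": -0.26, "R": 0.12, "S": -0.20,
    "T": -0.18, "V": 0.00, "W": 0.08, "Y": -0.14,
}
_FORMAL_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0}
_ELEMENT_RADIUS = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
# recognizable standard sidechain heavy-atom names (CG, CD1, OD1, NE2, SG, ...) get zero
# charge and an element radius so full-atom files remain scorable with the bead model
import re as _re

_SIDECHAIN_NAME = _re.compile(r"^[CNOS][BGDEZH][0-9]?$|^[CNOS]H[0-9]$|^OXT$")


def _bead_charge_radius(res: Residue, atom: AtomRecord) -> tuple[float, float]:
    name = atom.name
    if name.startswith("H") or atom.element == "H":
        return 0.0, _ELEMENT_RADIUS["H"]
    if name == "CB":
        q = _CB_BASE + _SIDECHAIN_DELTA[res.aaType] + _FORMAL_CHARGE.get(res.aaType, 0.0)
        return q, _ELEMENT_RADIUS["C"]
    if name in _BACKBONE_CHARGE:
        q = _BACKBONE_CHARGE[name]
        if name == "CA":
            if res.aaType == "G":
                q = _BACKBONE_CHARGE["CA"] + _CB_BASE  # glycine has no CB to carry it
            else:
                q = _BACKBONE_CHARGE["CA"] - _SIDECHAIN_DELTA[res.aaType]
        radius = _ELEMENT_RADIUS.get(atom.element, _ELEMENT_RADIUS["C"])
        return q, radius
    if _SIDECHAIN_NAME.match(name) and atom.element in _ELEMENT_RADIUS:
        return 0.0, _ELEMENT_RADIUS[atom.element]
    raise UnmappedAtomError(
        f"atom {name!r} ({res.aaType}{res.seqIndex}, chain {res.chainId}) has no entry "
        f"in the bundled charge/radius table")


@dataclass
class ChargedStructure:
    """A structure whose atoms all carry a partial charge (e) and radius (A)."""

    structure: ProteinStructure
    forcefieldName: str = "bead"

    def iter_atoms(self):
        for res in self.structure.iter_residues():
            for atom in res.atoms.values():
                yield res, atom

    def residue_net_charges(self) -> dict[tuple[str, int], float]:
        out: dict[tuple[str, int], float] = {}
        for res in self.structure.iter_residues():
            out[(res.chainId, res.seqIndex)] = sum(
                a.charge or 0.0 for a in res.atoms.values())
        return out

    def total_charge(self) -> float:
        return sum(a.charge or 0.0 for _, a in self.iter_atoms())

    def validate(self, tol: float = 1e-3) -> None:
        for res, atom in self.iter_atoms():
            if atom.charge is None or not math.isfinite(atom.charge):
                raise ValueError(f"atom {atom.name} of residue {res.seqIndex} has no charge")
            if atom.radius is None or atom.radius <= 0:
                raise ValueError(f"atom {atom.name} of residue {res.seqIndex} has no radius")
        for (chain, seq), q in self.residue_net_charges().items():
            if abs(q - round(q)) > tol:
                raise ValueError(
                    f"residue {chain}/{seq} net charge {q:.4f} is not integral")


def assign_charges_radii(
    structure: ProteinStructure, forcefieldName: str = "bead"
) -> ChargedStructure:
    """Attach partial charges and radii to every atom.

    ``forcefieldName`` of ``"bead"`` (default) uses the bundled coarse table; any other
    name requires an external PDB2PQR executable named in the configuration (raises
    :class:`MissingExecutableError` when absent).  If the atoms already carry charges
    (e.g. parsed from a PQR file) they are kept untouched and only validated.
    """
    charged = ChargedStructure(structure=copy.deepcopy(structure),
                               forcefieldName=forcefieldName)
    already = all(a.charge is not None and a.radius is not None
                  for _, a in charged.iter_atoms())
    if already:
        charged.forcefieldName = "pqr-input"
        charged.validate()
        return charged
    if forcefieldName != "bead":
        exe = shutil.which("pdb2pqr") or shutil.which("pdb2pqr30")
        if exe is None:
            raise MissingExecutableError(
                "pdb2pqr executable not found on PATH (config key: executables.pdb2pqr); "
                f"cannot assign forcefield {forcefieldName!r}")
        raise NotImplementedError("external PDB2PQR assignment requires scoring via PQR files")
    for res, atom in charged.iter_atoms():
        atom.charge, atom.radius = _bead_charge_radius(res, atom)
    charged.validate()
    return charged


# ---------------------------------------------------------------------------
# Solver parameters and grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverParams:
    """Continuum-electrostatics settings.

    Defaults are the standard protein continuum setup: solute dielectric 2, solvent
    dielectric 78, probe radius 1.4 A, 298 K, zero ionic strength.  ``method`` selects
    the built-in backend mode: analytic uniform-dielectric Coulomb sums (``"coulomb"``,
    using the solvent dielectric throughout) or the two-dielectric finite-difference
    grid solver (``"fd"``).
    """

    soluteDielectric: float = 2.0
    solventDielectric: float = 78.0
    probeRadius: float = 1.4
    temperature: float = 298.0
    ionicStrength: float = 0.0
    gridSpacing: float = 0.5
    paddingFactor: float = 1.7
    method: Literal["coulomb", "fd"] = "coulomb"
    maxIterations: int = 10000
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.soluteDielectric < 1 or self.solventDielectric < 1:
            raise ValueError("dielectric constants must be >= 1")
        if self.gridSpacing <= 0:
            raise ValueError("gridSpacing must be > 0")
        if self.ionicStrength < 0:
            raise ValueError("ionicStrength must be >= 0")

    def kappa_sq(self) -> float:
        """Debye screening parameter squared, A^-2 (0 at zero ionic strength)."""
        if self.ionicStrength == 0.0:
            return 0.0
        lam_b = coulomb_constant_angstrom(self.temperature) / self.solventDielectric
        n_per_A3 = self.ionicStrength * constants.Avogadro * 1e-27
        return 8.0 * math.pi * lam_b * n_per_A3


@dataclass
class PotentialField:
    """Electrostatic potential on a regular grid, kT/e."""

    origin: np.ndarray          # (3,) A
    spacing: np.ndarray         # (3,) A
    values: np.ndarray          # (nx, ny, nz) kT/e
    units: str = "kT/e"

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def node_position(self, i: int, j: int, k: int) -> np.ndarray:
        return self.origin + self.spacing * np.array([i, j, k], dtype=float)


@dataclass
class AtomPotentials:
    """Potential value at named atoms, keyed by (chainId, seqIndex, atomName)."""

    values: dict[tuple[str, int, str], float]
    backendName: str

    def get(self, chainId: str, seqIndex: int, atomName: str) -> float | None:
        return self.values.get((chainId, seqIndex, atomName))


# ---------------------------------------------------------------------------
# Built-in backends
# ---------------------------------------------------------------------------

_MIN_SEPARATION = 1e-3  # A; guards the Coulomb sum against exactly coincident atoms


def _charge_arrays(charged: ChargedStructure):
    pos, q, keys = [], [], []
    for res, atom in charged.iter_atoms():
        pos.append(atom.position)
        q.append(atom.charge)
        keys.append((res.chainId, res.seqIndex, atom.name))
    return np.asarray(pos, dtype=float), np.asarray(q, dtype=float), keys


def _coulomb_at(points: np.ndarray, pos: np.ndarray, q: np.ndarray,
                params: SolverParams, exclude: list[int | None] | None = None) -> np.ndarray:
    """Uniform-dielectric screened-Coulomb potential at each point, kT/e.

    ``exclude[i]`` optionally names a source-charge index omitted from the sum for point
    i (the atom's own charge when reading the potential at an atom center).
    """
    C = coulomb_constant_angstrom(params.temperature) / params.solventDielectric
    kappa = math.sqrt(params.kappa_sq())
    d = np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=2)
    d = np.maximum(d, _MIN_SEPARATION)
    contrib = C * q[None, :] / d
    if kappa > 0:
        contrib = contrib * np.exp(-kappa * d)
    if exclude is not None:
        for i, j in enumerate(exclude):
            if j is not None:
                contrib[i, j] = 0.0
    return contrib.sum(axis=1)


def _grid_geometry(pos: np.ndarray, radii: np.ndarray, params: SolverParams):
    lo = (pos - radii[:, None]).min(axis=0)
    hi = (pos + radii[:, None]).max(axis=0)
    center = 0.5 * (lo + hi)
    extent = hi - lo
    # box: molecular extent scaled by the padding factor, with a floor so small test
    # systems still get room for the boundary condition to be accurate
    half = np.maximum(extent * params.paddingFactor / 2.0, extent / 2.0 + 8.0)
    h = params.gridSpacing
    n = np.maximum(np.ceil(2.0 * half / h).astype(int) + 1, 2)
    origin = center - (n - 1) * h / 2.0
    return origin, np.full(3, h), n


def _dielectric_map(origin, h, dims, pos, radii, params: SolverParams) -> np.ndarray:
    eps = np.full(tuple(dims), params.solventDielectric, dtype=float)
    if params.soluteDielectric == params.solventDielectric:
        return eps
    xs = origin[0] + h[0] * np.arange(dims[0])
    ys = origin[1] + h[1] * np.arange(dims[1])
    zs = origin[2] + h[2] * np.arange(dims[2])
    for p, r in zip(pos, radii):
        rr = r + params.probeRadius
        i0 = np.searchsorted(xs, p[0] - rr)
        i1 = np.searchsorted(xs, p[0] + rr, side="right")
        j0 = np.searchsorted(ys, p[1] - rr)
        j1 = np.searchsorted(ys, p[1] + rr, side="right")
        k0 = np.searchsorted(zs, p[2] - rr)
        k1 = np.searchsorted(zs, p[2] + rr, side="right")
        if i0 >= i1 or j0 >= j1 or k0 >= k1:
            continue
        X, Y, Z = np.meshgrid(xs[i0:i1], ys[j0:j1], zs[k0:k1], indexing="ij")
        inside = (X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2 <= rr * rr
        sub = eps[i0:i1, j0:j1, k0:k1]
        sub[inside] = params.soluteDielectric
    return eps


def _spread_charges(origin, h, dims, pos, q) -> np.ndarray:
    """Trilinear (cloud-in-cell) assignment of point charges to grid nodes."""
    rho = np.zeros(tuple(dims))
    t = (pos - origin) / h
    i0 = np.floor(t).astype(int)
    frac = t - i0
    for (ix, iy, iz), (fx, fy, fz), qq in zip(i0, frac, q):
        for dx in (0, 1):
            wx = fx if dx else 1.0 - fx
            for dy in (0, 1):
                wy = fy if dy else 1.0 - fy
                for dz in (0, 1):
                    wz = fz if dz else 1.0 - fz
                    rho[ix + dx, iy + dy, iz + dz] += qq * wx * wy * wz
    return rho


def solve_potential(charged: ChargedStructure, params: SolverParams) -> PotentialField:
    """Solve the linearized Poisson(-Boltzmann) equation on a regular grid.

    Charges are spread to the nearest nodes (cloud-in-cell); the dielectric map is the
    solute value inside the probe-inflated van der Waals envelope and the solvent value
    outside, with harmonic-mean face dielectrics in the 7-point stencil.  Boundary nodes
    take Dirichlet values from the analytic solvent-dielectric Coulomb field (exact for
    any charge distribution once the boundary is far enough from the solute).  The
    symmetric positive-definite system is solved by conjugate gradients.

    Returns the field in kT/e at ``params.temperature``.
    """
    charged.validate()
    pos, q, _ = _charge_arrays(charged)
    radii = np.array([a.radius for _, a in charged.iter_atoms()], dtype=float)
    origin, h, dims = _grid_geometry(pos, radii, params)
    nx, ny, nz = (int(v) for v in dims)
    hh = float(h[0])

    eps = _dielectric_map(origin, h, dims, pos, radii, params)
    rho = _spread_charges(origin, h, dims, pos, q)
    lam = coulomb_constant_angstrom(params.temperature)

    # Dirichlet boundary values from the analytic exterior field
    phi = np.zeros((nx, ny, nz))
    bmask = np.zeros((nx, ny, nz), dtype=bool)
    bmask[0, :, :] = bmask[-1, :, :] = True
    bmask[:, 0, :] = bmask[:, -1, :] = True
    bmask[:, :, 0] = bmask[:, :, -1] = True
    bidx = np.argwhere(bmask)
    bpts = origin + bidx * h
    phi[bmask] = _coulomb_at(bpts, pos, q, params)

    # assemble  sum_f eps_f (phi_n - phi_c) - kappa^2 h^2 eps phi_c = -4 pi lam q_c / h
    interior = ~bmask
    idx = -np.ones((nx, ny, nz), dtype=np.int64)
    n_unknown = int(interior.sum())
    idx[interior] = np.arange(n_unknown)

    kap2 = params.kappa_sq()
    diag = np.zeros(n_unknown)
    rhs = -4.0 * math.pi * lam * rho[interior] / hh
    if kap2 > 0.0:
        solvent = eps[interior] == params.solventDielectric
        diag -= kap2 * hh * hh * np.where(solvent, params.solventDielectric, 0.0)

    entries_r, entries_c, entries_v = [], [], []
    for axis, shift in (((1, 0, 0), None), ((0, 1, 0), None), ((0, 0, 1), None)):
        dx, dy, dz = axis
        # face dielectric between (i,j,k) and (i+dx, j+dy, k+dz): harmonic mean
        e1 = eps[: nx - dx or nx, : ny - dy or ny, : nz - dz or nz]
        e2 = eps[dx:, dy:, dz:]
        ef = 2.0 * e1 * e2 / (e1 + e2)
        # contributions of this face to both adjacent cells
        c_idx = idx[: nx - dx or nx, : ny - dy or ny, : nz - dz or nz]
        n_idx = idx[dx:, dy:, dz:]
        c_int = c_idx >= 0
        n_int = n_idx >= 0
        both = c_int & n_int
        # off-diagonal entries (symmetric)
        entries_r.append(c_idx[both])
        entries_c.append(n_idx[both])
        entries_v.append(ef[both])
        # diagonal accumulation: each face subtracts eps_f from its cell's diagonal
        np.subtract.at(diag, c_idx[c_int], ef[c_int])
        np.subtract.at(diag, n_idx[n_int], ef[n_int])
        # neighbour is a boundary node -> move the known value to the RHS
        cb = c_int & ~n_int
        phi_n = phi[dx:, dy:, dz:]
        np.subtract.at(rhs, c_idx[cb], ef[cb] * phi_n[cb])
        nb = n_int & ~c_int
        phi_c = phi[: nx - dx or nx, : ny - dy or ny, : nz - dz or nz]
        np.subtract.at(rhs, n_idx[nb], ef[nb] * phi_c[nb])

    r = np.concatenate([np.arange(n_unknown)] + entries_r + entries_c)
    c = np.concatenate([np.arange(n_unknown)] + entries_c + entries_r)
    v = np.concatenate([diag] + entries_v + entries_v)
    A = sparse.csr_matrix((v, (r, c)), shape=(n_unknown, n_unknown))

    # negate for positive definiteness
    M = sparse.diags(1.0 / (-A.diagonal()))
    x, info = cg(-A, -rhs, rtol=params.tolerance, maxiter=params.maxIterations, M=M)
    if info != 0:
        resid = float(np.linalg.norm(-A @ x + rhs))
        raise ConvergenceError(
            f"finite-difference solver did not converge in {params.maxIterations} "
            f"iterations (residual {resid:.3e})")
    phi[interior] = x
    return PotentialField(origin=origin, spacing=h, values=phi)


def potential_at(field: PotentialField, position) -> float:
    """Trilinear interpolation of the field at an arbitrary position (A)."""
    p = np.asarray(position, dtype=float)
    t = (p - field.origin) / field.spacing
    dims = np.array(field.dims)
    if np.any(t < -1e-9) or np.any(t > dims - 1 + 1e-9):
        raise OutOfBoundsError(f"position {position} outside grid (dims {tuple(dims)})")
    t = np.clip(t, 0.0, dims - 1)
    i0 = np.minimum(np.floor(t).astype(int), dims - 2)
    f = t - i0
    v = field.values
    ix, iy, iz = i0
    fx, fy, fz = f
    c00 = v[ix, iy, iz] * (1 - fx) + v[ix + 1, iy, iz] * fx
    c10 = v[ix, iy + 1, iz] * (1 - fx) + v[ix + 1, iy + 1, iz] * fx
    c01 = v[ix, iy, iz + 1] * (1 - fx) + v[ix + 1, iy, iz + 1] * fx
    c11 = v[ix, iy + 1, iz + 1] * (1 - fx) + v[ix + 1, iy + 1, iz + 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return float(c0 * (1 - fz) + c1 * fz)


_FEATURE_ATOMS = ("N", "CA", "C", "CB")


def atom_potentials(
    charged: ChargedStructure,
    params: SolverParams | None = None,
    backend: str | Callable[[ChargedStructure], AtomPotentials] = "builtin",
) -> AtomPotentials:
    """Potential at every N, C-alpha, C and C-beta atom, from one solve per structure.

    ``backend`` is ``"builtin"`` (mode chosen by ``params.method``), ``"external"``
    (PDB2PQR + APBS), or a callable mapping the charged structure to
    :class:`AtomPotentials` (useful for injecting synthetic potentials in simulations).
    In the built-in Coulomb mode the atom's own charge is excluded from the sum at its
    center (the self-term of a point charge is infinite and carries no information).
    """
    if params is None:
        params = SolverParams()
    if callable(backend):
        return backend(charged)
    if backend == "external":
        with tempfile.TemporaryDirectory() as td:
            pqr = Path(td) / "structure.pqr"
            write_pqr(charged.structure, pqr)
            atoms = _requested_atoms(charged)
            return run_external_backend(pqr, params, [k for k, _ in atoms])
    if backend != "builtin":
        raise ValueError(f"unknown backend {backend!r}")

    charged.validate()
    requested = _requested_atoms(charged)
    keys = [k for k, _ in requested]
    points = np.asarray([p for _, p in requested], dtype=float)
    if params.method == "coulomb":
        pos, q, all_keys = _charge_arrays(charged)
        key_to_idx = {k: i for i, k in enumerate(all_keys)}
        exclude = [key_to_idx.get(k) for k in keys]
        vals = _coulomb_at(points, pos, q, params, exclude=exclude)
        return AtomPotentials(values=dict(zip(keys, vals.tolist())),
                              backendName="builtin-coulomb")
    field = solve_potential(charged, params)
    vals = [potential_at(field, p) for p in points]
    return AtomPotentials(values=dict(zip(keys, vals)), backendName="builtin-fd")


def _requested_atoms(charged: ChargedStructure):
    out = []
    for res in charged.structure.iter_residues():
        for name in _FEATURE_ATOMS:
            atom = res.get_atom(name)
            if atom is not None:
                out.append(((res.chainId, res.seqIndex, name), atom.position))
    return out


# ---------------------------------------------------------------------------
# External APBS backend
# ---------------------------------------------------------------------------

_APBS_TEMPLATE = """\
read
    mol pqr {pqr}
end
elec
    mg-auto
    dime {dime_x} {dime_y} {dime_z}
    cglen {cg_x:.3f} {cg_y:.3f} {cg_z:.3f}
    fglen {fg_x:.3f} {fg_y:.3f} {fg_z:.3f}
    cgcent mol 1
    fgcent mol 1
    mol 1
    lpbe
    bcfl sdh
    pdie {pdie:.1f}
    sdie {sdie:.1f}
    srfm mol
    chgm spl2
    sdens 10.0
    srad {srad:.1f}
    swin 0.3
    temp {temp:.1f}
    calcenergy no
    calcforce no
    write pot dx {dx_out}
end
quit
"""


def write_apbs_input(pqr_path: Path, params: SolverParams, extent: np.ndarray,
                     dx_out: Path) -> str:
    """Render APBS input text with the standard continuum parameters."""
    fg = np.maximum(extent + 10.0, 20.0)
    cg = fg * params.paddingFactor
    dime = np.maximum(((fg / params.gridSpacing) // 32 + 1) * 32 + 1, 65).astype(int)
    return _APBS_TEMPLATE.format(
        pqr=pqr_path, dime_x=dime[0], dime_y=dime[1], dime_z=dime[2],
        cg_x=cg[0], cg_y=cg[1], cg_z=cg[2], fg_x=fg[0], fg_y=fg[1], fg_z=fg[2],
        pdie=params.soluteDielectric, sdie=params.solventDielectric,
        srad=params.probeRadius, temp=params.temperature, dx_out=dx_out,
    )


def read_opendx(path: str | Path) -> PotentialField:
    """Read an OpenDX regular scalar grid (the format APBS writes potentials in)."""
    path = Path(path)
    origin = spacing = None
    dims = None
    deltas = []
    data: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("object 1"):
                parts = s.split()
                dims = tuple(int(v) for v in parts[-3:])
            elif s.startswith("origin"):
                origin = np.array([float(v) for v in s.split()[1:4]])
            elif s.startswith("delta"):
                deltas.append([float(v) for v in s.split()[1:4]])
            elif s.startswith(("object", "attribute", "component", "end")):
                continue
            else:
                try:
                    data.extend(float(v) for v in s.split())
                except ValueError as exc:
                    raise ValueError(f"{path}: bad OpenDX data at line {lineno}") from exc
    if dims is None or origin is None or len(deltas) != 3:
        raise ValueError(f"{path}: incomplete OpenDX header")
    spacing = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    values = np.array(data).reshape(dims)  # dx data order: z fastest
    return PotentialField(origin=origin, spacing=spacing, values=values)


def run_external_backend(
    charged_path: str | Path,
    params: SolverParams,
    atoms: list[tuple[str, int, str]],
    apbs_executable: str | None = None,
) -> AtomPotentials:
    """Run APBS on a PQR file and interpolate the potential at the requested atoms.

    Raises :class:`MissingExecutableError` when the binary is absent (tests skip on this
    error rather than fail) and :class:`BackendError` on a nonzero exit, with no partial
    output files left behind.
    """
    from escapist.structure_io import parse_structure

    charged_path = Path(charged_path)
    exe = apbs_executable or shutil.which("apbs")
    if exe is None:
        raise MissingExecutableError(
            "apbs executable not found on PATH (config key: executables.apbs)")
    structure = parse_structure(charged_path)
    pos = np.array([a.position for r in structure.iter_residues()
                    for a in r.atoms.values()])
    extent = pos.max(axis=0) - pos.min(axis=0)
    with tempfile.TemporaryDirectory() as td:
        dx_out = Path(td) / "pot"
        in_file = Path(td) / "apbs.in"
        in_file.write_text(write_apbs_input(charged_path, params, extent, dx_out))
        proc = subprocess.run([exe, str(in_file)], capture_output=True, text=True,
                              cwd=td)
        if proc.returncode != 0:
            raise BackendError(f"apbs exited {proc.returncode}: {proc.stderr[-2000:]}")
        dx_files = sorted(Path(td).glob("pot*.dx"))
        if not dx_files:
            raise BackendError("apbs produced no OpenDX output")
        field = read_opendx(dx_files[0])
    lookup = {}
    for res in structure.iter_residues():
        for atom in res.atoms.values():
            lookup[(res.chainId, res.seqIndex, atom.name)] = atom.position
    version = subprocess.run([exe, "--version"], capture_output=True, text=True)
    name = f"apbs ({version.stdout.strip() or 'unknown version'})"
    values = {k: potential_at(field, lookup[k]) for k in atoms if k in lookup}
    return AtomPotentials(values=values, backendName=name)
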