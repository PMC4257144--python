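"""Charge assignment, the built-in solvers against closed-form oracles, and the
external-backend adapter contracts."""

import math
import shutil

import numpy as np
import pytest

from escapist.electrostatics import (
    MissingExecutableError,
    OutOfBoundsError,
    PotentialField,
    SolverParams,
    UnmappedAtomError,
    assign_charges_radii,
    atom_potentials,
    coulomb_constant_angstrom,
    kt_over_e_to_millivolts,
    millivolts_to_kt_over_e,
    potential_at,
    read_opendx,
    run_external_backend,
    solve_potential,
    write_apbs_input,
)
from escapist.fixtures import PeptideSpec, generate_peptide, synthetic_charge_system
from escapist.structure_io import parse_structure, write_pqr

UNIFORM = SolverParams(soluteDielectric=78.0, solventDielectric=78.0, method="fd")


class TestChargeAssignment:
    @pytest.mark.parametrize("aa,net", [("A", 0), ("D", -1), ("E", -1),
                                        ("K", 1), ("R", 1), ("G", 0), ("S", 0)])
    def test_residue_net_charges_are_formal(self, aa, net):
        pep = generate_peptide(PeptideSpec(sequence="A" + aa + "A"))
        charged = assign_charges_radii(pep)
        q = charged.residue_net_charges()[("A", 2)]
        assert abs(q - net) < 1e-3

    def test_total_charge_sums_formal_charges(self):
        pep = generate_peptide(PeptideSpec(sequence="DKEAR"))
        assert abs(assign_charges_radii(pep).total_charge() - 0.0) < 1e-3

    def test_unmapped_atom_is_named_in_error(self, polyala10):
        res = next(polyala10.iter_residues())
        bad = res.atoms["CA"]
        res.atoms["XX1"] = type(bad)(name="XX1", element="X",
                                     position=(0.0, 0.0, 0.0))
        with pytest.raises(UnmappedAtomError, match="XX1"):
            assign_charges_radii(polyala10)

    def test_pqr_roundtrip_preserves_charges(self, tmp_path):
        charged = assign_charges_radii(generate_peptide(PeptideSpec(sequence="ADKF")))
        path = tmp_path / "pep.pqr"
        write_pqr(charged.structure, path)
        back = assign_charges_radii(parse_structure(path))
        assert back.forcefieldName == "pqr-input"
        orig = {(r.seqIndex, a.name): (a.charge, a.radius)
                for r, a in charged.iter_atoms()}
        redo = {(r.seqIndex, a.name): (a.charge, a.radius)
                for r, a in back.iter_atoms()}
        assert orig.keys() == redo.keys()
        for k in orig:
            assert orig[k][0] == pytest.approx(redo[k][0], abs=1e-4)
            assert orig[k][1] == pytest.approx(redo[k][1], abs=1e-4)


class TestFiniteDifferenceSolver:
    def test_zero_charges_give_zero_field(self):
        system = synthetic_charge_system("point", q=0.0)
        field = solve_potential(system, UNIFORM)
        assert np.all(field.values == 0.0)

    def test_uniform_dielectric_matches_coulomb(self):
        system = synthetic_charge_system("point", q=1.0)
        field = solve_potential(system, UNIFORM)
        exact = coulomb_constant_angstrom(298.0) / (78.0 * 5.0)
        got = potential_at(field, (5.0, 0.0, 0.0))
        assert abs(got - exact) / exact < 0.05

    def test_born_ion_exterior_potential(self):
        system = synthetic_charge_system("born", q=1.0, radius=2.0)
        field = solve_potential(system, SolverParams(method="fd"))
        # outside a spherically symmetric dielectric cavity the field is pure
        # solvent-dielectric Coulomb, by Gauss's law
        exact = coulomb_constant_angstrom(298.0) / (78.0 * 4.0)
        got = potential_at(field, (4.0, 0.0, 0.0))
        assert abs(got - exact) / exact < 0.10

    def test_grid_refinement_stability(self):
        system = synthetic_charge_system("born", q=1.0, radius=2.0)
        coarse = solve_potential(system, SolverParams(method="fd", gridSpacing=0.5))
        fine = solve_potential(system, SolverParams(method="fd", gridSpacing=0.25))
        p = (4.0, 0.0, 0.0)
        a, b = potential_at(coarse, p), potential_at(fine, p)
        assert abs(a - b) / abs(b) < 0.05

    def test_dipole_antisymmetry(self):
        system = synthetic_charge_system("dipole", q=1.0, separation=6.0)
        field = solve_potential(system, UNIFORM)
        plus = potential_at(field, (-3.0, 0.0, 2.5))
        minus = potential_at(field, (3.0, 0.0, 2.5))
        assert plus == pytest.approx(-minus, rel=1e-6, abs=1e-9)


class TestTrilinearInterpolation:
    @staticmethod
    def linear_field(a=(1.0, -2.0, 0.5), n=6, h=1.0):
        grid = np.arange(n) * h
        X, Y, Z = np.meshgrid(grid, grid, grid, indexing="ij")
        values = a[0] * X + a[1] * Y + a[2] * Z
        return PotentialField(origin=np.zeros(3), spacing=np.full(3, h), values=values)

    def test_node_identity(self):
        f = self.linear_field()
        assert potential_at(f, (2.0, 3.0, 1.0)) == pytest.approx(
            f.values[2, 3, 1], abs=1e-12)

    def test_edge_midpoint_is_average(self):
        values = np.zeros((2, 2, 2))
        values[0, 0, 0], values[1, 0, 0] = 2.0, 4.0
        f = PotentialField(origin=np.zeros(3), spacing=np.ones(3), values=values)
        assert potential_at(f, (0.5, 0.0, 0.0)) == pytest.approx(3.0, abs=1e-12)

    def test_linear_fields_reproduced_exactly(self):
        f = self.linear_field(a=(0.7, -1.3, 2.9))
        rng = np.random.default_rng(0)
        for p in rng.uniform(0.0, 5.0, size=(50, 3)):
            expected = 0.7 * p[0] - 1.3 * p[1] + 2.9 * p[2]
            assert potential_at(f, p) == pytest.approx(expected, abs=1e-12)

    def test_out_of_bounds_raises(self):
        f = self.linear_field()
        with pytest.raises(OutOfBoundsError):
            potential_at(f, (10.0, 0.0, 0.0))


class TestCoulombBackendProperties:
    def test_linearity_of_charge_sets(self, polyala10):
        charged = assign_charges_radii(polyala10)
        params = SolverParams()
        full = atom_potentials(charged, params)

        import copy
        half_a, half_b = copy.deepcopy(charged), copy.deepcopy(charged)
        for i, (_, atom) in enumerate(half_a.iter_atoms()):
            if i % 2 == 0:
                atom.charge = 0.0
        for i, (_, atom) in enumerate(half_b.iter_atoms()):
            if i % 2 == 1:
                atom.charge = 0.0
        # split charge sets are not residue-integral, so compute them unvalidated
        pa = _potentials_no_validate(half_a, params)
        pb = _potentials_no_validate(half_b, params)
        for key, v in full.values.items():
            assert pa[key] + pb[key] == pytest.approx(v, abs=1e-9)

    def test_doubling_charges_doubles_potentials(self, polyala10):
        import copy
        charged = assign_charges_radii(polyala10)
        doubled = copy.deepcopy(charged)
        for _, atom in doubled.iter_atoms():
            atom.charge *= 2.0
        base = atom_potentials(charged, SolverParams())
        twice = _potentials_no_validate(doubled, SolverParams())
        for key, v in base.values.items():
            assert twice[key] == pytest.approx(2.0 * v, abs=1e-9)

    def test_rigid_rotation_invariance(self):
        pep = generate_peptide(PeptideSpec(sequence="ADKFE", jitter=0.1, seed=3))
        charged = assign_charges_radii(pep)
        base = atom_potentials(charged, SolverParams())

        import copy
        theta = 0.83
        R = np.array([[math.cos(theta), -math.sin(theta), 0.0],
                      [math.sin(theta), math.cos(theta), 0.0],
                      [0.0, 0.0, 1.0]])
        rotated = copy.deepcopy(charged)
        for _, atom in rotated.iter_atoms():
            atom.position = tuple((R @ np.asarray(atom.position)) + 5.0)
        rot = atom_potentials(rotated, SolverParams())
        for key, v in base.values.items():
            assert rot.values[key] == pytest.approx(v, abs=1e-6)

    def test_glycine_has_no_cb_entry(self):
        pep = generate_peptide(PeptideSpec(sequence="AGA"))
        pots = atom_potentials(assign_charges_radii(pep), SolverParams())
        assert pots.get("A", 2, "CB") is None
        assert pots.get("A", 1, "CB") is not None
        assert pots.get("A", 2, "CA") is not None

    def test_builtin_is_bit_reproducible(self, polyala10):
        charged = assign_charges_radii(polyala10)
        a = atom_potentials(charged, SolverParams())
        b = atom_potentials(charged, SolverParams())
        assert a.values == b.values


def _potentials_no_validate(charged, params):
    from escapist.electrostatics import _charge_arrays, _coulomb_at, _requested_atoms
    requested = _requested_atoms(charged)
    keys = [k for k, _ in requested]
    points = np.asarray([p for _, p in requested])
    pos, q, all_keys = _charge_arrays(charged)
    idx = {k: i for i, k in enumerate(all_keys)}
    vals = _coulomb_at(points, pos, q, params, exclude=[idx.get(k) for k in keys])
    return dict(zip(keys, vals.tolist()))


class TestUnits:
    def test_millivolt_roundtrip_is_identity(self):
        phi = np.array([-108.9, 0.0, 93.7, 420.0])
        back = millivolts_to_kt_over_e(kt_over_e_to_millivolts(phi))
        assert np.allclose(back, phi, atol=1e-12)

    def test_coulomb_constant_scale(self):
        # e^2/(4 pi eps0 kT) at 298 K is about 560.7 A
        assert coulomb_constant_angstrom(298.0) == pytest.approx(560.74, rel=1e-3)


class TestExternalBackend:
    def test_input_file_carries_methods_parameters(self, tmp_path):
        params = SolverParams()
        text = write_apbs_input(tmp_path / "x.pqr", params,
                                np.array([20.0, 20.0, 20.0]), tmp_path / "pot")
        assert "pdie 2.0" in text
        assert "sdie 78.0" in text
        assert "temp 298.0" in text
        assert "srad 1.4" in text
        assert "lpbe" in text

    def test_missing_executable_error(self, tmp_path):
        if shutil.which("apbs"):
            pytest.skip("apbs present; missing-executable path not exercisable")
        charged = assign_charges_radii(generate_peptide(PeptideSpec(sequence="ADA")))
        pqr = tmp_path / "pep.pqr"
        write_pqr(charged.structure, pqr)
        with pytest.raises(MissingExecutableError, match="apbs"):
            run_external_backend(pqr, SolverParams(), [("A", 1, "CA")])
        assert sorted(p.name for p in tmp_path.iterdir()) == ["pep.pqr"]

    def test_opendx_roundtrip_parsing(self, tmp_path):
        dx = (
            "# comment\n"
            "object 1 class gridpositions counts 2 2 2\n"
            "origin 0.0 0.0 0.0\n"
            "delta 0.5 0.0 0.0\n"
            "delta 0.0 0.5 0.0\n"
            "delta 0.0 0.0 0.5\n"
            "object 2 class gridconnections counts 2 2 2\n"
            "object 3 class array type double rank 0 items 8 data follows\n"
            "1.0 2.0 3.0\n4.0 5.0 6.0\n7.0 8.0\n"
            "attribute \"dep\" string \"positions\"\n")
        path = tmp_path / "pot.dx"
        path.write_text(dx)
        field = read_opendx(path)
        assert field.dims == (2, 2, 2)
        assert field.values[0, 0, 0] == 1.0
        assert field.values[0, 0, 1] == 2.0  # z varies fastest in OpenDX order
        assert field.values[1, 1, 1] == 8.0
        assert potential_at(field, (0.25, 0.0, 0.0)) == pytest.approx(3.0)
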