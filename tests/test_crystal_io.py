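"""Cell geometry, CIF round trips, bond perception and molecule extraction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyscape.crystal_io import (
    AtomSite,
    CrystalStructure,
    SymmetryOp,
    UnitCell,
    cell_volume,
    density,
    detect_zprime,
    extract_molecules,
    perceive_bonds,
    read_cif,
    write_cif,
    write_xyz,
)
from polyscape.errors import (
    CifFormatError,
    ConnectivityError,
    ElementError,
    SymmetryError,
)


class TestUnitCell:
    @pytest.mark.parametrize(
        "cell, expected",
        [
            (UnitCell(10, 10, 10), 1000.0),
            (UnitCell(5, 6, 7, 90, 90, 120), 181.8653),
        ],
    )
    def test_volume_closed_form(self, cell, expected):
        assert cell_volume(cell) == pytest.approx(expected, abs=1e-3)

    @given(
        st.floats(1.0, 50.0),
        st.floats(1.0, 50.0),
        st.floats(1.0, 50.0),
        st.floats(60.0, 120.0),
        st.floats(60.0, 120.0),
        st.floats(60.0, 120.0),
        st.floats(0.5, 3.0),
    )
    def test_volume_matches_lattice_determinant_and_scales(self, a, b, c, al, be, ga, k):
        try:
            cell = UnitCell(a, b, c, al, be, ga)
        except ValueError:
            return  # metrically impossible angle combination
        det = abs(np.linalg.det(cell.matrix()))
        assert cell_volume(cell) == pytest.approx(det, rel=1e-9)
        scaled = UnitCell(k * a, k * b, k * c, al, be, ga)
        assert cell_volume(scaled) == pytest.approx(k**3 * cell_volume(cell), rel=1e-9)

    @pytest.mark.parametrize("bad", [dict(a=-1, b=5, c=5), dict(a=5, b=5, c=5, alpha=0.0)])
    def test_invalid_cells_rejected(self, bad):
        with pytest.raises(ValueError):
            UnitCell(**{"a": 5, "b": 5, "c": 5, **bad})


class TestDensity:
    def test_roy_like_density(self):
        # Z=4, M=259.28 g/mol, V=1200 Å³ → ρ = Z·M/(0.602214·V)
        s = CrystalStructure(
            "d",
            UnitCell(10, 10, 12),
            [SymmetryOp.identity()],
            [AtomSite("C", (0, 0, 0), "C1")],
            z_total=4,
        )
        assert density(s, molar_mass=259.28) == pytest.approx(1.4351, abs=2e-4)

    def test_zero_molar_mass(self):
        s = CrystalStructure(
            "d", UnitCell(10, 10, 10), [SymmetryOp.identity()],
            [AtomSite("C", (0, 0, 0), "C1")], z_total=1,
        )
        assert density(s, molar_mass=0.0) == 0.0

    def test_intensive_under_cell_doubling(self, toy_p1):
        rho = density(toy_p1)
        big_cell = UnitCell(2 * toy_p1.cell.a, toy_p1.cell.b, toy_p1.cell.c)
        sites = [
            AtomSite(s.element, (s.frac[0] / 2 + dx, s.frac[1], s.frac[2]), f"{s.label}_{i}")
            for i, dx in enumerate((0.0, 0.5))
            for s in toy_p1.sites
        ]
        doubled = CrystalStructure("dbl", big_cell, [SymmetryOp.identity()], sites, z_total=2)
        assert density(doubled) == pytest.approx(rho, rel=1e-9)


MINIMAL_CIF = """data_one_carbon
_cell_length_a 10.0
_cell_length_b 10.0
_cell_length_c 10.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
_symmetry_space_group_name_H-M 'P 1'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 C 0.0 0.0 0.0
"""


class TestCif:
    def test_identity_case(self, tmp_path):
        p = tmp_path / "one.cif"
        p.write_text(MINIMAL_CIF)
        s = read_cif(p)
        assert len(s.ops) == 1 and s.ops[0].is_identity()
        assert len(s.sites) == 1 and s.sites[0].element == "C"

    def test_hm_symbol_resolves_p21(self, tmp_path):
        p = tmp_path / "p21.cif"
        p.write_text(MINIMAL_CIF.replace("'P 1'", "'P 21'"))
        s = read_cif(p)
        assert len(s.ops) == 2

    def test_explicit_ops_take_precedence(self, tmp_path):
        text = MINIMAL_CIF.replace(
            "_symmetry_space_group_name_H-M 'P 1'",
            "_symmetry_space_group_name_H-M 'P 21'\n"
            "loop_\n_symmetry_equiv_pos_as_xyz\nx,y,z\n",
        )
        p = tmp_path / "mixed.cif"
        p.write_text(text)
        assert len(read_cif(p).ops) == 1

    def test_round_trip_lossless(self, toy_p21, tmp_path):
        p = tmp_path / "rt.cif"
        write_cif(toy_p21, p)
        back = read_cif(p)
        assert back.id == toy_p21.id
        assert len(back.ops) == 2 and back.z_total == 2
        f0 = np.array([s.frac for s in toy_p21.sites])
        f1 = np.array([s.frac for s in back.sites])
        assert np.max(np.abs(f0 - f1)) < 1e-6
        for attr in ("a", "b", "c", "alpha", "beta", "gamma"):
            assert getattr(back.cell, attr) == pytest.approx(
                getattr(toy_p21.cell, attr), abs=1e-4
            )
        # both molecules recoverable after re-read
        assert len(extract_molecules(back)) == 2

    @pytest.mark.parametrize(
        "mutation, exc",
        [
            (lambda t: t.replace("_cell_length_a 10.0\n", ""), CifFormatError),
            (lambda t: t.replace("_symmetry_space_group_name_H-M 'P 1'\n", ""), SymmetryError),
            (lambda t: t.replace("C1 C", "C1 Qq"), ElementError),
        ],
    )
    def test_malformed_cifs(self, tmp_path, mutation, exc):
        p = tmp_path / "bad.cif"
        p.write_text(mutation(MINIMAL_CIF))
        with pytest.raises(exc):
            read_cif(p)

    def test_partial_occupancy_rejected(self, tmp_path):
        text = MINIMAL_CIF.replace(
            "_atom_site_fract_z\nC1 C 0.0 0.0 0.0",
            "_atom_site_fract_z\n_atom_site_occupancy\nC1 C 0.0 0.0 0.0 0.5",
        )
        p = tmp_path / "occ.cif"
        p.write_text(text)
        with pytest.raises(CifFormatError):
            read_cif(p)

    def test_write_empty_structure_rejected(self, tmp_path):
        s = CrystalStructure(
            "empty", UnitCell(10, 10, 10), [SymmetryOp.identity()], [], z_total=None
        )
        with pytest.raises(CifFormatError):
            write_cif(s, tmp_path / "empty.cif")

    def test_xyz_export(self, toy_p1, tmp_path):
        p = tmp_path / "toy.xyz"
        write_xyz(toy_p1, p)
        lines = p.read_text().splitlines()
        assert int(lines[0]) == 10 and len(lines) == 12


class TestBondsAndMolecules:
    def test_bond_cutoffs(self):
        cell = UnitCell(20, 20, 20)
        coords = np.array([[5.0, 5, 5], [6.5, 5, 5], [9.5, 5, 5]])
        bonds = perceive_bonds(coords, ["C", "C", "C"], cell)
        assert (0, 1) in bonds  # 1.50 Å
        assert (1, 2) not in bonds  # 3.0 Å

    def test_bond_across_periodic_boundary(self):
        cell = UnitCell(10, 10, 10)
        coords = np.array([[0.2, 5, 5], [9.11, 5, 5]])  # 1.09 Å via minimum image
        bonds = perceive_bonds(coords, ["C", "H"], cell)
        assert bonds == [(0, 1)]

    def test_disjoint_diatomics(self):
        cell = UnitCell(12, 12, 12)
        sites = [
            AtomSite("C", (0.1, 0.1, 0.1), "C1"),
            AtomSite("O", (0.1, 0.1, 0.2), "O1"),
            AtomSite("C", (0.6, 0.6, 0.6), "C2"),
            AtomSite("O", (0.6, 0.6, 0.7), "O2"),
        ]
        s = CrystalStructure("di", cell, [SymmetryOp.identity()], sites, z_total=2)
        mols = extract_molecules(s)
        assert [len(m.elements) for m in mols] == [2, 2]

    def test_unwrap_across_boundary(self, toy_p1):
        # shift the molecule so it straddles the cell boundary, then re-extract
        shifted = CrystalStructure(
            "shifted",
            toy_p1.cell,
            list(toy_p1.ops),
            [
                AtomSite(s.element, tuple(np.array(s.frac) + 0.45), s.label)
                for s in toy_p1.sites
            ],
            z_total=1,
        )
        (mol,) = extract_molecules(shifted)
        for i, j in mol.bonds:
            assert np.linalg.norm(mol.coords[i] - mol.coords[j]) < 2.0

    def test_z_total_mismatch_raises(self, toy_p1):
        wrong = CrystalStructure(
            "wrong", toy_p1.cell, list(toy_p1.ops), list(toy_p1.sites), z_total=3
        )
        with pytest.raises(ConnectivityError):
            extract_molecules(wrong)

    def test_supercell_extraction_consistency(self, toy_p1):
        (mol,) = extract_molecules(toy_p1)
        sites = [
            AtomSite(
                s.element,
                tuple((np.array(s.frac) + shift) / 2.0),
                f"{s.label}_{k}",
            )
            for k, shift in enumerate(
                np.array([[i, j, l] for i in range(2) for j in range(2) for l in range(2)])
            )
            for s in toy_p1.sites
        ]
        big = CrystalStructure(
            "sc",
            UnitCell(2 * toy_p1.cell.a, 2 * toy_p1.cell.b, 2 * toy_p1.cell.c),
            [SymmetryOp.identity()],
            sites,
            z_total=8,
        )
        mols = extract_molecules(big)
        assert len(mols) == 8
        # every copy congruent to the unit-cell molecule (identical distance sets)
        ref = np.sort(np.linalg.norm(mol.coords[:, None] - mol.coords[None, :], axis=-1), axis=None)
        for m in mols:
            d = np.sort(np.linalg.norm(m.coords[:, None] - m.coords[None, :], axis=-1), axis=None)
            assert np.allclose(d, ref, atol=1e-8)
        assert density(big) == pytest.approx(density(toy_p1), rel=1e-9)


class TestZPrime:
    def test_p1_single_molecule(self, toy_p1):
        assert detect_zprime(toy_p1) == (1, 1)

    def test_p21_z1(self, toy_p21):
        assert detect_zprime(toy_p21) == (2, 1)

    def test_two_distinct_molecules_in_p1(self, toy_p1):
        sites = [AtomSite(s.element, s.frac, s.label) for s in toy_p1.sites] + [
            AtomSite(s.element, tuple((np.array(s.frac) + 0.5) % 1.0), s.label + "b")
            for s in toy_p1.sites
        ]
        s = CrystalStructure("z2", toy_p1.cell, [SymmetryOp.identity()], sites, z_total=2)
        assert detect_zprime(s) == (2, 2)


class TestSymmetryOp:
    def test_determinant_validation(self):
        with pytest.raises(SymmetryError):
            SymmetryOp(((2, 0, 0), (0, 1, 0), (0, 0, 1)), (0, 0, 0))

    def test_xyz_round_trip(self):
        op = SymmetryOp.from_xyz("-x,y+1/2,-z")
        assert SymmetryOp.from_xyz(op.to_xyz()) == op

    def test_identity_moved_first(self):
        cell = UnitCell(10, 10, 10)
        ops = [SymmetryOp.from_xyz("-x,y+1/2,-z"), SymmetryOp.identity()]
        s = CrystalStructure("o", cell, ops, [AtomSite("C", (0.1, 0.1, 0.1), "C1")])
        assert s.ops[0].is_identity()
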