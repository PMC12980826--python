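"""Geometry stack: PDB parsing, assembly expansion, neighborhoods,
Shrake–Rupley SASA and outer-shell category sums."""

import math
import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from aavsorb.capsid_surface import (
    Atom,
    CapsidAssembly,
    ParseError,
    RigidTransform,
    Structure,
    acidic_basic_correlation,
    classify_residue,
    compute_sasa,
    expand_assembly,
    golden_spiral_points,
    outer_sidechain_sasa,
    outer_surface_descriptor,
    read_structure,
    read_transform_file,
    select_neighborhood,
    write_transform_file,
)
from aavsorb.synthetic_data import make_sphere_cluster

MINIMAL_PDB = """REMARK 350 BIOMOLECULE: 1
REMARK 350 APPLY THE FOLLOWING TO CHAINS: A
REMARK 350   BIOMT1   1  1.000000  0.000000  0.000000        0.00000
REMARK 350   BIOMT2   1  0.000000  1.000000  0.000000        0.00000
REMARK 350   BIOMT3   1  0.000000  0.000000  1.000000        0.00000
ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_single_atom_identity_transform(self):
        st = read_structure(MINIMAL_PDB)
        assert len(st.atoms) == 1
        assert len(st.transforms) == 1
        assert st.transforms[0].is_identity()
        np.testing.assert_allclose(st.atoms[0].coords, [1.0, 2.0, 3.0])
        assert st.atoms[0].vdw_radius == pytest.approx(1.70)  # carbon

    def test_backbone_flag(self):
        st = read_structure(MINIMAL_PDB)
        assert st.atoms[0].name == "CA"
        assert not st.atoms[0].is_sidechain

    def test_no_coordinates_raises(self):
        with pytest.raises(ParseError, match="coordinates"):
            read_structure("REMARK 350 BIOMOLECULE: 1\nEND\n")

    def test_missing_transforms_tells_caller(self):
        text = "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\nEND\n"
        with pytest.raises(ParseError, match="pass transforms"):
            read_structure(text)
        st = read_structure(text, transforms=[RigidTransform.identity()])
        assert len(st.transforms) == 1

    def test_toy_capsid_roundtrip(self, toy_capsid):
        """Writing then reading a generated structure reproduces
        coordinates to PDB precision (1e-3 Å) and all transforms."""
        st = read_structure(toy_capsid.pdb_text)
        orig = toy_capsid.structure.coords_array()
        np.testing.assert_allclose(st.coords_array(), orig, atol=1e-3)
        assert len(st.transforms) == len(toy_capsid.structure.transforms)
        for a, b in zip(st.transforms, toy_capsid.structure.transforms):
            np.testing.assert_allclose(a.rotation, b.rotation, atol=2e-6)

    def test_transform_file_roundtrip(self, toy_capsid):
        parsed = read_transform_file(toy_capsid.transform_text)
        for a, b in zip(parsed, toy_capsid.structure.transforms):
            np.testing.assert_allclose(a.rotation, b.rotation, atol=1e-8)
            np.testing.assert_allclose(a.translation, b.translation, atol=1e-8)
        assert write_transform_file(parsed) == toy_capsid.transform_text


def _atom(xyz, name="CB", res="ALA", rid=1, copy=0, r=1.7):
    return Atom(
        name=name, residue_name=res, residue_id=rid, chain_id="A",
        coords=np.asarray(xyz, dtype=float), vdw_radius=r,
        is_sidechain=name not in ("N", "CA", "C", "O", "OXT"), copy_index=copy,
    )


class TestExpandAssembly:
    def test_symmetry_pair(self):
        rot180 = np.diag([-1.0, -1.0, 1.0])
        st = Structure(
            atoms=[_atom([1, 0, 0])],
            transforms=[RigidTransform.identity(), RigidTransform(rot180, np.zeros(3))],
        )
        asm = expand_assembly(st)
        coords = asm.coords_array()
        np.testing.assert_allclose(coords, [[1, 0, 0], [-1, 0, 0]], atol=1e-12)
        np.testing.assert_allclose(asm.center, [0, 0, 0], atol=1e-12)

    def test_copy_counting(self, toy_capsid):
        asm = expand_assembly(toy_capsid.structure)
        n = len(toy_capsid.structure.atoms)
        assert len(asm.atoms) == n * toy_capsid.spec.n_copies
        assert asm.n_copies == toy_capsid.spec.n_copies

    def test_symmetric_shell_centroid_at_origin(self, toy_capsid):
        asm = expand_assembly(toy_capsid.structure)
        np.testing.assert_allclose(asm.center, [0, 0, 0], atol=1e-9)

    def test_non_orthonormal_rotation_rejected(self):
        bad = np.eye(3) * 1.1
        with pytest.raises(ValueError, match="orthonormal"):
            Structure(
                atoms=[_atom([0, 0, 0])],
                transforms=[RigidTransform.identity(), RigidTransform(bad, np.zeros(3))],
            )


class TestSelectNeighborhood:
    def _two_copy_assembly(self, separation):
        atoms = [_atom([0, 0, 0], copy=0), _atom([separation, 0, 0], copy=1)]
        return CapsidAssembly(atoms=atoms, center=np.zeros(3), n_copies=2)

    def test_beyond_cutoff_returns_reference_alone(self):
        asm = self._two_copy_assembly(100.0)
        with pytest.warns(UserWarning, match="no neighbor"):
            sel = select_neighborhood(asm, 0, contact_cutoff=6.0)
        assert [a.copy_index for a in sel] == [0]

    def test_within_cutoff_keeps_both(self):
        asm = self._two_copy_assembly(3.0)
        sel = select_neighborhood(asm, 0, contact_cutoff=6.0)
        assert sorted({a.copy_index for a in sel}) == [0, 1]

    def test_matches_brute_force_all_pairs(self, rng):
        """Neighbor copies equal a brute-force pairwise distance scan."""
        atoms = []
        for k in range(8):
            center = rng.uniform(-30, 30, 3)
            for i in range(6):
                atoms.append(_atom(center + rng.uniform(-3, 3, 3), rid=i + 1, copy=k))
        asm = CapsidAssembly(atoms=atoms, center=np.zeros(3), n_copies=8)
        cutoff = 9.0
        coords = asm.coords_array()
        copies = asm.copy_indices()
        ref = coords[copies == 0]
        expected = {0}
        for k in range(1, 8):
            other = coords[copies == k]
            dmin = min(
                np.linalg.norm(a - b) for a in ref for b in other
            )
            if dmin <= cutoff:
                expected.add(k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_neighborhood(asm, 0, contact_cutoff=cutoff)
        assert {a.copy_index for a in sel} == expected


class TestComputeSasa:
    def test_isolated_sphere_closed_form(self):
        area = compute_sasa(coords=np.zeros((1, 3)), radii=np.array([1.9]), probe_radius=1.4)
        assert area[0] == pytest.approx(4 * math.pi * 3.3**2, rel=0.005)

    def test_disjoint_pair_no_occlusion(self):
        atoms, analytic = make_sphere_cluster(
            np.array([[0.0, 0, 0], [10.0, 0, 0]]), np.array([1.7, 1.5])
        )
        np.testing.assert_allclose(compute_sasa(atoms), analytic, rtol=1e-12)

    def test_two_sphere_cap_closed_form(self):
        """Equal spheres r=1.7, probe 1.4, centers 2 Å apart: each loses a
        cap of height R − d/2 (R = 3.1)."""
        atoms, analytic = make_sphere_cluster(
            np.array([[0.0, 0, 0], [2.0, 0, 0]]), np.array([1.7, 1.7])
        )
        R = 3.1
        expected = 4 * math.pi * R**2 - 2 * math.pi * R * (R - 1.0)
        assert analytic == pytest.approx([expected, expected])
        np.testing.assert_allclose(compute_sasa(atoms), analytic, rtol=0.01)

    @pytest.mark.parametrize("d", [1.5, 2.5, 3.0, 4.0])
    def test_unequal_two_sphere_cap(self, d):
        atoms, analytic = make_sphere_cluster(
            np.array([[0.0, 0, 0], [d, 0, 0]]), np.array([1.7, 1.52])
        )
        np.testing.assert_allclose(compute_sasa(atoms), analytic, rtol=0.01)

    def test_coincident_atoms_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            compute_sasa(coords=np.zeros((2, 3)), radii=np.array([1.7, 1.7]))

    def test_input_validation(self):
        one = np.zeros((1, 3))
        with pytest.raises(ValueError):
            compute_sasa(coords=one, radii=np.array([1.7]), n_points=50)
        with pytest.raises(ValueError):
            compute_sasa(coords=one, radii=np.array([1.7]), probe_radius=-0.1)

    def test_occlusion_monotonicity(self):
        """Adding an atom never increases any existing atom's SASA
        (exact for the lab-frame point set); 100 random 5-atom clusters."""
        for trial in range(100):
            r = np.random.default_rng(trial)
            pos = r.uniform(-4, 4, (5, 3))
            rad = r.uniform(1.4, 1.9, 5)
            base = compute_sasa(coords=pos, radii=rad)
            extra = np.vstack([pos, r.uniform(-4, 4, 3)])
            erad = np.append(rad, r.uniform(1.4, 1.9))
            after = compute_sasa(coords=extra, radii=erad)
            assert (after[:5] <= base + 1e-12).all()

    def test_rigid_motion_invariance(self):
        """Canonical-frame alignment makes SASA invariant under rotation
        + translation of the whole cluster to fp precision."""
        for s in range(20):
            r = np.random.default_rng(s)
            n = int(r.integers(3, 8))
            pos = r.uniform(-4, 4, (n, 3))
            rad = r.uniform(1.4, 1.9, n)
            a1 = compute_sasa(coords=pos, radii=rad, align_frame=True)
            rot = Rotation.random(random_state=1000 + s).as_matrix()
            a2 = compute_sasa(coords=pos @ rot.T + r.uniform(-20, 20, 3),
                              radii=rad, align_frame=True)
            np.testing.assert_allclose(a2, a1, rtol=1e-6)

    def test_translation_invariance_lab_frame(self, rng):
        pos = rng.uniform(-4, 4, (6, 3))
        rad = rng.uniform(1.4, 1.9, 6)
        a1 = compute_sasa(coords=pos, radii=rad)
        a2 = compute_sasa(coords=pos + np.array([7.0, -3.0, 11.0]), radii=rad)
        np.testing.assert_allclose(a1, a2, rtol=1e-9)

    def test_biotite_cross_check(self):
        """Independent Shrake–Rupley implementation (biotite) agrees on a
        random cluster with matched radii to quadrature tolerance."""
        biotite_struc = pytest.importorskip("biotite.structure")
        r = np.random.default_rng(5)
        n = 8
        pos = r.uniform(-5, 5, (n, 3))
        rad = np.full(n, 1.7)
        arr = biotite_struc.AtomArray(n)
        arr.coord = pos.astype(np.float32)
        arr.set_annotation("element", np.array(["C"] * n))
        arr.set_annotation("atom_name", np.array(["CB"] * n))
        arr.set_annotation("res_name", np.array(["ALA"] * n))
        arr.set_annotation("res_id", np.arange(1, n + 1))
        arr.set_annotation("chain_id", np.array(["A"] * n))
        ref = biotite_struc.sasa(arr, probe_radius=1.4, point_number=2000, vdw_radii=rad)
        ours = compute_sasa(coords=pos, radii=rad, probe_radius=1.4, n_points=2000)
        np.testing.assert_allclose(ours, ref, rtol=0.02)

    def test_golden_spiral_unit_norm_and_coverage(self):
        pts = golden_spiral_points(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        # quasi-uniform: mean position near the origin
        assert np.linalg.norm(pts.mean(axis=0)) < 1e-3


class TestClassifyResidue:
    @pytest.mark.parametrize(
        "code,expected",
        [("PHE", "hydrophobic"), ("ILE", "hydrophobic"), ("LEU", "hydrophobic"),
         ("TYR", "hydrophobic"), ("TRP", "hydrophobic"), ("VAL", "hydrophobic"),
         ("MET", "hydrophobic"), ("PRO", "hydrophobic"), ("CYS", "hydrophobic"),
         ("ALA", "hydrophobic"), ("ASP", "acidic"), ("GLU", "acidic"),
         ("LYS", "basic"), ("ARG", "basic"), ("SER", "unclassified"),
         ("GLY", "unclassified"), ("HIS", "unclassified"), ("XYZ", "unclassified")],
    )
    def test_category_table(self, code, expected):
        assert classify_residue(code) == expected


class TestOuterSidechainSasa:
    def test_threshold_is_strict(self):
        """An atom exactly at the threshold radius is excluded ('more
        than 105 Å')."""
        atoms = [_atom([105.0, 0, 0], res="PHE"), _atom([106.0, 0, 0], res="PHE", rid=2)]
        sasa = np.array([10.0, 10.0])
        res = outer_sidechain_sasa(atoms, np.zeros(3), sasa, radial_threshold=105.0)
        assert res.sasa_hydrophobic == pytest.approx(10.0)
        assert res.n_atoms_outer == 1

    def test_single_term_sum(self):
        atoms = [_atom([106.0, 0, 0], res="LEU")]
        res = outer_sidechain_sasa(atoms, np.zeros(3), np.array([10.0]), 105.0)
        assert res.sasa_hydrophobic == pytest.approx(10.0)
        assert res.sasa_acidic == res.sasa_basic == 0.0

    def test_empty_outer_shell_warns(self):
        atoms = [_atom([10.0, 0, 0], res="LEU")]
        with pytest.warns(UserWarning, match="all sums are 0"):
            res = outer_sidechain_sasa(atoms, np.zeros(3), np.array([10.0]), 105.0)
        assert res.sasa_hydrophobic == 0.0

    def test_hydrophilic_is_acidic_plus_basic(self, toy_capsid):
        asm = expand_assembly(toy_capsid.structure)
        areas = compute_sasa(asm.atoms)
        res = outer_sidechain_sasa(asm.atoms, asm.center, areas, 105.0)
        assert res.sasa_hydrophilic == res.sasa_acidic + res.sasa_basic

    def test_matches_brute_force_tally(self, toy_capsid):
        """Category sums equal an independent per-atom tally over the
        generator's ground-truth table, and the included atom set equals
        a brute-force radial scan."""
        asm = expand_assembly(toy_capsid.structure)
        areas = compute_sasa(asm.atoms)
        threshold = 105.0
        res = outer_sidechain_sasa(asm.atoms, asm.center, areas, threshold)

        gt = toy_capsid.ground_truth.set_index("residue_id")
        tally = {"hydrophobic": 0.0, "acidic": 0.0, "basic": 0.0}
        n_outer = 0
        for atom, area in zip(asm.atoms, areas):
            if atom.copy_index != 0:
                continue
            if np.linalg.norm(atom.coords - asm.center) <= threshold:
                continue
            n_outer += 1
            cat = gt.loc[atom.residue_id, "category"]
            if cat in tally:
                tally[cat] += area
        assert res.n_atoms_outer == n_outer
        assert res.sasa_hydrophobic == pytest.approx(tally["hydrophobic"], abs=1e-9)
        assert res.sasa_acidic == pytest.approx(tally["acidic"], abs=1e-9)
        assert res.sasa_basic == pytest.approx(tally["basic"], abs=1e-9)

    def test_category_conservation(self, toy_capsid):
        """Categorized sums never exceed the total outer side-chain SASA
        of the reference copy (unclassified residues fill the gap)."""
        asm = expand_assembly(toy_capsid.structure)
        areas = compute_sasa(asm.atoms)
        res = outer_sidechain_sasa(asm.atoms, asm.center, areas, 105.0)
        total = sum(
            a
            for atom, a in zip(asm.atoms, areas)
            if atom.copy_index == 0
            and atom.is_sidechain
            and np.linalg.norm(atom.coords - asm.center) > 105.0
        )
        assert res.sasa_hydrophobic + res.sasa_acidic + res.sasa_basic <= total + 1e-9

    def test_toy_ground_truth_exact(self, toy_capsid):
        """Well-separated construction: category sums equal count ×
        isolated-sphere area."""
        res = outer_surface_descriptor(toy_capsid.structure, serotype="toy")
        exp = toy_capsid.expected_category_sums(105.0)
        assert res.sasa_hydrophobic == pytest.approx(exp["hydrophobic"], rel=1e-9)
        assert res.sasa_acidic == pytest.approx(exp["acidic"], rel=1e-9)
        assert res.sasa_basic == pytest.approx(exp["basic"], rel=1e-9)


class TestAcidicBasicCorrelation:
    def _desc(self, acidic, basic):
        from aavsorb.capsid_surface import OuterSASAResult

        return OuterSASAResult(
            serotype="x", sasa_hydrophobic=0.0, sasa_acidic=acidic,
            sasa_basic=basic, n_atoms_outer=1, radial_threshold=105.0,
            probe_radius=1.4,
        )

    def test_identical_vectors(self):
        descs = [self._desc(v, v) for v in (1.0, 2.0, 5.0, 9.0)]
        assert acidic_basic_correlation(descs) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        descs = [self._desc(v, 10.0 - v) for v in (1.0, 2.0, 5.0, 9.0)]
        assert acidic_basic_correlation(descs) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        a = rng.uniform(1, 10, 4)
        b = rng.uniform(1, 10, 4)
        descs = [self._desc(x, y) for x, y in zip(a, b)]
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std() * b.std())
        assert acidic_basic_correlation(descs) == pytest.approx(expected, abs=1e-12)

    def test_requires_three_and_variance(self):
        with pytest.raises(ValueError):
            acidic_basic_correlation([self._desc(1, 1), self._desc(2, 2)])
        with pytest.raises(ValueError, match="zero variance"):
            acidic_basic_correlation([self._desc(1, 1), self._desc(1, 2), self._desc(1, 3)])
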