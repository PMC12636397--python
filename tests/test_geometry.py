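"""Structure parsing, helix spacing, superposition, SASA and steric overlap."""

import math

import numpy as np
import pytest

from hdcoop import (
    SegmentDefinition,
    StructureModel,
    ca_distance_matrix,
    graft_spacing,
    ideal_helix,
    interhelix_comparison,
    kabsch_superpose,
    read_structure,
    shrake_rupley,
    steric_overlap,
)
from hdcoop.geometry import Atom, Residue, residue_sasa, sphere_points
from hdcoop.simulate import ideal_domain

# Minimal 3-residue single-chain fixtures, identical content in both formats.
PDB_FIXTURE = """\
ATOM      1  N   ALA A  10       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A  10       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A  11       1.000   3.000   4.000  1.00  0.00           C
ATOM      4  CA  SER A  12       4.000   3.000   4.000  1.00  0.00           C
END
"""

CIF_FIXTURE = """\
data_fixture
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.pdbx_formal_charge
_atom_site.auth_seq_id
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 N N . ALA Axp A 1 ? 0.000 0.000 0.000 1 0 ? 10 A 1
ATOM 2 C CA . ALA Axp A 1 ? 1.000 0.000 0.000 1 0 ? 10 A 1
ATOM 3 C CA . GLY Axp A 2 ? 1.000 3.000 4.000 1 0 ? 11 A 1
ATOM 4 C CA . SER Axp A 3 ? 4.000 3.000 4.000 1 0 ? 12 A 1
"""


def two_sphere_model(d, name_b=5):
    """Two single-atom 'residues' (carbon spheres) on different chains."""
    ra = Residue(1, "SPH", (Atom("X1", "C", (0.0, 0.0, 0.0)),))
    rb = Residue(name_b, "SPH", (Atom("X2", "C", (d, 0.0, 0.0)),))
    return StructureModel("pair", {"A": (ra,), "B": (rb,)})


class TestReadStructure:
    def test_minimal_pdb_round_trip(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(PDB_FIXTURE)
        model = read_structure(path, {"A": 10})
        residues = model.chain("A")
        assert [r.hd_position for r in residues] == [1, 2, 3]
        assert residues[0].ca.xyz == (1.0, 0.0, 0.0)
        assert residues[0].atom("N") is not None

    def test_missing_chain_error_names_available(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(PDB_FIXTURE)
        with pytest.raises(ValueError, match="available chains: A"):
            read_structure(path, {"B": 10})

    def test_pdb_and_mmcif_encodings_agree(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        cif = tmp_path / "mini.cif"
        pdb.write_text(PDB_FIXTURE)
        cif.write_text(CIF_FIXTURE)
        m_pdb = read_structure(pdb, {"A": 10}, model_id="m")
        m_cif = read_structure(cif, {"A": 10}, model_id="m")
        for r1, r2 in zip(m_pdb.chain("A"), m_cif.chain("A")):
            assert r1.hd_position == r2.hd_position
            assert np.allclose(r1.ca.xyz, r2.ca.xyz)

    def test_residues_outside_hd_window_are_dropped(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(PDB_FIXTURE)
        model = read_structure(path, {"A": -55})  # residues map to 66-68
        assert model.chain("A") == ()


class TestCaDistances:
    def test_three_four_five_triangle(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(PDB_FIXTURE)
        dm = ca_distance_matrix(read_structure(path, {"A": 10}), "A")
        assert dm.distance(1, 2) == pytest.approx(5.0)

    def test_ideal_helix_consecutive_spacing(self):
        dm = ca_distance_matrix(ideal_helix(18), "A")
        # chord of rise 1.5 A, twist 100 deg, radius 2.3 A
        expected = math.sqrt(1.5**2 + 2 * 2.3**2 * (1 - math.cos(math.radians(100))))
        for i in range(1, 18):
            assert dm.distance(i, i + 1) == pytest.approx(expected)
        assert expected == pytest.approx(3.83, abs=0.01)

    def test_two_turns_nearly_stack(self):
        dm = ca_distance_matrix(ideal_helix(18), "A")
        # i, i+7 spans ~700 deg (~2 turns): lateral offset is small
        lateral = math.sqrt(dm.distance(1, 8) ** 2 - (7 * 1.5) ** 2)
        assert lateral < 2.0

    def test_symmetry_and_zero_diagonal(self):
        dm = ca_distance_matrix(ideal_helix(10), "A")
        assert np.allclose(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0.0)


class TestKabsch:
    def test_identity_superposition(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-12)

    def test_recovers_exact_rigid_motion(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        theta = math.pi / 2
        rot = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = pts @ rot.T + np.array([1.0, -2.0, 3.0])
        R, t, rmsd = kabsch_superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, rot, atol=1e-10)

    def test_rmsd_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(8, 3))
        b = a + rng.normal(scale=0.3, size=(8, 3))
        _, _, rmsd0 = kabsch_superpose(a, b)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = 1.1
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        rot = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)
        _, _, rmsd1 = kabsch_superpose(a @ rot.T + 5.0, b @ rot.T + 5.0)
        assert rmsd1 == pytest.approx(rmsd0, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_no_reflection_for_chiral_point_sets(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        R, _, _ = kabsch_superpose(pts, mirrored)
        assert np.linalg.det(R) == pytest.approx(1.0)


class TestInterhelixComparison:
    def test_recovers_constructed_spacing_difference(self):
        narrow = [ideal_domain(model_id=f"pl{i}") for i in range(3)]
        wide = [ideal_domain(helix2_offset=11.0, model_id=f"an{i}") for i in range(3)]
        result = interhelix_comparison({"PairedLike": narrow, "ANTP": wide})
        h12 = result.summary[result.summary.combo == "helix1-helix2"]
        assert h12.mean_difference.mean() == pytest.approx(2.0, abs=0.3)

    def test_identical_structures_give_zero_difference_p_one(self):
        models = [ideal_domain(model_id=f"m{i}") for i in range(2)]
        result = interhelix_comparison({"PairedLike": models, "ANTP": models})
        assert np.allclose(result.summary.mean_difference, 0.0)
        assert np.allclose(result.summary.p, 1.0)

    def test_single_structure_per_family_is_flagged_underpowered(self):
        result = interhelix_comparison(
            {"PairedLike": [ideal_domain()], "ANTP": [ideal_domain(11.0)]}
        )
        assert result.summary.underpowered.all()
        assert result.summary.mean_difference.notna().all()

    def test_mirrored_family_labels_negate_the_difference(self):
        narrow = [ideal_domain(model_id=f"p{i}") for i in range(2)]
        wide = [ideal_domain(11.0, model_id=f"a{i}") for i in range(2)]
        fwd = interhelix_comparison({"PairedLike": narrow, "ANTP": wide})
        rev = interhelix_comparison({"ANTP": wide, "PairedLike": narrow})
        assert np.allclose(
            fwd.summary.mean_difference, -rev.summary.mean_difference
        )


class TestGraftSpacing:
    def test_identity_graft_is_a_no_op(self):
        model = ideal_domain()
        grafted, report = graft_spacing(model, model)
        for r_in, r_out in zip(model.chain("A"), grafted.chain("A")):
            assert np.allclose(r_in.ca.xyz, r_out.ca.xyz, atol=1e-9)
        assert all(r == pytest.approx(0.0, abs=1e-9) for r in report.values())

    def test_chimera_adopts_donor_helix_spacing(self):
        model = ideal_domain()
        donor = ideal_domain(helix2_offset=11.0, model_id="donor")
        grafted, report = graft_spacing(model, donor)
        dm_g = ca_distance_matrix(grafted, "A")
        dm_d = ca_distance_matrix(donor, "A")
        for a, b in ((12, 37), (15, 33), (19, 30), (22, 29)):
            assert dm_g.distance(a, b) == pytest.approx(dm_d.distance(a, b), abs=0.1)
        assert max(report.values()) < 1e-6  # identical segment shapes

    def test_missing_segment_is_an_error(self):
        model = ideal_domain()
        donor_res = tuple(
            r for r in ideal_domain(model_id="partial").chain("A")
            if not 26 <= r.hd_position <= 39
        )
        donor = StructureModel("partial", {"A": donor_res})
        with pytest.raises(ValueError, match="helix2"):
            graft_spacing(model, donor)


class TestSasaAndOverlap:
    def test_isolated_sphere_area_converges_to_closed_form(self):
        areas = shrake_rupley(np.zeros((1, 3)), np.array([1.7]), n_points=4000)
        exact = 4 * math.pi * (1.7 + 1.4) ** 2
        assert abs(areas[0] - exact) / exact < 0.01

    def test_sphere_points_are_unit_and_balanced(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01

    def test_distant_residues_do_not_overlap(self):
        ov = steric_overlap(two_sphere_model(25.0), ("A", 1), ("B", 5))
        assert abs(ov.overlap) < 1.0

    def test_coincident_copies_overlap_fully(self):
        ov = steric_overlap(two_sphere_model(0.0), ("A", 1), ("B", 5))
        exact = 4 * math.pi * (1.7 + 1.4) ** 2
        assert ov.overlap == pytest.approx(exact, rel=0.02)
        assert ov.overlap <= min(ov.area_a, ov.area_b) + 1e-6

    def test_two_sphere_overlap_matches_numerical_integration(self):
        # independent oracle: latitude-slice integration of the two buried caps
        R, d = 1.7 + 1.4, 2.0
        cos_cut = d / (2 * R)  # symmetric spheres: cap above the bisector plane
        mu = np.linspace(cos_cut, 1.0, 200_001)
        cap = 2 * math.pi * R**2 * np.trapezoid(np.ones_like(mu), mu)
        oracle = 2 * cap
        ov = steric_overlap(two_sphere_model(d), ("A", 1), ("B", 5), n_points=960)
        assert abs(ov.overlap - oracle) / oracle < 0.02

    def test_overlap_is_symmetric(self):
        model = two_sphere_model(2.5)
        ab = steric_overlap(model, ("A", 1), ("B", 5))
        ba = steric_overlap(model, ("B", 5), ("A", 1))
        assert ab.overlap == pytest.approx(ba.overlap, rel=1e-9)

    def test_bonded_pairs_are_rejected(self):
        ra = Residue(1, "ALA", (Atom("CA", "C", (0.0, 0.0, 0.0)),))
        rb = Residue(2, "ALA", (Atom("CA", "C", (3.8, 0.0, 0.0)),))
        model = StructureModel("chain", {"A": (ra, rb)})
        with pytest.raises(ValueError, match="bonded"):
            steric_overlap(model, ("A", 1), ("A", 2))

    def test_multi_atom_residue_sasa_excludes_buried_surface(self):
        r1 = Residue(1, "XX", (Atom("C1", "C", (0.0, 0.0, 0.0)),
                               Atom("C2", "C", (1.5, 0.0, 0.0))))
        isolated = residue_sasa([r1])
        two_spheres = 2 * 4 * math.pi * (1.7 + 1.4) ** 2
        assert isolated < two_spheres


class TestSegments:
    def test_default_segments_cover_the_domain(self):
        ranges = SegmentDefinition().ranges()
        assert ranges["arm"] == (1, 8)
        assert ranges["helix3"] == (40, 60)

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            SegmentDefinition(arm=(1, 9))
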