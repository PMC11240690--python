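"""Geometry builders, the packaged template, PDB I/O, and hit location."""

import math

import numpy as np
import pytest

from nanodna import geometry
from nanodna.geometry import (
    ATOMIC_RADII_NM,
    MoietyKey,
    build_high_res_bdna,
    build_simple_bdna,
    load_bp_template,
    load_bp_template_bonds,
    locate_hit,
    locate_hits,
    read_pdb,
    write_pdb,
)


class TestHighResBuilder:
    def test_canonical_model_counts(self, model41):
        assert model41.n_bp == 41
        assert model41.n_nucleotides == 82
        template = load_bp_template()
        assert len(model41.atoms) == 41 * len(template)

    def test_atom_radii_follow_element_table(self, model41):
        seen = {}
        for a in model41.atoms:
            assert a.radius == ATOMIC_RADII_NM[a.element]
            seen[a.element] = a.radius
        assert seen == {"H": 0.120, "C": 0.170, "N": 0.150, "O": 0.140, "P": 0.190}

    def test_single_bp_is_template_with_axial_shift(self):
        model = build_high_res_bdna(1)
        template = load_bp_template()
        got = np.array([a.position for a in model.atoms])
        want = template[["x_nm", "y_nm", "z_nm"]].to_numpy()
        want = want + [0.0, 0.0, 0.17]  # bp 1 centred at rise/2
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_consecutive_bp_related_by_rigid_step(self, model5):
        per_bp = len(load_bp_template())
        rot = np.array([
            [math.cos(math.radians(36)), -math.sin(math.radians(36)), 0],
            [math.sin(math.radians(36)), math.cos(math.radians(36)), 0],
            [0, 0, 1.0],
        ])
        for i in range(4):
            a = np.array([x.position for x in model5.atoms[i * per_bp:(i + 1) * per_bp]])
            b = np.array([x.position
                          for x in model5.atoms[(i + 1) * per_bp:(i + 2) * per_bp]])
            np.testing.assert_allclose(b, a @ rot.T + [0, 0, 0.34], atol=1e-9)

    def test_bond_lengths_preserved_and_near_references(self, model5):
        template = load_bp_template()
        bonds = load_bp_template_bonds()
        name_to_row = {n: i for i, n in enumerate(template["name"])}
        per_bp = len(template)
        # template bonds within 5% of the documented reference lengths
        pos0 = template[["x_nm", "y_nm", "z_nm"]].to_numpy()
        for b in bonds.itertuples(index=False):
            d = np.linalg.norm(pos0[name_to_row[b.atom_i]] - pos0[name_to_row[b.atom_j]])
            assert abs(d - b.ref_nm) / b.ref_nm < 0.05
        # rigid construction preserves them exactly in every repeat
        for bp in (0, 2, 4):
            atoms = model5.atoms[bp * per_bp:(bp + 1) * per_bp]
            pos = {a.name: a.position for a in atoms}
            for b in bonds.itertuples(index=False):
                d = np.linalg.norm(pos[b.atom_i] - pos[b.atom_j])
                d0 = np.linalg.norm(pos0[name_to_row[b.atom_i]]
                                    - pos0[name_to_row[b.atom_j]])
                assert abs(d - d0) < 1e-9

    def test_all_atoms_inside_bounding_cylinder(self, model41):
        cyl = model41.bounding_cylinder
        for a in model41.atoms:
            r = math.hypot(a.position[0], a.position[1])
            assert r + a.radius <= cyl.diameter / 2.0 + 1e-9
            assert cyl.z0 - 1e-9 <= a.position[2] - a.radius
            assert a.position[2] + a.radius <= cyl.z0 + cyl.height + 1e-9

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="n_bp"):
            build_high_res_bdna(0)
        template = load_bp_template()
        bad = template.copy()
        bad.loc[0, "element"] = "Xx"
        with pytest.raises(ValueError, match="Xx"):
            build_high_res_bdna(2, template=bad)


class TestSimpleBuilder:
    def test_stack_height_and_counts(self, simple42):
        assert len(simple42.segments) == 2 * 42
        top = max(s.z_center + s.thickness / 2 for s in simple42.segments)
        assert top == pytest.approx(42 * 0.34)  # 14.28 nm

    def test_single_bp_has_two_segments(self):
        assert len(build_simple_bdna(1).segments) == 2

    def test_phase_progression_follows_twist(self, simple42):
        labeled = [s for s in simple42.segments if s.strand == "labeled"]
        for i, seg in enumerate(labeled):
            assert seg.phase_angle == pytest.approx((i * 36.0) % 360.0)

    def test_rejects_nonpositive_diameter(self):
        with pytest.raises(ValueError, match="outer_diameter"):
            build_simple_bdna(5, outer_diameter=0.0)


class TestLocateHit:
    def test_atom_center_maps_to_its_moiety(self, model41):
        a = model41.atoms[123]
        hit = locate_hit(a.position, model41)
        assert hit.region == "target"
        assert hit.key == a.key

    def test_far_point_is_outside(self, model41):
        assert locate_hit([1e6, 1e6, 1e6], model41).region == "outside"

    def test_cylinder_only_point_gets_nearest_moiety(self, model41):
        # on the axis, between base pairs: inside the cylinder, outside atoms
        hit = locate_hit([0.0, 0.0, -0.1], model41)
        assert hit.region in ("cylinder", "target")
        assert hit.key is not None

    def test_matches_brute_force_scan(self, model41, rng):
        """KD-tree accelerated lookup agrees with an exhaustive all-atoms
        scan (nearest containing atom; ties by bp then labeled strand)."""
        pts = rng.uniform([-2, -2, -2], [2, 2, 16], size=(1000, 3))
        hits = locate_hits(pts, model41)
        pos = np.array([a.position for a in model41.atoms])
        radii = np.array([a.radius for a in model41.atoms])
        strand_rank = {"labeled": 0, "nonlabeled": 1}
        for p, hit in zip(pts, hits):
            d = np.linalg.norm(pos - p, axis=1)
            inside = np.flatnonzero(d <= radii)
            if inside.size:
                best = min(inside, key=lambda j: (
                    d[j], model41.atoms[j].bp_index,
                    strand_rank[model41.atoms[j].strand]))
                assert hit.region == "target"
                assert hit.key == model41.atoms[best].key
            elif model41.bounding_cylinder.contains(p[None, :])[0]:
                assert hit.region == "cylinder"
            else:
                assert hit.region == "outside"

    def test_simple_model_segment_lookup(self, simple42):
        seg = simple42.segments[0]  # bp 1, labeled, phase 0
        mid = math.radians(seg.phase_angle + 90.0)
        r = 0.5 * (seg.inner_radius + seg.outer_radius)
        p = [r * math.cos(mid), r * math.sin(mid), seg.z_center]
        hit = locate_hit(p, simple42)
        assert hit.region == "target"
        assert hit.key == MoietyKey(1, "labeled", "sugar_phosphate")


PDB_3ATOMS = """\
ATOM      1  P    DT A   1       1.000   2.000   3.000  1.00  0.00           P
ATOM      2  C1'  DT A   1       4.000   5.000   6.000  1.00  0.00           C
ATOM      3  N1   DT A   1       7.000   8.000   9.000  1.00  0.00           N
END
"""


class TestPDB:
    def test_three_atom_file_converts_angstrom_to_nm(self, tmp_path):
        path = tmp_path / "three.pdb"
        path.write_text(PDB_3ATOMS)
        result = read_pdb(path)
        assert len(result.atoms) == 3
        np.testing.assert_allclose(result.atoms[0].position, [0.1, 0.2, 0.3])

    def test_atom_name_convention_sets_moiety(self, tmp_path):
        path = tmp_path / "three.pdb"
        path.write_text(PDB_3ATOMS)
        result = read_pdb(path)
        by_name = {a.name: a for a in result.atoms}
        assert by_name["P"].moiety == "sugar_phosphate"
        assert by_name["C1'"].moiety == "sugar_phosphate"
        assert by_name["N1"].moiety == "base"

    def test_empty_file_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        assert read_pdb(path).atoms == []

    def test_unparseable_record_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  P    DT A   1       x.xxx   2.000   3.000\n")
        with pytest.raises(ValueError, match="line 1"):
            read_pdb(path)

    def test_unknown_element_skipped_and_counted(self, tmp_path):
        text = PDB_3ATOMS.replace(
            "ATOM      3  N1   DT A   1       7.000   8.000   9.000  1.00  0.00           N",
            "ATOM      3 FE    DT A   1       7.000   8.000   9.000  1.00  0.00          FE")
        path = tmp_path / "fe.pdb"
        path.write_text(text)
        with pytest.warns(UserWarning, match="unknown element"):
            result = read_pdb(path)
        assert result.n_skipped == 1
        assert len(result.atoms) == 2

    def test_write_then_read_roundtrip(self, tmp_path, model5):
        path = tmp_path / "model.pdb"
        write_pdb(model5, path)
        result = read_pdb(path)
        assert len(result.atoms) == len(model5.atoms)
        # the reader regroups atoms chain by chain; compare sorted
        def order(atoms):
            idx = sorted(range(len(atoms)),
                         key=lambda i: (atoms[i].strand, atoms[i].bp_index,
                                        atoms[i].name.split(".")[-1]))
            return np.array([atoms[i].position for i in idx])

        np.testing.assert_allclose(order(result.atoms), order(model5.atoms),
                                   atol=5e-5)  # PDB fixed-format precision
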