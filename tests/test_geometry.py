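"""Structure annotation, superposition, distances, boxes, fragment specs, edits."""

import numpy as np
import pandas as pd
import pytest

from retroscreen import geometry as geo
from retroscreen import synthetic as syn
from retroscreen.errors import GeometryError


def simple_structure(coords, resname="ALA", chain="A", bw=None):
    atoms = [
        geo.Atom(chain, i + 1, resname, "CA", np.asarray(c, float), element="C")
        for i, c in enumerate(coords)
    ]
    return geo.AnnotatedStructure(atoms=atoms, bw=bw or {})


def random_rigid_transform(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q, rng.normal(scale=10, size=3)


class TestLoadAnnotate:
    def test_pdb_round_trip_with_bw(self, tmp_path, toy_complex):
        pdb = tmp_path / "bundle.pdb"
        toy_complex.to_pdb(pdb)
        bw_rows = [
            {"chain": c, "resnum": r, "generic_number": gn}
            for (c, r), gn in toy_complex.bw.items()
        ]
        bw_rows.append({"chain": "A", "resnum": 9999, "generic_number": "45.52"})
        bw = tmp_path / "bw.tsv"
        pd.DataFrame(bw_rows).to_csv(bw, sep="\t", index=False)
        st = geo.load_and_annotate(pdb, bw)
        # all real rows matched, loop-style label on a missing residue reported
        assert st.bw[("A", 1)] == "1.30"
        assert len(st.unmatched_bw) == 1
        assert st.unmatched_bw[0]["generic_number"] == "45.52"
        assert "LIG" in st.ligands

    def test_loop_style_numbers_accepted(self):
        st = simple_structure([(0, 0, 0)], bw={("A", 1): "45.52"})
        assert st.bw_residue("45.52") == ("A", 1)

    def test_duplicate_bw_assignment_rejected(self):
        with pytest.raises(GeometryError, match="BW"):
            geo.AnnotatedStructure(
                atoms=[
                    geo.Atom("A", 1, "ALA", "CA", np.zeros(3)),
                    geo.Atom("A", 2, "ALA", "CA", np.ones(3)),
                ],
                bw={("A", 1): "2.63", ("A", 2): "2.63"},
            )

    def test_malformed_file_errors(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises(GeometryError):
            geo.load_and_annotate(bad)


class TestSuperpose:
    def test_identical_copies_rmsd_zero(self, toy_complex):
        _, rmsd = geo.superpose_backbones(toy_complex, toy_complex)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_invariance(self, toy_complex, rng):
        R, t = random_rigid_transform(rng)
        moved = toy_complex.transformed(R, t)
        _, rmsd = geo.superpose_backbones(toy_complex, moved)
        assert rmsd <= 1e-6

    def test_selection_restricts_atoms(self, toy_complex, rng):
        R, t = random_rigid_transform(rng)
        moved = toy_complex.transformed(R, t)
        _, rmsd = geo.superpose_backbones(toy_complex, moved, selection=["1.30-1.59"])
        assert rmsd <= 1e-6

    def test_displaced_atom_matches_numerical_oracle(self, rng):
        """Kabsch RMSD equals scipy's independent rotation-alignment optimum."""
        from scipy.spatial.transform import Rotation

        n = 12
        coords = rng.normal(scale=5, size=(n, 3))
        bw = {("A", i + 1): f"1.{30 + i}" for i in range(n)}
        ref = geo.AnnotatedStructure(
            atoms=[geo.Atom("A", i + 1, "ALA", "CA", coords[i].copy()) for i in range(n)],
            bw=dict(bw),
        )
        perturbed = coords.copy()
        perturbed[0] += np.array([1.0, -2.0, 0.5])
        R, t = random_rigid_transform(rng)
        mob = geo.AnnotatedStructure(
            atoms=[geo.Atom("A", i + 1, "ALA", "CA", R @ perturbed[i] + t) for i in range(n)],
            bw=dict(bw),
        )
        _, rmsd = geo.superpose_backbones(ref, mob, atom_names=("CA",))
        P = perturbed - perturbed.mean(axis=0)
        Q = coords - coords.mean(axis=0)
        rot, oracle_ssd = Rotation.align_vectors(Q, P)
        oracle_rmsd = np.sqrt(np.mean(np.sum((P @ rot.as_matrix().T - Q) ** 2, axis=1)))
        assert rmsd == pytest.approx(oracle_rmsd, abs=1e-6)

    def test_too_few_matches_errors(self):
        a = simple_structure([(0, 0, 0)], bw={("A", 1): "1.30"})
        with pytest.raises(GeometryError, match=">= 3"):
            geo.superpose_backbones(a, a, atom_names=("CA",))


class TestDistanceTable:
    def test_three_four_five(self):
        st = simple_structure(
            [(0, 0, 0), (3, 4, 0)], bw={("A", 1): "3.29", ("A", 2): "6.48"}
        )
        st.name = "s"
        table = geo.bw_distance_table([st], [("3.29", "6.48")])
        assert table.loc["s", "3.29-6.48"] == pytest.approx(5.0)

    def test_self_pair_zero(self):
        st = simple_structure([(1, 2, 3)], bw={("A", 1): "3.29"})
        st.name = "s"
        assert geo.bw_distance_table([st], [("3.29", "3.29")]).iloc[0, 0] == 0.0

    def test_missing_in_one_structure_flags_nan(self):
        a = simple_structure([(0, 0, 0), (3, 4, 0)], bw={("A", 1): "3.29", ("A", 2): "6.48"})
        a.name = "a"
        b = simple_structure([(0, 0, 0)], bw={("A", 1): "3.29"})
        b.name = "b"
        table = geo.bw_distance_table([a, b], [("3.29", "6.48")])
        assert np.isnan(table.loc["b", "3.29-6.48"])
        assert table.loc["a", "3.29-6.48"] == pytest.approx(5.0)

    def test_unresolvable_pair_errors(self):
        a = simple_structure([(0, 0, 0)], bw={("A", 1): "3.29"})
        with pytest.raises(GeometryError, match="unresolvable"):
            geo.bw_distance_table([a], [("3.29", "9.99")])

    def test_invariant_to_superposition(self, toy_complex, rng):
        pairs = [("1.39", "7.40"), ("3.29", "6.48")]
        t1 = geo.bw_distance_table([toy_complex], pairs)
        R, t = random_rigid_transform(rng)
        t2 = geo.bw_distance_table([toy_complex.transformed(R, t)], pairs)
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-9)

    def test_two_helix_axis_separation(self):
        # mid-height residues of 10 Å-separated axes: within the 2×radius bound
        st = syn.gen_helix_bundle([(0, 0), (10, 0)], residues_per_helix=20)
        d = float(np.linalg.norm(st.ca("A", 10) - st.ca("A", 30)))
        assert abs(d - 10.0) <= 2 * 2.3 + 0.1


class TestProximalAtoms:
    def _structure(self):
        atoms = [
            geo.Atom("A", 1, "ALA", "CA", np.array([5.4, 0, 0])),
            geo.Atom("A", 2, "ALA", "CA", np.array([5.6, 0, 0])),
            geo.Atom("A", 3, "ALA", "CA", np.array([9.0, 0, 0])),
            geo.Atom("A", 3, "ALA", "CB", np.array([30.0, 0, 0])),
            geo.Atom("L", 9, "LIG", "C1", np.zeros(3)),
        ]
        st = geo.AnnotatedStructure(atoms=atoms)
        st.ligands["LIG"] = [4]
        return st

    def test_atom_granularity_boundary(self):
        st = self._structure()
        hits = geo.select_proximal_atoms(st, "LIG", 5.5, "atom")
        names = {(st.atoms[i].resnum, st.atoms[i].name) for i in hits}
        assert (1, "CA") in names and (2, "CA") not in names

    def test_residue_granularity_pulls_whole_residue(self):
        st = self._structure()
        hits = geo.select_proximal_atoms(st, "LIG", 10.0, "residue")
        names = {(st.atoms[i].resnum, st.atoms[i].name) for i in hits}
        assert (3, "CB") in names  # far atom of a near residue included

    def test_empty_reference_errors(self):
        st = self._structure()
        with pytest.raises(GeometryError, match="empty"):
            geo.select_proximal_atoms(st, [], 5.0)


class TestEnvelopeBox:
    def test_margin_applied_per_axis(self, rng):
        pts = rng.uniform([0, -5, 2], [10, 5, 8], size=(50, 3))
        pts[0] = [0, -5, 2]
        pts[1] = [10, 5, 8]
        box = geo.build_envelope_box(pts, margin=4)
        np.testing.assert_allclose(box.min_corner, [-4, -9, -2])
        np.testing.assert_allclose(box.max_corner, [14, 9, 12])

    def test_single_point_cube(self):
        box = geo.build_envelope_box([[1, 2, 3]], margin=4)
        np.testing.assert_allclose(
            np.array(box.max_corner) - np.array(box.min_corner), [8, 8, 8]
        )

    def test_zero_margin_tight(self):
        box = geo.build_envelope_box([[0, 0, 0], [1, 2, 3]], margin=0)
        assert box.min_corner == (0, 0, 0) and box.max_corner == (1, 2, 3)

    def test_nesting_strict(self, rng):
        pts = rng.normal(size=(10, 3))
        big, small = geo.build_envelope_box(pts, 4), geo.build_envelope_box(pts, 2)
        assert np.all(np.array(big.min_corner) < np.array(small.min_corner))
        assert np.all(np.array(big.max_corner) > np.array(small.max_corner))

    def test_empty_errors(self):
        with pytest.raises(GeometryError):
            geo.build_envelope_box(np.empty((0, 3)))


class TestFragmentSpec:
    def test_orthosteric_minimum_nine(self, toy_complex):
        spec = geo.build_fragment_spec(toy_complex, "LIG", "orthosteric")
        assert spec.min_fragment_length() >= 9
        assert any(hi - lo + 1 <= 5 for _c, lo, hi in spec.seed_segments)
        geo.validate_fragment_spec(spec, toy_complex)

    def test_allosteric_minimum_eighteen(self, toy_complex):
        spec = geo.build_fragment_spec(toy_complex, "LIG", "allosteric")
        assert spec.min_fragment_length() >= 18

    @staticmethod
    def _fragment_helices(st, f):
        return {
            int(st.bw[("A", rn)].split(".")[0])
            for rn in range(f.start, f.end + 1)
            if ("A", rn) in st.bw
        }

    def test_orthosteric_mobility_classes(self, toy_complex):
        spec = geo.build_fragment_spec(toy_complex, "LIG", "orthosteric")
        for f in spec.fragments:
            helices = self._fragment_helices(toy_complex, f)
            expected = "fully_flexible" if helices & {1, 2, 7} else "sidechain_only"
            assert f.mobility == expected

    def test_allosteric_omits_tm4_tm5(self, toy_complex):
        spec = geo.build_fragment_spec(toy_complex, "LIG", "allosteric")
        for f in spec.fragments:
            helices = self._fragment_helices(toy_complex, f)
            assert not (helices and helices <= {4, 5})

    def test_orthosteric_tethers_include_tm2_anchors(self, toy_complex):
        spec = geo.build_fragment_spec(toy_complex, "LIG", "orthosteric")
        bw_tethers = {t.bw for t in spec.tethers if t.bw}
        assert {"2.53", "2.56", "2.60", "2.63"} <= bw_tethers

    def test_restraint_parameters(self, toy_complex):
        for mode, anchors in (
            ("orthosteric", {"1.39", "3.32", "7.36", "7.39", "7.40", "7.44"}),
            ("allosteric", {"8.49", "8.50"}),
        ):
            spec = geo.build_fragment_spec(toy_complex, "LIG", mode)
            assert {r.bw for r in spec.restraints} == anchors
            assert all((r.dmin, r.dmax, r.weight) == (1.8, 2.4, 1.0) for r in spec.restraints)

    def test_sampling_directives(self, toy_complex):
        o = geo.build_fragment_spec(toy_complex, "LIG", "orthosteric")
        a = geo.build_fragment_spec(toy_complex, "LIG", "allosteric")
        assert (o.pre_minimization_steps, o.global_steps) == (10_000, 1_000_000)
        assert (a.pre_minimization_steps, a.global_steps) == (100_000, 1_000_000)

    def test_missing_anchor_errors(self, toy_complex):
        import copy

        st = copy.deepcopy(toy_complex)
        key = st.bw_residue("2.63")
        del st.bw[key]
        with pytest.raises(GeometryError, match="2.63"):
            geo.build_fragment_spec(st, "LIG", "orthosteric")

    def test_disulfide_partner_included(self):
        """A seed touching one cysteine of a disulfide pulls in the partner."""
        st = syn.make_toy_complex()
        # forge a disulfide between a seeded residue and a remote one
        seed_idx = geo.select_proximal_atoms(st, "LIG", 5.5, "residue")
        seeded = sorted({st.atoms[i].resnum for i in seed_idx})
        cys_a, cys_b = seeded[0], 205  # 205 is far from the ligand (TM7 end)
        assert cys_b not in seeded
        for at in st.atoms:
            if at.chain == "A" and at.resnum in (cys_a, cys_b):
                at.resname = "CYS"
        # place SG atoms 2.0 Å apart
        mid = (st.get_atom("A", cys_a, "CA").xyz + st.get_atom("A", cys_b, "CA").xyz) / 2
        st.atoms.append(geo.Atom("A", cys_a, "CYS", "SG", mid + [0, 0, 1.0], element="S"))
        st.atoms.append(geo.Atom("A", cys_b, "CYS", "SG", mid - [0, 0, 1.0], element="S"))
        spec = geo.build_fragment_spec(st, "LIG", "orthosteric")
        assert any(f.contains(cys_b) for f in spec.fragments)
        geo.validate_fragment_spec(spec, st)


class TestMutationEdits:
    def _tyr_structure(self):
        names = geo.RESIDUE_HEAVY_ATOMS["TYR"]
        atoms = [
            geo.Atom("A", 70, "TYR", n, np.array([float(i), 0, 0]))
            for i, n in enumerate(names)
        ]
        return geo.AnnotatedStructure(atoms=atoms)

    def test_shrink_to_ala_truncates_to_cb(self):
        st = self._tyr_structure()
        out = geo.apply_mutation_edits(st, [geo.MutationEdit("A", 70, "Y", "A")])
        names = {a.name for a in out.atoms}
        assert names == {"N", "CA", "C", "O", "CB"}
        assert all(a.resname == "ALA" for a in out.atoms)

    def test_grow_flags_placeholders_occupancy_zero(self):
        names = geo.RESIDUE_HEAVY_ATOMS["CYS"]
        st = geo.AnnotatedStructure(
            atoms=[geo.Atom("A", 70, "CYS", n, np.array([float(i), 0, 0]))
                   for i, n in enumerate(names)]
        )
        out = geo.apply_mutation_edits(st, [geo.MutationEdit("A", 70, "C", "Y")])
        placeholders = [a for a in out.atoms if a.occupancy == 0.0]
        assert placeholders  # ring atoms missing from CYS
        assert all(np.isnan(a.xyz).all() for a in placeholders)
        assert all(a.resname == "TYR" for a in out.atoms)
        # SG is not a TYR atom: removed
        assert "SG" not in {a.name for a in out.atoms}

    def test_mismatched_identity_errors(self):
        st = self._tyr_structure()
        with pytest.raises(GeometryError, match="A70"):
            geo.apply_mutation_edits(st, [geo.MutationEdit("A", 70, "G", "A")])

    def test_original_untouched(self):
        st = self._tyr_structure()
        geo.apply_mutation_edits(st, [geo.MutationEdit("A", 70, "Y", "A")])
        assert {a.name for a in st.atoms} == set(geo.RESIDUE_HEAVY_ATOMS["TYR"])
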