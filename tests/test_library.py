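"""Library curation: pActivity conversion, parsing, roles, fingerprints, UPGMA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retroscreen import library as lib
from retroscreen.errors import CurationError, StructureParseError


class TestPActivity:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [(1, "nM", 9.0), (10, "nM", 8.0), (1, "uM", 6.0), (1, "M", 0.0), (100, "pM", 10.0)],
    )
    def test_unit_conversion(self, value, unit, expected):
        assert lib.compute_pactivity(value, unit) == pytest.approx(expected, abs=1e-12)

    def test_hundredfold_potency_loss_is_two_units(self):
        # a ~100x activity cliff corresponds to Δp = 2
        assert lib.compute_pactivity(1, "nM") - lib.compute_pactivity(100, "nM") == pytest.approx(2.0)

    @given(p=st.floats(min_value=3, max_value=12))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, p):
        assert lib.compute_pactivity(10.0 ** (-p), "M") == pytest.approx(p, abs=1e-9)

    @pytest.mark.parametrize("bad", [0, -1e-9])
    def test_nonpositive_value_rejected(self, bad):
        with pytest.raises(CurationError):
            lib.compute_pactivity(bad, "nM")

    def test_unknown_unit_rejected(self):
        with pytest.raises(CurationError):
            lib.compute_pactivity(1, "fM")


class TestParse:
    def _write(self, tmp_path, text):
        p = tmp_path / "table.tsv"
        p.write_text(text)
        return p

    def test_aliases_preserved(self, tmp_path):
        p = self._write(
            tmp_path,
            "compound_id\tsmiles\talias\tchemotype\treceptor\tsite\tmeasure\tvalue\tunit\n"
            "cherney08a_22\tCCN\tBMS CCR2 22\tBMS\thCCR2\torthosteric\tIC50\t5\tnM\n",
        )
        library = lib.parse_compound_table(p)
        rec = library.get("cherney08a_22")
        assert rec.aliases == ["BMS CCR2 22"]
        assert rec.activities[0].pactivity == pytest.approx(8.301, abs=1e-3)

    def test_empty_table_warns(self, tmp_path):
        p = self._write(tmp_path, "compound_id\tsmiles\n")
        with pytest.warns(UserWarning, match="empty"):
            library = lib.parse_compound_table(p)
        assert library.compounds == []

    def test_duplicate_id_error_names_both_rows(self, tmp_path):
        p = self._write(tmp_path, "compound_id\tsmiles\nc1\tCC\nc1\tCCC\n")
        with pytest.raises(CurationError, match="rows 0 and 1"):
            lib.parse_compound_table(p)

    def test_bad_smiles_rejected_not_dropped(self, tmp_path):
        p = self._write(tmp_path, "compound_id\tsmiles\nok\tCCO\nbad\tnot_a_smiles\n")
        library = lib.parse_compound_table(p)
        assert library.ids == ["ok"]
        assert len(library.rejections) == 1
        assert library.rejections[0].compound_id == "bad"

    def test_sdf_round_trip(self, tmp_path):
        from rdkit import Chem

        mol = Chem.MolFromSmiles("c1ccccc1O")
        mol.SetProp("_Name", "phenol")
        mol.SetProp("compound_id", "phenol")
        sdf = tmp_path / "in.sdf"
        with Chem.SDWriter(str(sdf)) as w:
            w.write(mol)
        library = lib.parse_compound_table(sdf, format="sdf")
        assert library.ids == ["phenol"]


class TestRoles:
    def _library(self, pacts, cutoff=7.5, chemotype="BI"):
        comps = [
            lib.CompoundRecord(
                compound_id=f"c{i}",
                chemotype=chemotype,
                activities=[lib.ActivityRecord("hCCR2", "orthosteric", "IC50", 10.0 ** (-p))],
            )
            for i, p in enumerate(pacts)
        ]
        return lib.ScreeningLibrary(compounds=comps, thresholds={chemotype: cutoff})

    def test_strictly_above_cutoff_is_active(self):
        out = lib.assign_roles(self._library([7.6]), "hCCR2", "orthosteric")
        assert out.compounds[0].role == "active"

    def test_boundary_value_is_inactive(self):
        # "actives of pActivity > cutoff" is a strict inequality
        out = lib.assign_roles(self._library([7.5]), "hCCR2", "orthosteric")
        assert out.compounds[0].role == "inactive"

    def test_lower_chemotype_cutoff(self):
        out = lib.assign_roles(self._library([6.6], cutoff=6.5, chemotype="UCB"), "hCCR2", "orthosteric")
        assert out.compounds[0].role == "active"

    def test_missing_threshold_errors(self):
        library = self._library([8.0], chemotype="GSK")
        library.thresholds = {"BI": 7.5}
        with pytest.raises(CurationError, match="GSK"):
            lib.assign_roles(library, "hCCR2", "orthosteric")

    def test_idempotent(self):
        once = lib.assign_roles(self._library([8.0, 7.0]), "hCCR2", "orthosteric")
        twice = lib.assign_roles(once, "hCCR2", "orthosteric")
        assert [c.role for c in once.compounds] == [c.role for c in twice.compounds]

    def test_most_potent_measurement_wins(self):
        rec = lib.CompoundRecord(
            compound_id="c",
            chemotype="BI",
            activities=[
                lib.ActivityRecord("hCCR2", "orthosteric", "IC50", 1e-7),  # p = 7
                lib.ActivityRecord("hCCR2", "orthosteric", "Ki", 1e-9),  # p = 9
            ],
        )
        library = lib.ScreeningLibrary(compounds=[rec], thresholds={"BI": 7.5})
        out = lib.assign_roles(library, "hCCR2", "orthosteric")
        assert out.compounds[0].role == "active"

    def test_decoys_untouched(self):
        library = self._library([8.0])
        library.compounds[0].role = "decoy"
        out = lib.assign_roles(library, "hCCR2", "orthosteric")
        assert out.compounds[0].role == "decoy"


class TestFingerprint:
    def test_equivalent_smiles_identical(self):
        assert lib.compute_fingerprint("OCC") == lib.compute_fingerprint("CCO")

    def test_stereoisomers_identical(self):
        # stereochemical activity cliffs must register similarity 1.0
        a = lib.compute_fingerprint("C[C@H](N)C(=O)O")
        b = lib.compute_fingerprint("C[C@@H](N)C(=O)O")
        assert a == b
        assert lib.tanimoto_distance(a, b) == 0.0

    def test_methane_nonempty(self):
        assert len(lib.compute_fingerprint("C")) >= 1

    def test_unparsable_errors(self):
        with pytest.raises(StructureParseError):
            lib.compute_fingerprint("][")


class TestTanimoto:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({1, 2, 3}, {1, 2, 3}, 0.0),
            ({1, 2}, {3, 4}, 1.0),
            ({1, 2, 3}, {2, 3, 4}, 0.5),
        ],
    )
    def test_examples(self, a, b, expected):
        assert lib.tanimoto_distance(frozenset(a), frozenset(b)) == expected

    def test_both_empty_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert lib.tanimoto_distance(frozenset(), frozenset()) == 0.0

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_identity(self, data):
        bits = st.frozensets(st.integers(0, 63), max_size=20)
        a, b = data.draw(bits), data.draw(bits)
        if len(a) == 0 or len(b) == 0:
            return
        assert lib.tanimoto_distance(a, b) == lib.tanimoto_distance(b, a)
        assert lib.tanimoto_distance(a, a) == 0.0
        assert 0.0 <= lib.tanimoto_distance(a, b) <= 1.0


class TestUPGMA:
    def test_hand_example(self):
        d = [[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]]
        dendro = lib.upgma(["A", "B", "C"], d)
        assert dendro.merges[0] == (("A",), ("B",), 0.2)
        (a, b, h) = dendro.merges[1]
        assert {a, b} == {("A", "B"), ("C",)}
        assert h == pytest.approx(0.7)

    def test_cut_hand_example(self):
        d = [[0, 0.2, 0.6], [0.2, 0, 0.8], [0.6, 0.8, 0]]
        dendro = lib.upgma(["A", "B", "C"], d)
        assert dendro.cut(0.5) == [("A", "B"), ("C",)]
        assert dendro.cut(0.1) == [("A",), ("B",), ("C",)]
        assert dendro.cut(1.0) == [("A", "B", "C")]

    def test_all_zero_distances_single_cluster(self):
        d = np.zeros((4, 4))
        dendro = lib.upgma(list("abcd"), d)
        assert all(h == 0 for *_x, h in dendro.merges)
        assert dendro.cut(0.0) == [("a", "b", "c", "d")]

    def test_heights_non_decreasing_random(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            dendro = lib.upgma([f"x{i}" for i in range(n)], D)
            heights = [h for *_m, h in dendro.merges]
            assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_matches_scipy_average_linkage(self, rng):
        """Merge heights and cut partitions agree with scipy on tie-free matrices."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        for _ in range(50):
            n = 6
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            ids = [f"x{i}" for i in range(n)]
            dendro = lib.upgma(ids, D)
            Z = linkage(squareform(D), method="average")
            ours = sorted(h for *_m, h in dendro.merges)
            theirs = sorted(Z[:, 2])
            np.testing.assert_allclose(ours, theirs, atol=1e-12)
            cut = float(rng.random())
            labels = fcluster(Z, t=cut, criterion="distance")
            scipy_parts = {}
            for i, lab in enumerate(labels):
                scipy_parts.setdefault(lab, []).append(ids[i])
            scipy_set = {tuple(sorted(v)) for v in scipy_parts.values()}
            assert set(dendro.cut(cut)) == scipy_set

    def test_label_stability_under_permutation(self, rng):
        n = 7
        D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        ids = [f"c{i}" for i in range(n)]
        dendro1 = lib.upgma(ids, D)
        perm = rng.permutation(n)
        dendro2 = lib.upgma([ids[i] for i in perm], D[np.ix_(perm, perm)])
        assert dendro1.labels(0.4) == dendro2.labels(0.4)

    def test_cluster_chemotypes_assigns_labels(self):
        comps = [
            lib.CompoundRecord("a1", fingerprint=frozenset({1, 2, 3, 4})),
            lib.CompoundRecord("a2", fingerprint=frozenset({1, 2, 3, 5})),
            lib.CompoundRecord("b1", fingerprint=frozenset({10, 11, 12})),
        ]
        library = lib.ScreeningLibrary(compounds=comps)
        dendro, labels = lib.cluster_chemotypes(library, cut_height=0.5)
        assert labels["a1"] == labels["a2"] == "a1"
        assert labels["b1"] == "b1"
        assert comps[0].chemotype == "a1"
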