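"""Pedigree I/O, genetic-group augmentation and relationship matrices."""

import numpy as np
import pandas as pd
import pytest

from provblup.pedigree import (
    GroupAssignmentError,
    GroupScheme,
    PedigreeError,
    PedigreeFormatError,
    PedigreeRecord,
    augment_with_groups,
    build_A_tabular,
    build_Ainv_with_groups,
    build_group_fractions,
    compute_inbreeding,
    read_pedigree,
    sort_and_validate,
    write_pedigree,
)


def _write(tmp_path, text, name="ped.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPedigree:
    def test_founders_only_file(self, tmp_path):
        p = _write(tmp_path, "individual,dam,sire,provenance\nA,,,P1\nB,,,P1\nC,0,0,P2\n")
        recs = read_pedigree(p)
        assert len(recs) == 3
        assert all(r.dam == "" and r.sire == "" for r in recs)
        assert recs[2].provenance == "P2"

    def test_open_pollinated_convention(self, tmp_path):
        p = _write(tmp_path, "individual,dam,sire,provenance\nM1,,,P1\nO1,M1,,P1\n")
        recs = read_pedigree(p)
        assert recs[1].dam == "M1" and recs[1].sire == ""

    def test_self_parentage_rejected(self, tmp_path):
        p = _write(tmp_path, "individual,dam,sire,provenance\nX,X,,\n")
        with pytest.raises(PedigreeError):
            read_pedigree(p)

    def test_duplicate_individual_rejected(self, tmp_path):
        p = _write(tmp_path, "individual,dam,sire,provenance\nA,,,P1\nA,,,P1\n")
        with pytest.raises(PedigreeError):
            read_pedigree(p)

    def test_missing_columns_rejected(self, tmp_path):
        p = _write(tmp_path, "id,mother\nA,\n")
        with pytest.raises(PedigreeFormatError):
            read_pedigree(p)

    def test_tab_delimited(self, tmp_path):
        p = _write(tmp_path, "individual\tdam\tsire\tprovenance\nA\t\t\tP1\n")
        assert read_pedigree(p)[0].individual == "A"


class TestSortAndValidate:
    def test_offspring_before_dam_reordered(self):
        recs = [PedigreeRecord("O1", dam="M1"), PedigreeRecord("M1")]
        out = sort_and_validate(recs)
        assert [r.individual for r in out] == ["M1", "O1"]

    def test_cycle_detected(self):
        recs = [PedigreeRecord("A", dam="B"), PedigreeRecord("B", dam="A")]
        with pytest.raises(PedigreeError, match="cycle"):
            sort_and_validate(recs)

    def test_sorted_input_is_fixed_point(self):
        recs = [PedigreeRecord("M1"), PedigreeRecord("O1", dam="M1"),
                PedigreeRecord("O2", dam="M1")]
        assert sort_and_validate(recs) == recs

    def test_undeclared_parents_become_founders(self):
        out = sort_and_validate([PedigreeRecord("O1", dam="M9", sire="S9")])
        ids = [r.individual for r in out]
        assert set(ids) == {"M9", "S9", "O1"} and ids[-1] == "O1"
        founders = {r.individual: r for r in out}
        assert founders["M9"].provenance == ""


@pytest.fixture
def op_records():
    recs = []
    for prov in ("A", "B"):
        for m in range(2):
            mid = f"M{prov}{m}"
            recs.append(PedigreeRecord(mid, provenance=prov))
            for o in range(2):
                recs.append(PedigreeRecord(f"O{prov}{m}{o}", dam=mid, provenance=prov))
    recs.append(PedigreeRecord("CTRL"))
    return recs


class TestAugmentation:
    def test_gc1_mother_and_offspring_slots(self, op_records):
        scheme = GroupScheme.for_provenances(["A", "B"], "gc1")
        aug = augment_with_groups(op_records, scheme, ungrouped="founder")
        recs = {r.individual: r for r in aug.records}
        assert (recs["MA0"].dam, recs["MA0"].sire) == ("GRP_A", "GRP_POLLEN")
        assert recs["OA00"].dam == "MA0" and recs["OA00"].sire == "GRP_POLLEN"

    def test_gc2_both_sides_to_provenance_group(self, op_records):
        scheme = GroupScheme.for_provenances(["A", "B"], "gc2")
        aug = augment_with_groups(op_records, scheme, ungrouped="founder")
        recs = {r.individual: r for r in aug.records}
        assert (recs["MA0"].dam, recs["MA0"].sire) == ("GRP_A", "GRP_A")
        assert recs["OB10"].sire == "GRP_B"

    def test_mode_none_is_identity(self, op_records):
        aug = augment_with_groups(op_records, GroupScheme(mode="none"))
        assert aug.groups == []
        assert [r.individual for r in aug.records] == [
            r.individual for r in sort_and_validate(op_records)
        ]
        assert any(r.dam == "" for r in aug.records)

    def test_unprovenanced_founder_errors_by_default(self, op_records):
        scheme = GroupScheme.for_provenances(["A", "B"], "gc1")
        with pytest.raises(GroupAssignmentError):
            augment_with_groups(op_records, scheme)

    def test_gc1_requires_distinct_pollen_group(self):
        with pytest.raises(ValueError):
            GroupScheme(mode="gc1", provenance_groups={"A": "G1"}, pollen_group="G1")

    def test_roundtrip_with_role_column(self, op_records, tmp_path):
        scheme = GroupScheme.for_provenances(["A", "B"], "gc2")
        aug = augment_with_groups(op_records, scheme, ungrouped="founder")
        path = tmp_path / "aug.csv"
        write_pedigree(aug, path)
        df = pd.read_csv(path, keep_default_na=False)
        assert (df["role"] == "group").sum() == 2
        assert (df["role"] == "individual").sum() == aug.n_individuals


class TestInbreeding:
    def test_founders_are_noninbred(self, op_records):
        aug = augment_with_groups(op_records, GroupScheme(mode="none"))
        assert np.all(aug.inbreeding == 0.0)

    @pytest.mark.parametrize(
        "mating, expected",
        [("full_sib", 0.25), ("half_sib", 0.125)],
    )
    def test_classical_values(self, mating, expected):
        recs = [PedigreeRecord("D"), PedigreeRecord("S"), PedigreeRecord("S2")]
        recs += [PedigreeRecord("K1", dam="D", sire="S")]
        sire2 = "S" if mating == "full_sib" else "S2"
        recs += [PedigreeRecord("K2", dam="D", sire=sire2)]
        recs += [PedigreeRecord("X", dam="K1", sire="K2")]
        aug = augment_with_groups(recs, GroupScheme(mode="none"))
        F = dict(zip(aug.individuals, aug.inbreeding))
        assert F["X"] == pytest.approx(expected)

    def test_selfing_rejected(self):
        recs = [PedigreeRecord("A"), PedigreeRecord("B", dam="A", sire="A")]
        with pytest.raises(PedigreeError, match="selfing"):
            augment_with_groups(recs, GroupScheme(mode="none"))


class TestTabularA:
    def test_unrelated_founders_give_identity(self):
        recs = [PedigreeRecord(f"F{i}") for i in range(4)]
        A = build_A_tabular(augment_with_groups(recs, GroupScheme(mode="none")))
        assert np.allclose(A.values, np.eye(4))

    def test_textbook_relationships(self):
        recs = [
            PedigreeRecord("D"),
            PedigreeRecord("S"),
            PedigreeRecord("K1", dam="D", sire="S"),
            PedigreeRecord("K2", dam="D", sire="S"),
            PedigreeRecord("H", dam="D"),
        ]
        A = build_A_tabular(augment_with_groups(recs, GroupScheme(mode="none")))
        assert A.loc["D", "K1"] == pytest.approx(0.5)  # parent-offspring
        assert A.loc["K1", "K2"] == pytest.approx(0.5)  # full sibs
        assert A.loc["K1", "H"] == pytest.approx(0.25)  # half sibs

    def test_op_half_sibs_with_phantom_sires(self, op_records):
        scheme = GroupScheme.for_provenances(["A", "B"], "gc1")
        aug = augment_with_groups(op_records, scheme, ungrouped="founder")
        A = build_A_tabular(aug)
        assert A.loc["OA00", "OA01"] == pytest.approx(0.25)
        # groups excluded from the index set
        assert "GRP_A" not in A.index

    def test_diagonal_and_definiteness_on_random_pedigrees(self, rng):
        for _ in range(5):
            recs = [PedigreeRecord(f"F{i}") for i in range(6)]
            for k in range(25):
                pool = [r.individual for r in recs]
                dam, sire = rng.choice(pool, 2, replace=False)
                recs.append(PedigreeRecord(f"I{k}", dam=dam, sire=sire))
            aug = augment_with_groups(recs, GroupScheme(mode="none"))
            A = build_A_tabular(aug).values
            assert np.allclose(A, A.T)
            d = np.diag(A)
            assert np.all((d >= 1.0 - 1e-12) & (d <= 2.0 + 1e-12))
            assert np.linalg.eigvalsh(A).min() > 0


class TestAinvWithGroups:
    def test_single_founder_single_group(self):
        aug = augment_with_groups(
            [PedigreeRecord("F1", provenance="A")],
            GroupScheme.for_provenances(["A"], "gc2"),
        )
        M = build_Ainv_with_groups(aug).toarray()
        # phantom groups carry the unknown ancestors' mean, not their
        # variance: the prior is (a - g)^2, i.e. [[1,-1],[-1,1]] over (g, i)
        assert np.allclose(M, [[1.0, -1.0], [-1.0, 1.0]])

    def test_mode_none_founders_identity(self):
        recs = [PedigreeRecord(f"F{i}") for i in range(5)]
        aug = augment_with_groups(recs, GroupScheme(mode="none"))
        assert np.allclose(build_Ainv_with_groups(aug).toarray(), np.eye(5))

    def test_inverse_of_tabular_A_mode_none(self, rng):
        recs = [PedigreeRecord(f"F{i}") for i in range(10)]
        for k in range(190):
            pool = [r.individual for r in recs]
            dam, sire = rng.choice(pool, 2, replace=False)
            kwargs = {"dam": dam} if k % 3 == 0 else {"dam": dam, "sire": sire}
            recs.append(PedigreeRecord(f"I{k}", **kwargs))
        aug = augment_with_groups(recs, GroupScheme(mode="none"))
        A = build_A_tabular(aug).values
        Ainv = build_Ainv_with_groups(aug).toarray()
        assert np.allclose(A @ Ainv, np.eye(len(A)), atol=1e-9)

    def test_quaas_block_identity(self, op_records):
        scheme = GroupScheme.for_provenances(["A", "B"], "gc1")
        aug = augment_with_groups(op_records, scheme, ungrouped="founder")
        Astar = build_Ainv_with_groups(aug).toarray()
        Ainv = build_Ainv_with_groups(aug, include_groups=False).toarray()
        Q = build_group_fractions(aug).values
        expect = np.block(
            [[Q.T @ Ainv @ Q, -Q.T @ Ainv], [-Ainv @ Q, Ainv]]
        )
        assert np.allclose(Astar, expect)


class TestGroupFractions:
    def test_gc2_offspring_fully_on_provenance_group(self, op_records):
        scheme = GroupScheme.for_provenances(["A", "B"], "gc2")
        aug = augment_with_groups(op_records, scheme, ungrouped="founder")
        Q = build_group_fractions(aug)
        assert Q.loc["OA00", "GRP_A"] == pytest.approx(1.0)
        assert Q.loc["OA00"].sum() == pytest.approx(1.0)

    def test_gc1_offspring_quarter_three_quarters(self, op_records):
        # the mother's own unknown sire points at the pollen group, so the
        # offspring's recursion gives 1/4 provenance + 3/4 pollen
        scheme = GroupScheme.for_provenances(["A", "B"], "gc1")
        aug = augment_with_groups(op_records, scheme, ungrouped="founder")
        Q = build_group_fractions(aug)
        assert Q.loc["OB10", "GRP_B"] == pytest.approx(0.25)
        assert Q.loc["OB10", "GRP_POLLEN"] == pytest.approx(0.75)

    def test_rows_sum_to_one_except_controls(self, op_records):
        scheme = GroupScheme.for_provenances(["A", "B"], "gc1")
        aug = augment_with_groups(op_records, scheme, ungrouped="founder")
        Q = build_group_fractions(aug)
        sums = Q.sum(axis=1)
        assert np.allclose(sums.drop("CTRL"), 1.0)
        assert sums["CTRL"] == 0.0
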