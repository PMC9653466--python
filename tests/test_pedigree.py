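import numpy as np
import pytest

from flockgen.pedigree import (
    PedigreeError, ainverse, amatrix, build_pedigree, history_sheet,
    inbreeding, inbreeding_wright, pedigree_sheet,
)

from conftest import kinship_oracle, random_trios


class TestBuildPedigree:
    def test_sorts_parents_before_offspring(self):
        ped = build_pedigree([("B", "A", None), ("A", None, None)])
        assert ped.ids.index("A") < ped.ids.index("B")

    def test_cycle_raises_naming_the_animals(self):
        with pytest.raises(PedigreeError, match="A.*B|B.*A"):
            build_pedigree([("A", "B", None), ("B", "A", None)])

    def test_dangling_parent_becomes_founder(self):
        ped = build_pedigree([("B", "GHOST", None)])
        assert "GHOST" in ped.ids
        assert ped.parents(ped.index_of("GHOST")) == (-1, -1)

    def test_parent_indices_precede_child_on_large_random_pedigree(self):
        rng = np.random.default_rng(0)
        ped = build_pedigree(random_trios(rng, 500))
        for i in range(len(ped)):
            s, d = ped.parents(i)
            assert s < i and d < i


class TestAmatrix:
    def test_unrelated_founders_give_identity(self):
        ped = build_pedigree([("A", None, None), ("B", None, None)])
        assert np.array_equal(amatrix(ped), np.eye(2))

    def test_trio_has_half_parent_offspring_and_unit_diagonal(self):
        ped = build_pedigree([("S", None, None), ("D", None, None), ("X", "S", "D")])
        A = amatrix(ped)
        x, s = ped.index_of("X"), ped.index_of("S")
        assert A[x, x] == 1.0
        assert A[x, s] == 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_twice_kinship_oracle_on_random_pedigrees(self, seed):
        rng = np.random.default_rng(seed)
        trios = random_trios(rng, 12)
        ped = build_pedigree(trios)
        phi, _ = kinship_oracle(trios)
        A = amatrix(ped)
        for i, a in enumerate(ped.ids):
            for j, b in enumerate(ped.ids):
                assert A[i, j] == pytest.approx(2 * phi(a, b), abs=1e-12)

    def test_positive_semi_definite(self):
        rng = np.random.default_rng(99)
        ped = build_pedigree(random_trios(rng, 60))
        assert np.linalg.eigvalsh(amatrix(ped)).min() >= -1e-9


class TestInbreeding:
    def test_full_sib_offspring(self):
        ped = build_pedigree([
            ("S", None, None), ("D", None, None),
            ("B1", "S", "D"), ("B2", "S", "D"), ("X", "B1", "B2"),
        ])
        assert inbreeding(ped)[ped.index_of("X")] == pytest.approx(0.25)

    def test_half_sib_offspring(self):
        ped = build_pedigree([
            ("S", None, None), ("D1", None, None), ("D2", None, None),
            ("H1", "S", "D1"), ("H2", "S", "D2"), ("X", "H1", "H2"),
        ])
        assert inbreeding(ped)[ped.index_of("X")] == pytest.approx(0.125)

    def test_parent_offspring_mating(self):
        ped = build_pedigree([
            ("S", None, None), ("D", None, None),
            ("A", "S", "D"), ("X", "S", "A"),
        ])
        assert inbreeding(ped)[ped.index_of("X")] == pytest.approx(0.25)

    def test_second_round_full_sib_mating(self):
        ped = build_pedigree([
            ("S", None, None), ("D", None, None),
            ("B1", "S", "D"), ("B2", "S", "D"),
            ("C1", "B1", "B2"), ("C2", "B1", "B2"), ("X", "C1", "C2"),
        ])
        assert inbreeding(ped)[ped.index_of("X")] == pytest.approx(0.375)

    def test_unknown_parent_means_zero_f(self):
        ped = build_pedigree([("S", None, None), ("X", "S", None)])
        assert inbreeding(ped)[ped.index_of("X")] == 0.0

    def test_deleting_non_ancestor_leaves_f_unchanged(self):
        trios = [
            ("S", None, None), ("D", None, None), ("U", None, None),
            ("B1", "S", "D"), ("B2", "S", "D"), ("V", "U", "D"), ("X", "B1", "B2"),
        ]
        full = build_pedigree(trios)
        f_full = dict(zip(full.ids, inbreeding(full)))
        pruned = build_pedigree([t for t in trios if t[0] not in ("U", "V")])
        f_pruned = dict(zip(pruned.ids, inbreeding(pruned)))
        for aid, f in f_pruned.items():
            assert f == pytest.approx(f_full[aid], abs=1e-15)


class TestWrightPaths:
    def test_parent_offspring_single_path(self):
        ped = build_pedigree([
            ("S", None, None), ("D", None, None),
            ("A", "S", "D"), ("X", "S", "A"),
        ])
        assert inbreeding_wright(ped, "X") == pytest.approx(0.25)

    def test_full_sib_two_common_ancestors(self):
        ped = build_pedigree([
            ("S", None, None), ("D", None, None),
            ("B1", "S", "D"), ("B2", "S", "D"), ("X", "B1", "B2"),
        ])
        assert inbreeding_wright(ped, "X") == pytest.approx(2 * 0.5 ** 3)

    def test_inbred_common_ancestor_contributes_1_plus_fa(self):
        # X's parents are both offspring of A, and A is itself a full-sib child
        ped = build_pedigree([
            ("G1", None, None), ("G2", None, None),
            ("B1", "G1", "G2"), ("B2", "G1", "G2"),
            ("A", "B1", "B2"),  # F_A = 0.25
            ("M1", None, None), ("M2", None, None),
            ("C1", "A", "M1"), ("C2", "A", "M2"), ("X", "C1", "C2"),
        ])
        assert inbreeding_wright(ped, "X") == pytest.approx(0.5 ** 3 * 1.25)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_recursive_method_on_random_pedigrees(self, seed):
        rng = np.random.default_rng(1000 + seed)
        ped = build_pedigree(random_trios(rng, 12))
        F = inbreeding(ped)
        for i, aid in enumerate(ped.ids):
            assert inbreeding_wright(ped, aid) == pytest.approx(F[i], abs=1e-12)


class TestAinverse:
    def test_founders_only_is_identity(self):
        ped = build_pedigree([("A", None, None), ("B", None, None)])
        assert np.array_equal(ainverse(ped).toarray(), np.eye(2))

    def test_trio_multiplies_back_to_identity(self):
        ped = build_pedigree([("S", None, None), ("D", None, None), ("X", "S", "D")])
        prod = amatrix(ped) @ ainverse(ped).toarray()
        assert np.abs(prod - np.eye(3)).max() < 1e-12

    def test_simulated_pedigree_multiplies_back_within_tolerance(self):
        from flockgen.sim import SimParams, simulate_flock
        ds, _ = simulate_flock(SimParams(
            n_founder_sires=6, n_founder_dams=35, n_generations=3, seed=4))
        ped = build_pedigree(ds.animals)
        assert len(ped) >= 140
        prod = amatrix(ped) @ ainverse(ped).toarray()
        assert np.abs(prod - np.eye(len(ped))).max() < 1e-8


class TestSheets:
    def test_founder_tree_has_unknown_parents(self):
        ped = build_pedigree([("A", None, None)])
        tree = pedigree_sheet(ped, "A", 3)
        assert tree["sire"]["id"] == "UNKNOWN" and tree["dam"]["id"] == "UNKNOWN"

    def test_depth_request_beyond_pedigree_bottoms_out_at_founders(self):
        ped = build_pedigree([
            ("G", None, None), ("H", None, None), ("P", "G", "H"),
            ("Q", None, None), ("X", "P", "Q"),
        ])
        tree = pedigree_sheet(ped, "X", 5)
        assert tree["sire"]["sire"]["id"] == "G"
        assert tree["sire"]["sire"]["sire"]["id"] == "UNKNOWN"

    def test_unknown_id_raises(self, small_flock):
        with pytest.raises(PedigreeError):
            history_sheet(small_flock, "NOPE")

    def test_history_sheet_progeny_and_trait_means(self, small_flock):
        sheet = history_sheet(small_flock, "R1")
        assert sheet["progeny"] == ["L1", "L2", "L3"]
        # progeny BWT mean recomputed directly from the trait table
        vals = [t.value for t in small_flock.traits
                if t.trait_code == "BWT" and t.animal_id in ("L1", "L2", "L3")]
        assert sheet["progeny_trait_summary"]["BWT"]["mean"] == pytest.approx(
            sum(vals) / len(vals))

    def test_history_sheet_of_eventless_animal_is_identity_only(self, small_flock):
        sheet = history_sheet(small_flock, "W1")
        assert sheet["traits"] == [] and sheet["progeny"] == []
        assert sheet["health"] == [] and sheet["disposal"] is None
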