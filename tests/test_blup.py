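import numpy as np
import pytest
import scipy.sparse as sp

from flockgen.blup import (
    BlupError, EBVTable, MixedModelSpec, assemble_mme, blup_ebv,
    individual_ebv, lambda_from_h2, rank_animals, solve_mme,
)
from flockgen.blup import EBVRow
from flockgen.pedigree import ainverse, amatrix, build_pedigree
from flockgen.sim import SimParams, simulate_flock
from flockgen.varcomp import RandomUnit

from conftest import random_trios


def gls_blup_oracle(y, X, Z, A, lam):
    """Closed-form GLS/BLUP through the phenotypic covariance V."""
    s2u, s2e = 1.0, lam  # any pair with ratio lam
    Zd = Z.toarray() if sp.issparse(Z) else np.asarray(Z)
    V = Zd @ A @ Zd.T * s2u + np.eye(len(y)) * s2e
    Vinv = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    u = s2u * A @ Zd.T @ Vinv @ (y - X @ b)
    return b, u


def random_mme_instance(rng, max_units=50):
    n_units = int(rng.integers(5, max_units + 1))
    trios = random_trios(rng, n_units)
    ped = build_pedigree(trios)
    A = amatrix(ped)
    Ainv = ainverse(ped)
    n_rec = int(rng.integers(n_units, 2 * n_units))
    rec_unit = rng.integers(0, n_units, size=n_rec)
    Z = sp.csr_matrix((np.ones(n_rec), (np.arange(n_rec), rec_unit)),
                      shape=(n_rec, n_units))
    sexes = rng.integers(0, 2, size=n_rec)
    X = np.column_stack([np.ones(n_rec), sexes.astype(float)])
    y = 20 + 2.0 * sexes + rng.normal(size=n_rec) * 3.0
    lam = float(rng.uniform(0.5, 5.0))
    return y, X, Z, A, Ainv, lam


class TestLambda:
    def test_printed_ratios(self):
        assert lambda_from_h2(0.25, RandomUnit.SIRE) == pytest.approx(15.0)
        assert lambda_from_h2(0.5, RandomUnit.ANIMAL) == pytest.approx(1.0)

    def test_sire_ratio_monotone_decreasing_toward_three(self):
        grid = np.linspace(0.05, 0.999, 50)
        vals = [lambda_from_h2(h, RandomUnit.SIRE) for h in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(3.0, abs=0.02)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_h2_outside_unit_interval_rejected(self, bad):
        with pytest.raises(BlupError):
            lambda_from_h2(bad)


class TestAssemble:
    def test_smallest_system_is_textbook_2x2(self):
        y = np.array([3.0])
        X = np.ones((1, 1))
        Z = sp.csr_matrix(np.ones((1, 1)))
        lam = 2.0
        sysm = assemble_mme(y, X, Z, np.eye(1), lam)
        assert np.allclose(sysm.coeff.toarray(), [[1, 1], [1, 1 + lam]])
        assert np.allclose(sysm.rhs, [3.0, 3.0])

    def test_unrecorded_unit_enters_only_through_lambda_ainv(self):
        # 2 units, 1 record on unit 0
        y = np.array([4.0])
        X = np.ones((1, 1))
        Z = sp.csr_matrix(([1.0], ([0], [0])), shape=(1, 2))
        lam = 1.5
        sysm = assemble_mme(y, X, Z, np.eye(2), lam)
        M = sysm.coeff.toarray()
        assert M[2, 2] == lam  # Z'Z diagonal 0 for the unrecorded unit
        assert sysm.rhs[2] == 0.0

    def test_dimension_mismatch_names_block(self):
        with pytest.raises(BlupError, match="Ainv"):
            assemble_mme(np.ones(2), np.ones((2, 1)),
                         sp.identity(2), np.eye(3), 1.0)


class TestSolve:
    def test_all_records_equal_gives_zero_ebv(self):
        y = np.full(4, 7.0)
        X = np.ones((4, 1))
        Z = sp.identity(4, format="csr")
        b, u = solve_mme(assemble_mme(y, X, Z, np.eye(4), 2.0))
        assert b[0] == pytest.approx(7.0)
        assert np.allclose(u, 0.0)

    def test_identity_a_closed_form_shrinkage(self):
        rng = np.random.default_rng(1)
        y = rng.normal(30, 4, size=8)
        X = np.ones((8, 1))
        Z = sp.identity(8, format="csr")
        lam = 3.0
        b, u = solve_mme(assemble_mme(y, X, Z, np.eye(8), lam))
        # closed form for Z'Z = I, A = I: u_i = (y_i - mu_hat)/(1 + lam)
        assert np.allclose(u, (y - b[0]) / (1 + lam), atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_v_matrix_gls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y, X, Z, A, Ainv, lam = random_mme_instance(rng)
        b, u = solve_mme(assemble_mme(y, X, Z, Ainv, lam))
        b0, u0 = gls_blup_oracle(y, X, Z, A, lam)
        assert np.abs(b - b0).max() < 1e-6
        assert np.abs(u - u0).max() < 1e-6

    def test_sum_of_ebv_is_zero_with_mean_model_and_identity_a(self):
        # subtracting the mean equation from the summed unit equations in
        # the MME leaves lambda * sum(u) = 0, so EBVs sum to zero exactly
        rng = np.random.default_rng(2)
        n_units = 12
        rec_unit = rng.integers(0, n_units, size=30)
        Z = sp.csr_matrix((np.ones(30), (np.arange(30), rec_unit)),
                          shape=(30, n_units))
        y = rng.normal(size=30)
        X = np.ones((30, 1))
        _, u = solve_mme(assemble_mme(y, X, Z, np.eye(n_units), 1.7))
        assert abs(float(u.sum())) < 1e-8

    def test_shrinkage_larger_lambda_smaller_norm(self):
        rng = np.random.default_rng(3)
        y, X, Z, A, Ainv, _ = random_mme_instance(rng, max_units=20)
        _, u1 = solve_mme(assemble_mme(y, X, Z, Ainv, 1.0))
        _, u2 = solve_mme(assemble_mme(y, X, Z, Ainv, 5.0))
        assert np.linalg.norm(u2) < np.linalg.norm(u1)

    def test_ebv_invariant_to_constant_phenotype_shift(self):
        rng = np.random.default_rng(4)
        y, X, Z, A, Ainv, lam = random_mme_instance(rng, max_units=15)
        _, u1 = solve_mme(assemble_mme(y, X, Z, Ainv, lam))
        _, u2 = solve_mme(assemble_mme(y + 100.0, X, Z, Ainv, lam))
        assert np.abs(u1 - u2).max() < 1e-8


class TestIndividualEbv:
    def test_formula_limits_and_arithmetic(self):
        phen = {"A": 40.0, "B": 20.0}
        assert set(individual_ebv(phen, 0.0).as_dict().values()) == {30.0}
        assert individual_ebv(phen, 1.0).as_dict() == phen
        t = individual_ebv({"A": 40.0, "B": 30.0, "C": 20.0}, 0.25)
        assert t.as_dict()["A"] == pytest.approx(32.5)  # 30 + 0.25*(40-30)

    def test_empty_input_raises(self):
        with pytest.raises(BlupError):
            individual_ebv({}, 0.3)


class TestBlupEbv:
    def test_identity_a_reduces_to_deviation_form(self):
        # one founder cohort, one record each: BLUP collapses to
        # u_i = h2 (y_i - mu_hat), the deviation form of mass selection
        ds, _ = simulate_flock(SimParams(
            n_founder_sires=10, n_founder_dams=30, n_generations=1,
            survival_to_12m=1.0, sex_effect=0.0, seed=5))
        h2 = 0.3
        tab = blup_ebv(ds, MixedModelSpec(trait="W12M", fixed=(), h2=h2))
        recs = {t.animal_id: t.value for t in ds.traits if t.trait_code == "W12M"}
        mu = np.mean(list(recs.values()))
        ebv = tab.as_dict()
        for aid, yv in recs.items():
            assert ebv[aid] == pytest.approx(h2 * (yv - mu), abs=1e-8)

    def test_correlation_with_truth_increases_in_h2(self):
        corrs = []
        for h2 in (0.1, 0.3, 0.6):
            ds, truth = simulate_flock(SimParams(
                n_founder_sires=15, n_founder_dams=150, n_generations=3,
                h2_true=h2, seed=6))
            tab = blup_ebv(ds, MixedModelSpec(trait="W12M", h2=h2))
            ebv = tab.as_dict()
            ids = sorted(set(ebv) & set(truth.true_bv))
            c = np.corrcoef([ebv[a] for a in ids],
                            [truth.true_bv[a] for a in ids])[0, 1]
            corrs.append(c)
        assert corrs[0] > 0
        assert corrs[0] < corrs[1] < corrs[2]

    def test_unrecorded_ancestors_receive_ebv(self):
        ds, _ = simulate_flock(SimParams(
            n_founder_sires=4, n_founder_dams=12, n_generations=2,
            survival_to_12m=0.8, seed=7))
        tab = blup_ebv(ds, MixedModelSpec(trait="W12M", h2=0.3))
        assert len(tab.rows) == len(ds.animals)


class TestRanking:
    def make_table(self, vals, farm="F1"):
        t = EBVTable(trait="W12M", method="BLUP")
        for aid, v in vals.items():
            t.rows.append(EBVRow(aid, farm, "W12M", "BLUP", v))
        return t

    def test_descending_order(self):
        ranked = rank_animals([self.make_table({"A": 1.0, "B": 2.0})])
        assert [r["animal_id"] for r in ranked] == ["B", "A"]

    def test_exact_tie_broken_by_ascending_id(self):
        ranked = rank_animals([self.make_table({"R2": 1.0, "R10": 1.0})])
        assert [r["animal_id"] for r in ranked] == ["R10", "R2"]
        assert [r["rank"] for r in ranked] == [1, 1]

    def test_two_farm_merge_equals_concatenated_ranking(self):
        t1 = self.make_table({"A": 0.5, "B": 1.5}, farm="F1")
        t2 = self.make_table({"C": 1.0, "D": -0.5}, farm="F2")
        merged = rank_animals([t1, t2])
        concat = self.make_table({"A": 0.5, "B": 1.5, "C": 1.0, "D": -0.5})
        assert [r["animal_id"] for r in merged] == \
               [r["animal_id"] for r in rank_animals([concat])]
        assert {r["animal_id"]: r["farm_id"] for r in merged}["C"] == "F2"

    def test_mixed_traits_rejected(self):
        t1 = self.make_table({"A": 1.0})
        t2 = self.make_table({"B": 1.0})
        t2.trait = "BWT"
        for r in t2.rows:
            r.trait = "BWT"
        with pytest.raises(BlupError):
            rank_animals([t1, t2])
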