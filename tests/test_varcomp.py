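import numpy as np
import pytest
import scipy.sparse as sp

from flockgen.sim import SimParams, simulate_flock, simulate_sib_design
from flockgen.pedigree import ainverse, build_pedigree
from flockgen.varcomp import (
    H2Method, RandomUnit, SibDesign, VarcompError, build_design_matrices,
    h2_from_anova, nested_anova, reml_animal, reml_loglik,
)


def anova_ss_oracle(groups):
    """Definitional double-loop sums of squares for the nested partition."""
    allv = [v for dams in groups.values() for vals in dams.values() for v in vals]
    grand = np.mean(allv)
    ss_s = ss_d = ss_w = 0.0
    for dams in groups.values():
        sv = [v for vals in dams.values() for v in vals]
        sm = np.mean(sv)
        ss_s += len(sv) * (sm - grand) ** 2
        for vals in dams.values():
            dm = np.mean(vals)
            ss_d += len(vals) * (dm - sm) ** 2
            ss_w += sum((v - dm) ** 2 for v in vals)
    return ss_s, ss_d, ss_w


class TestNestedAnova:
    def test_all_equal_phenotypes_raise_total_variance_zero(self):
        groups = {"S1": {"D1": [5.0, 5.0]}, "S2": {"D2": [5.0, 5.0]}}
        with pytest.raises(VarcompError, match="TOTAL_VARIANCE_ZERO"):
            nested_anova(SibDesign(groups))

    def test_balanced_coefficients_reduce_to_n_n_dn(self):
        des, _ = simulate_sib_design(4, 2, 3, h2=0.3, seed=1)
        t = nested_anova(des)
        assert (t.k1, t.k2, t.k3) == (3.0, 3.0, 6.0)

    def test_sums_of_squares_match_definitional_oracle(self):
        des, _ = simulate_sib_design(4, 2, 3, h2=0.4, seed=2)
        t = nested_anova(des)
        ss_s, ss_d, ss_w = anova_ss_oracle(des.groups)
        assert t.ms_s * t.df_s == pytest.approx(ss_s, abs=1e-10)
        assert t.ms_d * t.df_d == pytest.approx(ss_d, abs=1e-10)
        assert t.ms_w * t.df_w == pytest.approx(ss_w, abs=1e-10)

    def test_ss_partition_and_permutation_invariance_unbalanced(self):
        rng = np.random.default_rng(3)
        groups = {
            f"S{i}": {
                f"S{i}D{j}": list(rng.normal(size=rng.integers(2, 6)))
                for j in range(rng.integers(2, 5))
            } for i in range(5)
        }
        t = nested_anova(SibDesign(groups))
        ss_s, ss_d, ss_w = anova_ss_oracle(groups)
        allv = [v for dams in groups.values() for vals in dams.values() for v in vals]
        ss_total = float(np.sum((np.array(allv) - np.mean(allv)) ** 2))
        assert ss_s + ss_d + ss_w == pytest.approx(ss_total, rel=1e-9)
        # reversed insertion order must not change anything
        rev = {s: {d: groups[s][d] for d in reversed(list(groups[s]))}
               for s in reversed(list(groups))}
        t2 = nested_anova(SibDesign(rev))
        for a, b in [(t.ms_s, t2.ms_s), (t.ms_d, t2.ms_d), (t.ms_w, t2.ms_w),
                     (t.sigma2_s, t2.sigma2_s), (t.sigma2_d, t2.sigma2_d)]:
            assert a == pytest.approx(b, rel=1e-12)

    def test_dam_appearing_under_two_sires_is_rejected(self):
        groups = {"S1": {"D1": [1.0, 2.0]}, "S2": {"D1": [3.0, 4.0]}}
        with pytest.raises(VarcompError, match="exactly one sire"):
            SibDesign(groups)


class TestH2FromAnova:
    def test_zero_family_components_give_zero_h2(self):
        des, _ = simulate_sib_design(6, 2, 4, h2=0.0, seed=4)
        t = nested_anova(des)
        # truncation may leave tiny positives; force exact zero case
        t.sigma2_s = t.sigma2_d = 0.0
        for comp in (H2Method.SIRE, H2Method.DAM, H2Method.SIRE_DAM):
            assert h2_from_anova(t, comp).h2_raw == 0.0

    def test_sire_dam_arithmetic(self):
        from flockgen.varcomp import AnovaTable
        t = AnovaTable(df_s=1, df_d=1, df_w=1, ms_s=0, ms_d=0, ms_w=0,
                       k1=1, k2=1, k3=1,
                       sigma2_s=0.075, sigma2_d=0.075, sigma2_w=0.85)
        assert h2_from_anova(t, "SIRE_DAM").h2_raw == pytest.approx(0.30)
        assert h2_from_anova(t, "SIRE").h2_raw == pytest.approx(0.30)

    def test_sire_and_dam_estimates_agree_in_expectation(self):
        # no maternal or dominance effects in the generator, so the sire
        # and dam routes estimate the same quantity
        from scipy.stats import ttest_ind
        sire, dam = [], []
        for rep in range(500):
            des, _ = simulate_sib_design(20, 2, 3, h2=0.3, seed=50_000 + rep)
            t = nested_anova(des)
            sire.append(h2_from_anova(t, "SIRE").h2_raw)
            dam.append(h2_from_anova(t, "DAM").h2_raw)
        assert ttest_ind(sire, dam).pvalue > 0.01


class TestDesignMatrices:
    def test_mean_plus_sex_contrast_for_two_sexes(self):
        ds, _ = simulate_flock(SimParams(
            n_founder_sires=3, n_founder_dams=10, n_generations=1, seed=6))
        y, X, Z, units, labels = build_design_matrices(ds, "W12M", ["sex", "year"])
        assert labels == ["mu", "sex:MALE"]  # one year, one farm -> dropped
        assert X.shape[1] == 2

    def test_farm_contrast_autoincluded_with_two_farms(self):
        ds, _ = simulate_flock(SimParams(
            n_founder_sires=3, n_founder_dams=10, n_generations=1,
            n_farms=2, seed=6))
        _, X, _, _, labels = build_design_matrices(ds, "W12M", ["sex"])
        assert any(l.startswith("farm:") for l in labels)

    def test_ols_on_design_recovers_simulated_sex_effect(self):
        ds, _ = simulate_flock(SimParams(
            n_founder_sires=120, n_founder_dams=360, n_generations=1,
            sex_effect=3.0, seed=7))
        y, X, _, _, labels = build_design_matrices(ds, "W12M", ["sex"])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        est = beta[labels.index("sex:MALE")]
        # MC se ~ sqrt(sigma2_p (1/108 + 1/324)) ~ 0.45
        assert est == pytest.approx(3.0, abs=1.5)

    def test_missing_trait_raises(self, small_flock):
        with pytest.raises(VarcompError):
            build_design_matrices(small_flock, "GFY9")


class TestRemlAnimal:
    def test_noiseless_fixed_effects_drive_h2_to_zero(self):
        rng = np.random.default_rng(8)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([10.0, 2.0])  # zero residual, no genetic signal
        Z = sp.identity(n, format="csr")
        est = reml_animal(y, X, Z, np.eye(n), maxit=500)
        assert est.h2_raw < 0.02

    def test_loglik_never_lower_at_solution_than_at_init(self):
        ds, _ = simulate_flock(SimParams(
            n_founder_sires=5, n_founder_dams=25, n_generations=2, seed=9))
        ped = build_pedigree(ds.animals)
        y, X, Z, _, _ = build_design_matrices(
            ds, "W12M", ["sex"], unit_ids=ped.ids)
        from flockgen.pedigree import amatrix
        A = amatrix(ped)
        init = (1.0, 1.0)
        est = reml_animal(y, X, Z, ainverse(ped), init=init)
        s2u, s2e = est.components["sigma2_u"], est.components["sigma2_e"]
        ll_init = reml_loglik(y, X, Z, A, *init)
        ll_sol = reml_loglik(y, X, Z, A, s2u, s2e)
        assert ll_sol >= ll_init - 1e-8

    def test_matches_independent_grid_search_on_grouped_design(self):
        # one-way random-effect layout: A = I, Z maps records to 12 groups
        rng = np.random.default_rng(10)
        q, reps = 12, 5
        u = rng.normal(0, np.sqrt(2.0), size=q)
        y = np.repeat(u, reps) + rng.normal(0, 1.0, size=q * reps) + 5.0
        X = np.ones((q * reps, 1))
        Z = sp.csr_matrix((np.ones(q * reps),
                           (np.arange(q * reps), np.repeat(np.arange(q), reps))),
                          shape=(q * reps, q))
        A = np.eye(q)
        est = reml_animal(y, X, Z, A, tol=1e-10, maxit=2000)
        # independent route: refine a direct grid over the likelihood surface
        best = (1.0, 1.0)
        span = 4.0
        for _ in range(8):
            g_u = np.linspace(max(best[0] - span, 1e-4), best[0] + span, 21)
            g_e = np.linspace(max(best[1] - span, 1e-4), best[1] + span, 21)
            vals = [(reml_loglik(y, X, Z, A, a, b), a, b) for a in g_u for b in g_e]
            _, bu, be = max(vals)
            best = (bu, be)
            span /= 4.0
        assert est.components["sigma2_u"] == pytest.approx(best[0], abs=1e-3)
        assert est.components["sigma2_e"] == pytest.approx(best[1], abs=1e-3)

    def test_nonconvergence_flag_at_tiny_maxit(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=30)
        X = np.ones((30, 1))
        Z = sp.identity(30, format="csr")
        est = reml_animal(y, X, Z, np.eye(30), maxit=2)
        assert est.converged is False and est.iterations == 2
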