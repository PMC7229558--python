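"""Principal chi-squared, Hotelling, SSUP, GOLD and Min2 global tests."""

import numpy as np
import pytest
from scipy import stats

from pchiassoc import (
    DiseaseModel,
    GenotypeDataset,
    MultiTest,
    PairingModel,
    ScoreStat,
    gold_test,
    hotelling_t2,
    min2,
    principal_chisq,
    prospective_score,
    select_components,
    simulate_dataset,
    ssup,
)
from pchiassoc.assoc_tests import _imhof_pvalue, _liu_pvalue
from pchiassoc.scores import CODING_ADDITIVE


def _random_score(dim, seed, coding=CODING_ADDITIVE):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(dim + 4, dim))
    v = a.T @ a
    u = rng.normal(size=dim)
    return ScoreStat(u, v, coding)


class TestSelectComponents:
    @pytest.mark.parametrize(
        "lam,threshold,expected",
        [
            ([1, 0, 0], 0.85, 1),
            ([3, 1, 1], 0.85, 3),  # cumulative fractions 0.6, 0.8, 1.0
            ([9, 1], 0.85, 1),  # 0.9 >= 0.85
            ([5, 5], 1.0, 2),
        ],
    )
    def test_threshold_rule(self, lam, threshold, expected):
        assert select_components(np.array(lam, float), threshold) == expected

    def test_floor_drops_null_space(self):
        # near-zero eigenvalue excluded from numerator and denominator
        assert select_components(np.array([9.0, 1.0, 1e-12]), 0.85) == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            select_components(np.zeros(3))


class TestPrincipalChisq:
    def test_scalar_case_is_one_df_score_test(self):
        sc = ScoreStat([2.0], [[2.0]], CODING_ADDITIVE)
        et = principal_chisq(sc)
        assert et.s == 1
        assert et.statistic == pytest.approx(2.0)
        assert et.p_value == pytest.approx(stats.chi2.sf(2.0, 1))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_full_rank_equals_hotelling_inverse_form(self, seed):
        sc = _random_score(5, seed)
        et = principal_chisq(sc, threshold=1.0)
        direct = sc.u @ np.linalg.inv(sc.v) @ sc.u
        assert et.statistic == pytest.approx(direct, rel=1e-8)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_invariant_to_joint_orthogonal_rotation(self, seed):
        sc = _random_score(4, seed)
        rng = np.random.default_rng(seed + 100)
        qmat, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        rotated = ScoreStat(sc.u @ qmat, qmat.T @ sc.v @ qmat, sc.coding)
        for thr in (0.85, 1.0):
            a = principal_chisq(sc, thr)
            b = principal_chisq(rotated, thr)
            assert a.s == b.s
            assert a.statistic == pytest.approx(b.statistic, rel=1e-8)

    def test_eigvec_diagonalization_invariant(self):
        sc = _random_score(6, 11)
        et = principal_chisq(sc)
        d = et.eigenvectors.T @ sc.v @ et.eigenvectors
        assert np.allclose(d, np.diag(et.eigenvalues), atol=1e-8 * et.eigenvalues[0])


class TestHotelling:
    def test_diagonal_hand_example(self):
        sc = ScoreStat([2.0, 2.0], np.diag([2.0, 2.0]), CODING_ADDITIVE)
        assert hotelling_t2(sc).statistic == pytest.approx(4.0)

    def test_equals_principal_chisq_threshold_one(self):
        sc = _random_score(5, 7)
        assert hotelling_t2(sc).statistic == pytest.approx(
            principal_chisq(sc, 1.0).statistic
        )

    def test_duplicated_column_does_not_change_retained_t2(self, make_dataset):
        d = make_dataset(seed=13, q=3)
        dup = GenotypeDataset(
            np.column_stack([d.genotypes, d.genotypes[:, 0]]),
            d.phenotype,
            d.snp_ids + ["S1dup"],
        )
        t_a = hotelling_t2(prospective_score(d))
        t_b = hotelling_t2(prospective_score(dup))
        assert t_b.diagnostics["retained_rank"] == t_a.diagnostics["retained_rank"]
        assert t_b.statistic == pytest.approx(t_a.statistic, rel=1e-6)


class TestSsup:
    def test_statistic_is_sum_of_squares(self):
        sc = ScoreStat([3.0, 4.0], np.diag([1.0, 1.0]), CODING_ADDITIVE)
        assert ssup(sc).statistic == pytest.approx(25.0)

    def test_single_snp_p_equals_chi2(self):
        sc = ScoreStat([1.4], [[0.7]], CODING_ADDITIVE)
        expected = stats.chi2.sf(1.4**2 / 0.7, 1)
        assert ssup(sc).p_value == pytest.approx(expected, rel=1e-6)
        assert ssup(sc, method="imhof").p_value == pytest.approx(expected, rel=1e-4)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_eigen_decomposition_identity(self, seed):
        # sum U^2 = sum lambda (U a / sqrt(lambda))^2 over all components
        sc = _random_score(5, seed)
        lam, vec = np.linalg.eigh(sc.v)
        z = (sc.u @ vec) / np.sqrt(lam)
        assert np.sum(lam * z**2) == pytest.approx(float(sc.u @ sc.u), rel=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_liu_close_to_exact_inversion(self, seed):
        rng = np.random.default_rng(seed)
        lam = rng.uniform(0.2, 3.0, size=6)
        t = lam.sum() + rng.uniform(0, 3) * np.sqrt(2 * (lam**2).sum())
        assert _liu_pvalue(t, lam) == pytest.approx(_imhof_pvalue(t, lam), abs=0.01)

    def test_requires_additive_score(self):
        sc = _random_score(4, 9, coding="codominant-empirical-bayes")
        with pytest.raises(ValueError):
            ssup(sc)


class TestGoldTest:
    def test_toy_statistic_and_pvalue(self):
        d = GenotypeDataset(np.array([[0], [2]]), np.array([1, 0]), ["S1"])
        res = gold_test(d, 0)
        assert res.statistic == pytest.approx(2.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(2.0, 1), abs=1e-6)

    def test_invariant_to_global_label_swap(self, make_dataset):
        d = make_dataset(seed=15)
        swapped = GenotypeDataset(d.genotypes, 1 - d.phenotype, d.snp_ids)
        assert gold_test(d, 0).statistic == pytest.approx(
            gold_test(swapped, 0).statistic
        )

    def test_null_statistic_matches_chi2_quantiles(self, nat2):
        # oracle statistic under the null follows chi2_1 (QQ agreement)
        rng = np.random.default_rng(21)
        stats_obs = []
        for _ in range(400):
            d = simulate_dataset(nat2, PairingModel(0.0), DiseaseModel.null(0), 250, 250, rng)
            stats_obs.append(gold_test(d, 0).statistic)
        ks = stats.kstest(stats_obs, stats.chi2(df=1).cdf)
        assert ks.pvalue > 0.01


class TestMin2:
    def test_observed_statistic_is_min_of_p_values(self, make_dataset):
        d = make_dataset(seed=17, n=200, q=4)
        res = min2(d, n_perm=30, rng=np.random.default_rng(0))
        assert res.statistic == pytest.approx(
            min(res.diagnostics["p_pchip"], res.diagnostics["p_pchib"])
        )
        assert 0 <= res.p_value <= 1

    def test_add_one_floor_under_strong_signal(self, nat2):
        rng = np.random.default_rng(1)
        d = simulate_dataset(
            nat2, PairingModel(0.0), DiseaseModel.additive(0, 4.0), 600, 600, rng
        )
        res = min2(d, n_perm=99, rng=rng)
        assert res.p_value == pytest.approx(1 / 100)

    def test_invalid_permutation_count(self, make_dataset):
        d = make_dataset(seed=18)
        with pytest.raises(ValueError):
            min2(d, n_perm=0, rng=np.random.default_rng(0))


class TestPcrEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_pchip_equals_pc_regression_score(self, make_dataset, seed):
        # the principal chi-squared statistic on the additive prospective
        # score equals the logistic score statistic of Y on the top PCs of
        # the centered genotype matrix (computed independently via SVD)
        d = make_dataset(seed=seed, n=150, q=5)
        battery = MultiTest(d)
        g = d.genotypes.astype(float)
        y = d.phenotype.astype(float)
        ybar = y.mean()
        gc = g - g.mean(axis=0)
        _, sv, wt = np.linalg.svd(gc, full_matrices=False)
        lam = ybar * (1 - ybar) * sv**2
        s = select_components(lam)
        pcs = gc @ wt[:s].T
        u_pc = pcs.T @ (y - ybar)
        v_pc = ybar * (1 - ybar) * (pcs.T @ pcs)
        direct = u_pc @ np.linalg.solve(v_pc, u_pc)
        assert battery.s_p == s
        assert battery.pchip().statistic == pytest.approx(direct, rel=1e-8)

    def test_ssup_and_pchi_share_component_scores(self, make_dataset):
        # SSUP = sum lam Z_k^2 and PChi = sum_{k<=s} Z_k^2 with identical Z_k
        d = make_dataset(seed=4, n=150, q=5)
        sc = prospective_score(d)
        lam, vec = np.linalg.eigh(sc.v)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]
        z = (sc.u @ vec) / np.sqrt(lam)
        s = select_components(lam)
        battery = MultiTest(d)
        assert battery.pchip().statistic == pytest.approx(np.sum(z[:s] ** 2), rel=1e-8)
        assert battery.ssup().statistic == pytest.approx(np.sum(lam * z**2), rel=1e-8)

    def test_pchip_pvalues_uniform_under_null(self, nat2):
        # chi2_s null law: p-values of the PChiP statistic are uniform
        rng = np.random.default_rng(33)
        pvals = []
        for _ in range(800):
            d = simulate_dataset(nat2, PairingModel(0.0), DiseaseModel.null(0), 400, 400, rng)
            pvals.append(MultiTest(d).pchip().p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_orthogonal_components_uncorrelated_under_null(self, nat2):
        # standardized component scores (U xi_j / sqrt(lam_j)) are
        # uncorrelated across null replicates
        rng = np.random.default_rng(34)
        zs = []
        for _ in range(500):
            d = simulate_dataset(nat2, PairingModel(0.0), DiseaseModel.null(0), 300, 300, rng)
            b = MultiTest(d)
            y = d.phenotype.astype(float)
            zs.append((y - y.mean()) @ b._proj_p)
        zs = np.array(zs)
        corr = np.corrcoef(zs, rowvar=False)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.abs(off).max() < 4 / np.sqrt(len(zs))
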