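"""Covariance proportionality tests and generalized-variance ratios."""

import numpy as np
import pytest

from craniomorph import (generalized_variance_ratio, group_covariances,
                         proportionality_test, relative_eigenvalues,
                         variance_comparison_table)


def wishart_cov(rng, sigma_chol, n):
    x = rng.normal(size=(n, sigma_chol.shape[0])) @ sigma_chol.T
    d = x - x.mean(axis=0)
    return d.T @ d / (n - 1)


class TestGroupCovariances:
    def test_identical_specimens_zero_matrix(self):
        scores = np.tile([1.0, 2.0, 3.0], (5, 1))
        covs = group_covariances(scores, ["g"] * 5)
        assert np.all(covs["g"][0] == 0.0)
        assert covs["g"][1] == 5

    def test_known_diagonal_recovered_at_large_n(self, rng):
        diag = np.array([4.0, 2.0, 1.0, 0.5])
        x = rng.normal(size=(500, 4)) * np.sqrt(diag)
        cov, n = group_covariances(x, ["g"] * 500)["g"]
        # entrywise standard error of a covariance entry is O(sigma^2/sqrt n)
        se = 3 * np.sqrt(2.0 / n) * np.outer(np.sqrt(diag), np.sqrt(diag))
        assert np.all(np.abs(cov - np.diag(diag)) <= se)

    def test_ml_denominator_flag(self, rng):
        x = rng.normal(size=(10, 3))
        c1 = group_covariances(x, ["g"] * 10, ddof=1)["g"][0]
        c0 = group_covariances(x, ["g"] * 10, ddof=0)["g"][0]
        assert np.allclose(c0 * 10 / 9, c1)

    def test_small_group_warns_singleton_errors(self, rng):
        with pytest.warns(UserWarning, match="rank deficient"):
            group_covariances(rng.normal(size=(4, 6)), ["g"] * 4)
        with pytest.raises(ValueError, match="covariance undefined"):
            group_covariances(rng.normal(size=(1, 3)), ["g"])


class TestProportionality:
    def test_exact_proportionality_statistic_zero(self, rng):
        a = rng.normal(size=(6, 6))
        s = a @ a.T + 6 * np.eye(6)
        cmp_ = proportionality_test(3.0 * s, s, 20, 20)
        assert cmp_.prop_statistic == pytest.approx(0.0, abs=1e-9)
        assert cmp_.prop_p == pytest.approx(1.0)
        assert cmp_.gv_ratio == pytest.approx(3.0 ** 6, rel=1e-9)
        assert cmp_.prop_df == 6 * 7 // 2 - 1

    def test_invariant_to_simultaneous_linear_transform(self, rng):
        a = rng.normal(size=(4, 4))
        s1 = a @ a.T + 4 * np.eye(4)
        b = rng.normal(size=(4, 4))
        s2 = b @ b.T + 4 * np.eye(4)
        t0 = proportionality_test(s1, s2, 30, 25).prop_statistic
        m = rng.normal(size=(4, 4)) + 3 * np.eye(4)
        t1 = proportionality_test(m @ s1 @ m.T, m @ s2 @ m.T, 30, 25).prop_statistic
        assert t1 == pytest.approx(t0, rel=1e-8)

    def test_type_one_error_within_binomial_ci(self):
        """Proportional populations, n=200 each, 500 replicates: the
        rejection rate at alpha=0.05 stays within the binomial envelope."""
        rng = np.random.default_rng(42)
        k, n, reps = 6, 200, 500
        a = rng.normal(size=(k, k))
        sigma = a @ a.T + k * np.eye(k)
        chol = np.linalg.cholesky(sigma)
        rej = 0
        for _ in range(reps):
            sa = wishart_cov(rng, chol, n)
            sb = wishart_cov(rng, np.sqrt(2.5) * chol, n)
            rej += proportionality_test(sa, sb, n, n).prop_p < 0.05
        rate = rej / reps
        # 3-sigma binomial CI around 0.05 at 500 replicates: +/- 0.029
        assert abs(rate - 0.05) < 0.03

    def test_power_against_inflated_eigenvalue(self):
        rng = np.random.default_rng(43)
        k, n, reps = 6, 200, 100
        a = rng.normal(size=(k, k))
        sigma = a @ a.T + k * np.eye(k)
        vals, vecs = np.linalg.eigh(sigma)
        vals_b = vals.copy()
        vals_b[-1] *= 5.0
        chol_a = np.linalg.cholesky(sigma)
        chol_b = np.linalg.cholesky(vecs @ np.diag(vals_b) @ vecs.T)
        rej = sum(
            proportionality_test(wishart_cov(rng, chol_a, n),
                                 wishart_cov(rng, chol_b, n), n, n).prop_p < 0.05
            for _ in range(reps))
        assert rej / reps > 0.9

    def test_singular_reference_refused(self, rng):
        s1 = np.eye(3)
        s2 = np.diag([1.0, 1.0, 0.0])
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            relative_eigenvalues(s1, s2)


class TestGeneralizedVariance:
    def test_trivial_ratios(self):
        assert generalized_variance_ratio(np.eye(4), np.eye(4)) == 1.0
        assert generalized_variance_ratio(np.diag([2.0, 3.0]), np.eye(2)) \
            == pytest.approx(6.0)

    def test_log_antisymmetry_and_product_of_relative_eigenvalues(self, rng):
        a = rng.normal(size=(5, 5))
        s1 = a @ a.T + 5 * np.eye(5)
        b = rng.normal(size=(5, 5))
        s2 = b @ b.T + 5 * np.eye(5)
        r_ab = generalized_variance_ratio(s1, s2)
        r_ba = generalized_variance_ratio(s2, s1)
        assert np.log(r_ab) == pytest.approx(-np.log(r_ba), rel=1e-9)
        lam = relative_eigenvalues(s1, s2)
        assert r_ab == pytest.approx(float(np.prod(lam)), rel=1e-9)

    def test_scale_equivariance(self, rng):
        k = 4
        a = rng.normal(size=(k, k))
        s1 = a @ a.T + k * np.eye(k)
        s2 = np.eye(k)
        c = 1.7
        r0 = generalized_variance_ratio(s1, s2)
        r1 = generalized_variance_ratio(c ** 2 * s1, s2)  # data scaled by c
        assert r1 == pytest.approx(r0 * c ** (2 * k), rel=1e-9)

    def test_nonsquare_rejected(self, rng):
        with pytest.raises(ValueError):
            generalized_variance_ratio(rng.normal(size=(3, 2)), np.eye(2))


class TestComparisonTable:
    def test_planted_gv_ladder_recovered(self):
        # one n=100 log-determinant ratio carries ~0.4 sd in log, so the
        # 25% envelope is checked on the geometric mean over 50 replicates
        k, n, reps = 4, 100, 50
        scales = [1.0, 2.0, 4.0, 8.0, 16.0, 32.0]
        logsum = {}
        for rep in range(reps):
            r = np.random.default_rng(900 + rep)
            scores, labels = [], []
            for i, s in enumerate(scales):
                scores.append(r.normal(size=(n, k)) * s ** (1 / (2 * k)))
                labels += [f"g{i}"] * n
            table = variance_comparison_table(np.vstack(scores), labels)
            for pair, cmp_ in table.comparisons.items():
                logsum[pair] = logsum.get(pair, 0.0) + np.log(cmp_.gv_ratio)
        for i in range(len(scales)):
            for j in range(i + 1, len(scales)):
                planted = scales[i] / scales[j]
                got = np.exp(logsum[(f"g{i}", f"g{j}")] / reps)
                assert got == pytest.approx(planted, rel=0.25)

    def test_empty_exclusion_matches_full_run(self, rng):
        scores = rng.normal(size=(30, 3))
        labels = ["a"] * 15 + ["b"] * 15
        t0 = variance_comparison_table(scores, labels)
        t1 = variance_comparison_table(scores, labels,
                                       specimen_ids=[str(i) for i in range(30)],
                                       exclude=[])
        assert t0.ratio_frame().equals(t1.ratio_frame())

    def test_exclusion_changes_only_affected_group(self, rng):
        scores = rng.normal(size=(30, 3))
        labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        ids = [f"s{i}" for i in range(30)]
        t0 = variance_comparison_table(scores, labels, specimen_ids=ids)
        t1 = variance_comparison_table(scores, labels, specimen_ids=ids,
                                       exclude=["s5"])  # member of group a
        r0, r1 = t0.ratio_frame(), t1.ratio_frame()
        assert r0.loc["b", "c"] == pytest.approx(r1.loc["b", "c"], rel=1e-12)
        assert r0.loc["a", "b"] != pytest.approx(r1.loc["a", "b"], rel=1e-6)

    def test_excluding_planted_outlier_shrinks_group_variance(self):
        from craniomorph.simulate import GroupSpec, SimulationSpec, simulate
        from craniomorph import gpa, pca, retain_components
        spec = SimulationSpec(
            groups=[GroupSpec("EuS", 12, sigma=0.02),
                    GroupSpec("Inuit", 12, sigma=0.02)],
            outliers={"EuS_2": 4.0}, seed=21)
        ds, _ = simulate(spec)
        aligned = gpa(ds)
        kept = retain_components(pca(aligned), 6)
        t_full = variance_comparison_table(kept.scores, aligned.labels,
                                           specimen_ids=aligned.specimen_ids)
        t_excl = variance_comparison_table(kept.scores, aligned.labels,
                                           specimen_ids=aligned.specimen_ids,
                                           exclude=["EuS_2"])
        assert t_excl.comparisons[("EuS", "Inuit")].gv_ratio \
            < t_full.comparisons[("EuS", "Inuit")].gv_ratio

    def test_exclusion_emptying_group_rejected(self, rng):
        scores = rng.normal(size=(6, 2))
        labels = ["a"] * 5 + ["b"]
        with pytest.raises(ValueError, match="emptied group"):
            variance_comparison_table(scores, labels,
                                      specimen_ids=list("uvwxyz"),
                                      exclude=["z"])
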