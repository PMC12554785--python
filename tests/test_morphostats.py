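"""Statistical core: GLM against a normal-equations oracle, smoothing
kernel analytics, BH-FDR hand computations, partial correlation against a
two-step residual oracle, Mann–Whitney exact enumeration, and permutation
cluster behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from morphnet.morphostats import (adjusted_correlation, build_design, fdr_bh,
                                  fit_group_glm, mann_whitney,
                                  permutation_cluster_fwe, smooth_volume)


def glm_oracle(X, y, col):
    """Independent normal-equations solve for one coefficient's t."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * np.linalg.inv(XtX)[col, col])
    t = beta[col] / se
    return beta[col], t, 2 * stats.t.sf(abs(t), df)


class TestGroupGLM:
    def test_matches_oracle_on_random_toy_designs(self):
        """100 random small designs: t and p equal the oracle to 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(8, 16)
            k_cov = rng.integers(0, 3)
            X = np.column_stack([np.ones(n),
                                 rng.integers(0, 2, n).astype(float),
                                 rng.standard_normal((n, k_cov))])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            y = rng.standard_normal(n)
            sm = fit_group_glm(y[:, None], design=X, group_index=1)
            b, t, p = glm_oracle(X, y, 1)
            assert sm.t[0] == pytest.approx(t, abs=1e-10)
            assert sm.p[0] == pytest.approx(p, abs=1e-10)
            assert sm.beta_group[0] == pytest.approx(b, abs=1e-10)

    def test_equals_classic_two_sample_t(self):
        data = pd.DataFrame({"v": [1.0, 2, 3, 4, 5, 6]})
        subs = pd.DataFrame({"group": ["patient"] * 3 + ["control"] * 3})
        sm = fit_group_glm(data, subjects=subs, covariates=())
        ref = stats.ttest_ind([1, 2, 3], [4, 5, 6])
        assert sm.t[0] == pytest.approx(ref.statistic, abs=1e-12)
        assert sm.p[0] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_identical_groups_give_t0_p1(self):
        data = pd.DataFrame({"v": [1.0, 2, 3, 1, 2, 3]})
        subs = pd.DataFrame({"group": ["patient"] * 3 + ["control"] * 3})
        sm = fit_group_glm(data, subjects=subs, covariates=())
        assert sm.t[0] == pytest.approx(0.0, abs=1e-12)
        assert sm.p[0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_covariate_leaves_t_unchanged(self):
        rng = np.random.default_rng(1)
        n = 20
        g = np.repeat([1.0, 0.0], n // 2)
        y = rng.standard_normal(n)
        X0 = np.column_stack([np.ones(n), g])
        # covariate orthogonalized against intercept, group and response
        c = rng.standard_normal(n)
        A = np.column_stack([np.ones(n), g, y])
        c -= A @ np.linalg.lstsq(A, c, rcond=None)[0]
        X1 = np.column_stack([X0, c])
        t0 = fit_group_glm(y[:, None], design=X0, group_index=1).t[0]
        t1 = fit_group_glm(y[:, None], design=X1, group_index=1).t[0]
        # same fit; only df bookkeeping differs
        assert t1 == pytest.approx(t0 * np.sqrt((n - 3) / (n - 2)), abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError):
            fit_group_glm(np.random.default_rng(0).standard_normal((6, 2)),
                          design=X, group_index=1)

    def test_zero_residual_variance_flagged(self):
        data = np.column_stack([np.repeat([1.0, 0.0], 4)])
        subs = pd.DataFrame({"group": ["patient"] * 4 + ["control"] * 4})
        X, _ = build_design(subs, covariates=())
        with pytest.warns(UserWarning):
            sm = fit_group_glm(data, design=X)
        assert np.isnan(sm.p[0])

    def test_null_p_uniformity(self):
        """Under the global null, uncorrected per-unit p-values are uniform."""
        rng = np.random.default_rng(5)
        subs = pd.DataFrame({"group": np.repeat(["patient", "control"], 15)})
        ps = []
        for _ in range(50):
            sm = fit_group_glm(rng.standard_normal((30, 20)),
                               subjects=subs, covariates=())
            ps.extend(sm.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSmoothing:
    def test_fwhm_zero_identity(self, rng):
        v = rng.standard_normal((8, 8, 8))
        np.testing.assert_array_equal(smooth_volume(v, 0.0), v)

    def test_constant_volume_invariant(self):
        v = np.full((10, 10, 10), 3.7)
        np.testing.assert_allclose(smooth_volume(v, 8.0), v, atol=1e-12)

    def test_impulse_matches_analytic_kernel(self):
        n = 41
        v = np.zeros((n, n, n))
        v[n // 2, n // 2, n // 2] = 1.0
        fwhm = 6.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        out = smooth_volume(v, fwhm)
        ax = np.arange(n) - n // 2
        g1 = np.exp(-0.5 * (ax / sigma) ** 2)
        g1 /= g1.sum()  # discrete normalization, as the filter applies
        expected = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_volume(np.zeros((4, 4, 4)), -1.0)


class TestFDR:
    def test_hand_computed_stepup(self):
        """Thresholds i*q/m = .0125, .025, .0375, .05 reject exactly two."""
        reject, qv = fdr_bh(np.array([0.01, 0.02, 0.04, 0.5]), q=0.05)
        assert reject.tolist() == [True, True, False, False]

    @pytest.mark.parametrize("p,expected", [
        (np.zeros(5), 5), (np.ones(5), 0),
    ])
    def test_degenerate_inputs(self, p, expected):
        reject, _ = fdr_bh(p)
        assert reject.sum() == expected

    def test_empty_input(self):
        reject, qv = fdr_bh(np.array([]))
        assert reject.size == 0 and qv.size == 0

    def test_bh_rejects_superset_of_bonferroni(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 0.2, 30)
            bh, _ = fdr_bh(p, q=0.05)
            bonf = p < 0.05 / p.size
            assert (bh | ~bonf).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.5]))


class TestAdjustedCorrelation:
    def test_identity(self):
        x = np.arange(10.0)
        r, p = adjusted_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_matches_two_step_residual_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([0.5, 1.9, 2.1, 4.0, 5.2])
        c = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        Z = np.column_stack([np.ones(5), c])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        r_oracle = np.corrcoef(rx, ry)[0, 1]
        r, p = adjusted_correlation(x, y, covariates=c)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        df = 5 - 1 - 2
        t = r_oracle * np.sqrt(df / (1 - r_oracle**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df), abs=1e-12)

    def test_null_correlation_small(self, rng):
        hits = 0
        for _ in range(40):
            x = rng.standard_normal(1000)
            y = rng.standard_normal(1000)
            r, _ = adjusted_correlation(x, y)
            hits += abs(r) < 0.1
        assert hits >= 38

    def test_zero_residual_variance_rejected(self):
        c = np.arange(6.0)
        with pytest.raises(ValueError):
            adjusted_correlation(2 * c, np.random.default_rng(0).standard_normal(6),
                                 covariates=c)


class TestMannWhitney:
    def test_exact_enumeration_separated(self):
        U, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert U == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples_p1(self):
        U, p = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == pytest.approx(1.0)

    def test_all_tied_p1(self):
        _, p = mann_whitney([5, 5, 5], [5, 5])
        assert p == 1.0

    def test_exact_matches_scipy_without_ties(self, rng):
        a = rng.standard_normal(6)
        b = rng.standard_normal(7) + 0.5
        U, p = mann_whitney(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert U == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_close_to_exact_at_n20(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 0.3
        _, p_approx = mann_whitney(a, b)  # n > 8 -> asymptotic
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert abs(p_approx - ref.pvalue) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPermutationClusters:
    def make_null(self, seed, n=16, grid=12):
        rng = np.random.default_rng(seed)
        stack = rng.standard_normal((n, grid, grid, grid))
        subs = pd.DataFrame({"group": np.repeat(["patient", "control"], n // 2)})
        return stack, subs

    def test_planted_effect_attains_minimum_p(self):
        """A 3-sd 27-voxel effect at n = 30/30 reaches p = 1/(n_perm+1)."""
        rng = np.random.default_rng(2)
        stack = rng.standard_normal((60, 12, 12, 12))
        stack[:30, 4:7, 4:7, 4:7] += 3.0
        subs = pd.DataFrame({"group": np.repeat(["patient", "control"], 30)})
        cs = permutation_cluster_fwe(stack, subjects=subs, covariates=(),
                                     n_perm=200, seed=0)
        assert cs.clusters[0]["size"] >= 27
        assert cs.clusters[0]["p_fwe"] == pytest.approx(1 / 201)

    def test_no_suprathreshold_voxels_empty(self):
        stack = np.random.default_rng(3).standard_normal((12, 8, 8, 8)) * 1e-6
        subs = pd.DataFrame({"group": np.repeat(["patient", "control"], 6)})
        cs = permutation_cluster_fwe(stack, subjects=subs, covariates=(),
                                     forming_p=1e-12, n_perm=100, seed=0)
        assert cs.clusters == []

    def test_identity_relabeling_reproduces_observed(self):
        """Permutation machinery is consistent: the observed t-map computed
        twice from the same data yields identical clusters."""
        stack, subs = self.make_null(4)
        stack[:, 2:5, 2:5, 2:5] += np.where(
            subs["group"].to_numpy() == "patient", 2.5, 0.0)[:, None, None, None]
        a = permutation_cluster_fwe(stack, subjects=subs, covariates=(),
                                    n_perm=50, seed=9)
        b = permutation_cluster_fwe(stack, subjects=subs, covariates=(),
                                    n_perm=50, seed=9)
        assert [c["size"] for c in a.clusters] == [c["size"] for c in b.clusters]
        assert [c["p_fwe"] for c in a.clusters] == [c["p_fwe"] for c in b.clusters]

    def test_connectivity_structures_differ(self):
        """A diagonal pair of voxels is one cluster at 26- but two at
        6-connectivity."""
        tmap = np.zeros((5, 5, 5))
        tmap[1, 1, 1] = tmap[2, 2, 2] = 10.0
        lab26, n26 = ndimage.label(tmap > 5, ndimage.generate_binary_structure(3, 3))
        lab6, n6 = ndimage.label(tmap > 5, ndimage.generate_binary_structure(3, 1))
        assert n26 == 1 and n6 == 2
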