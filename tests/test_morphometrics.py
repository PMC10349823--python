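"""Bill-size composites, centroid size, relative size, and shape rarity."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import boxcox_normmax

from thermomorph.morphometrics import (
    BILL_COLUMNS,
    bill_size_pc1,
    boxcox_mle,
    boxcox_transform,
    centroid_size,
    kde2d_density,
    phylo_pca_pc1,
    relative_bill_size,
    specialization_scores,
)
from thermomorph.phylo import PhyloCovariance, phylo_vcv, scale_unit_height, simulate_pure_birth


class TestBoxCox:
    def test_lognormal_lambda_near_zero(self):
        x = np.random.default_rng(1).lognormal(0.0, 0.5, 10_000)
        assert abs(boxcox_mle(x)) < 0.1

    def test_normal_lambda_near_one(self):
        x = np.random.default_rng(2).normal(5.0, 1.0, 10_000)
        assert abs(boxcox_mle(x) - 1.0) < 0.1

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_scipy_mle_oracle(self, seed):
        x = np.random.default_rng(seed).gamma(2.0, 3.0, 2_000)
        assert boxcox_mle(x) == pytest.approx(boxcox_normmax(x, method="mle"), abs=1e-3)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            boxcox_mle(np.full(100, 2.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            boxcox_mle(np.array([1.0, -1.0, 2.0, 3.0, 4.0]))

    @pytest.mark.parametrize(
        "x,lam,expected",
        [(2.0, 1.0, 1.0), (np.e, 0.0, 1.0), (4.0, 0.5, 2.0)],
    )
    def test_transform_closed_forms(self, x, lam, expected):
        assert boxcox_transform(np.array([x]), lam)[0] == pytest.approx(expected)

    def test_transform_continuous_at_zero(self):
        x = np.array([0.5, 1.0, 2.0, 5.0])
        np.testing.assert_allclose(
            boxcox_transform(x, 1e-9), np.log(x), atol=1e-6
        )


class TestBillPca:
    def _frame(self, arr):
        return pd.DataFrame(arr, columns=BILL_COLUMNS)

    def test_identical_columns_explain_everything(self):
        col = np.random.default_rng(0).lognormal(1, 0.3, 100)
        res = bill_size_pc1(self._frame(np.column_stack([col] * 4)))
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_independent_columns_explain_quarter(self):
        rng = np.random.default_rng(1)
        res = bill_size_pc1(self._frame(rng.lognormal(1, 0.3, (20_000, 4))))
        assert res.variance_explained[0] == pytest.approx(0.25, abs=0.02)

    def test_equicorrelated_loadings_match_closed_form(self):
        """For an equicorrelated correlation matrix the top eigenvector is 1/√p."""
        rng = np.random.default_rng(2)
        common = rng.normal(size=5_000)
        arr = np.exp(1 + np.column_stack([common + rng.normal(0, 0.6, 5_000) for _ in range(4)]))
        res = bill_size_pc1(self._frame(arr))
        np.testing.assert_allclose(res.loadings["PC1"], 0.5, atol=0.02)

    def test_pc1_loadings_all_positive(self):
        rng = np.random.default_rng(3)
        common = rng.normal(size=500)
        arr = np.exp(1 + np.column_stack([common + rng.normal(0, 0.5, 500) for _ in range(4)]))
        res = bill_size_pc1(self._frame(arr))
        assert (res.loadings["PC1"] > 0).all()

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bill_size_pc1(self._frame(np.ones((3, 4))))


class TestPhyloPca:
    def test_star_tree_equals_ordinary_pca(self):
        rng = np.random.default_rng(4)
        n = 60
        common = rng.normal(size=n)
        arr = np.exp(1 + np.column_stack([common + rng.normal(0, 0.4, n) for _ in range(4)]))
        df = pd.DataFrame(arr, columns=BILL_COLUMNS, index=[f"s{i}" for i in range(n)])
        star = PhyloCovariance(list(df.index), np.eye(n))
        ordinary = bill_size_pc1(df)
        phylo = phylo_pca_pc1(df, star)
        np.testing.assert_allclose(phylo.pc1, ordinary.pc1, atol=1e-8)

    def test_brownian_data_highly_correlated_with_ordinary(self):
        """With dominant shared-size signal the two PC1s agree almost exactly."""
        tree = simulate_pure_birth(80, seed=6)
        vcv = scale_unit_height(phylo_vcv(tree))
        rng = np.random.default_rng(7)
        L = np.linalg.cholesky(vcv.matrix + 1e-9 * np.eye(80))
        size = L @ rng.standard_normal(80)  # Brownian common factor
        arr = np.exp(
            1.0 + np.column_stack([size + rng.normal(0, 0.2, 80) for _ in range(4)])
        )
        df = pd.DataFrame(arr, columns=BILL_COLUMNS, index=vcv.labels)
        r = np.corrcoef(bill_size_pc1(df).pc1, phylo_pca_pc1(df, vcv).pc1)[0, 1]
        assert abs(r) > 0.99

    def test_label_mismatch_rejected(self):
        df = pd.DataFrame(
            np.ones((3, 4)) + np.eye(3, 4), columns=BILL_COLUMNS, index=["a", "b", "c"]
        )
        vcv = PhyloCovariance(["a", "b", "x"], np.eye(3))
        with pytest.raises(KeyError):
            phylo_pca_pc1(df, vcv, apply_boxcox=False)


class TestCentroidSize:
    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert centroid_size(square, expected_landmarks=None) == pytest.approx(np.sqrt(2))

    def test_degenerate_configuration(self):
        assert centroid_size(np.ones((79, 3))) == 0.0

    def test_homogeneous_scaling(self):
        rng = np.random.default_rng(8)
        config = rng.normal(size=(79, 3))
        assert centroid_size(config * 2.5) == pytest.approx(2.5 * centroid_size(config))

    def test_wrong_landmark_count(self):
        with pytest.raises(ValueError, match="79"):
            centroid_size(np.ones((10, 3)))


class TestRelativeBillSize:
    def test_exact_quadratic_gives_zero_residuals(self):
        rng = np.random.default_rng(9)
        m = rng.normal(4, 1, 40)
        bill = 1.0 + 0.4 * m - 0.02 * m**2
        r = relative_bill_size(bill, m, np.eye(40))
        np.testing.assert_allclose(r, 0.0, atol=1e-8)

    def test_star_tree_matches_ols(self):
        rng = np.random.default_rng(10)
        m = rng.normal(4, 1, 60)
        bill = 0.4 * m - 0.02 * m**2 + rng.normal(0, 0.2, 60)
        r = relative_bill_size(bill, m, np.eye(60))
        ols_resid = bill - np.polyval(np.polyfit(m, bill, 2), m)
        np.testing.assert_allclose(r, ols_resid, atol=1e-6)

    def test_shift_invariance(self):
        rng = np.random.default_rng(11)
        m = rng.normal(4, 1, 30)
        bill = 0.3 * m + rng.normal(0, 0.2, 30)
        tree = simulate_pure_birth(30, seed=12)
        vcv = scale_unit_height(phylo_vcv(tree))
        r1 = relative_bill_size(bill, m, vcv)
        r2 = relative_bill_size(bill + 7.0, m, vcv)
        np.testing.assert_allclose(r1, r2, atol=1e-6)


class TestSpecialization:
    def test_outlier_has_lowest_density(self):
        rng = np.random.default_rng(12)
        cluster = rng.normal(0, 0.1, size=(30, 2))
        pts = np.vstack([cluster, [[5.0, 5.0]]])
        dens = kde2d_density(pts)
        assert dens[-1] < dens[:-1].min()

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(150, 2))
        xs = np.linspace(-6, 6, 241)
        X, Y = np.meshgrid(xs, xs)
        dens = kde2d_density(pts, np.column_stack([X.ravel(), Y.ravel()])).reshape(X.shape)
        integral = np.trapezoid(np.trapezoid(dens, xs, axis=1), xs)
        assert integral == pytest.approx(1.0, abs=0.01)

    def test_rescaling_divides_density_by_scale_squared(self):
        rng = np.random.default_rng(14)
        pts = rng.normal(size=(80, 2))
        d1 = kde2d_density(pts)
        d2 = kde2d_density(2.0 * pts)
        np.testing.assert_allclose(d2, d1 / 4.0, rtol=1e-10)

    def test_matches_statsmodels_oracle(self):
        from statsmodels.nonparametric.kernel_density import KDEMultivariate

        rng = np.random.default_rng(15)
        pts = rng.normal(size=(120, 2))
        ours = kde2d_density(pts)
        sm = KDEMultivariate(pts, var_type="cc", bw=pts.std(axis=0, ddof=1) * 120 ** (-1 / 6))
        np.testing.assert_allclose(ours, sm.pdf(pts), rtol=1e-8)

    def test_family_means(self):
        rng = np.random.default_rng(16)
        pts = pd.DataFrame(rng.normal(size=(40, 2)), columns=["PC1", "PC2"])
        fams = ["f1"] * 20 + ["f2"] * 20
        sp, fam = specialization_scores(pts, fams)
        assert fam["f1"] == pytest.approx(sp.iloc[:20].mean())
        assert (sp >= 0).all()

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kde2d_density(np.random.default_rng(0).normal(size=(10, 2)))
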