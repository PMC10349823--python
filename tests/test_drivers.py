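"""Family-trait assembly, randomization tests, and intensity regressions."""

import numpy as np
import pandas as pd
import pytest

from thermomorph.drivers import (
    build_family_traits,
    conformance_intensity_gls,
    randomization_test,
)
from thermomorph.phylo import PhyloCovariance, phylo_vcv, scale_unit_height, simulate_pure_birth


class TestBuildFamilyTraits:
    def hand_data(self):
        species = pd.DataFrame(
            {
                "species": [f"s{i}" for i in range(5)],
                "family": ["A", "A", "A", "B", "B"],
                "temperature_c": [0.0, 10.0, 5.0, 20.0, 20.0],
                "ln_body_mass_g": [3.0, 4.0, 5.0, 2.0, 4.0],
            }
        )
        bill = pd.Series([1.0, 2.0, 3.0, 0.5, 1.5])
        rel = pd.Series([0.1, -0.1, 0.3, 0.0, 0.2])
        dens = pd.Series({"A": 0.25, "B": 0.5})
        return species, bill, rel, dens

    def test_hand_computed_means(self):
        species, bill, rel, dens = self.hand_data()
        t = build_family_traits(species, bill, rel, dens)
        assert t.loc["A", "mean_ln_body_mass"] == pytest.approx(4.0)
        assert t.loc["A", "mean_bill_size"] == pytest.approx(2.0)
        assert t.loc["A", "mean_relative_bill_size"] == pytest.approx(0.1)
        assert t.loc["A", "temperature_range"] == pytest.approx(10.0)
        assert t.loc["B", "temperature_range"] == 0.0  # all at one temperature
        assert t.loc["A", "ln_n_species"] == pytest.approx(np.log(3))
        assert t.loc["B", "mean_kernel_density"] == 0.5

    def test_ten_species_family_ln_n(self):
        species = pd.DataFrame(
            {
                "family": ["X"] * 10 + ["Y"] * 3,
                "temperature_c": np.arange(13.0),
                "ln_body_mass_g": np.ones(13),
            }
        )
        t = build_family_traits(
            species,
            pd.Series(np.ones(13)),
            pd.Series(np.zeros(13)),
            pd.Series({"X": 1.0, "Y": 1.0}),
        )
        assert t.loc["X", "ln_n_species"] == pytest.approx(2.302585, abs=1e-6)

    def test_missing_density_listed(self):
        species, bill, rel, dens = self.hand_data()
        with pytest.raises(KeyError, match="B"):
            build_family_traits(species, bill, rel, dens.drop("B"))


class TestRandomization:
    def make(self, n=30):
        idx = [f"f{i}" for i in range(n)]
        cats = pd.Series(
            ["bergmann"] * 5 + ["allen"] * 5 + ["neither"] * (n - 10), index=idx
        )
        return idx, cats

    def test_perfectly_sorted_trait_is_extreme(self):
        idx, _ = self.make()
        cats = pd.Series(["neither"] * 25 + ["bergmann"] * 5, index=idx)
        traits = pd.DataFrame({"mean_ln_body_mass": np.arange(30.0)}, index=idx)
        res = randomization_test(traits, cats, n_iter=1000, seed=1)
        by_cat = {r.category: r for r in res}
        assert by_cat["bergmann"].p <= 0.001
        assert by_cat["bergmann"].significant

    def test_observed_equal_to_null_mean_gives_half(self):
        # rank pairs (i, 29−i) give both categories the exact grand mean 14.5
        idx = [f"f{i}" for i in range(28)]
        vals = np.arange(1.0, 29.0)
        pair = np.minimum(vals, 29 - vals)  # 1..14, one pair per value
        cats = pd.Series(np.where(pair <= 7, "a", "b"), index=idx)
        traits = pd.DataFrame({"mean_ln_body_mass": vals}, index=idx)
        res = randomization_test(traits, cats, n_iter=4000, seed=2)
        for r in res:
            assert r.observed_mean == pytest.approx(14.5)
            assert r.p == pytest.approx(0.5, abs=0.1)

    def test_determinism(self):
        idx, cats = self.make()
        traits = pd.DataFrame(
            {"mean_ln_body_mass": np.random.default_rng(3).normal(size=30)}, index=idx
        )
        a = randomization_test(traits, cats, seed=9)
        b = randomization_test(traits, cats, seed=9)
        assert [(r.p, r.observed_mean) for r in a] == [(r.p, r.observed_mean) for r in b]

    def test_p_invariant_to_category_relabeling(self):
        idx, cats = self.make()
        traits = pd.DataFrame(
            {"mean_ln_body_mass": np.random.default_rng(4).normal(size=30)}, index=idx
        )
        res1 = randomization_test(traits, cats, seed=5)
        relabeled = cats.map({"bergmann": "zzz", "allen": "mmm", "neither": "aaa"})
        res2 = randomization_test(traits, relabeled, seed=5)
        remap = {"zzz": "bergmann", "mmm": "allen", "aaa": "neither"}
        p1 = {r.category: r.p for r in res1}
        p2 = {remap[r.category]: r.p for r in res2}
        assert p1 == p2

    def test_p_converges_at_large_n_iter(self):
        idx, cats = self.make()
        traits = pd.DataFrame(
            {"mean_ln_body_mass": np.random.default_rng(6).normal(size=30)}, index=idx
        )
        a = randomization_test(traits, cats, n_iter=10_000, seed=11)
        b = randomization_test(traits, cats, n_iter=10_000, seed=12)
        for ra, rb in zip(a, b):
            assert abs(ra.p - rb.p) < 0.01

    def test_single_category_rejected(self):
        idx, _ = self.make()
        traits = pd.DataFrame({"mean_ln_body_mass": np.ones(30)}, index=idx)
        with pytest.raises(ValueError):
            randomization_test(traits, pd.Series(["only"] * 30, index=idx))


class TestIntensityGls:
    def synthetic(self, n=100, seed=0, effect=0.02, lam_truth=0.0):
        rng = np.random.default_rng(seed)
        idx = [f"f{i}" for i in range(n)]
        traits = pd.DataFrame(
            {
                "mean_ln_body_mass": rng.normal(4, 1, n),
                "mean_relative_bill_size": rng.normal(0, 0.3, n),
                "temperature_range": rng.uniform(5, 35, n),
                "ln_n_species": rng.uniform(2.3, 5, n),
                "mean_kernel_density": rng.uniform(0.01, 0.3, n),
            },
            index=idx,
        )
        strength = effect * traits["mean_ln_body_mass"] + rng.normal(0, 0.02, n)
        slopes = pd.Series(-strength.to_numpy(), index=idx)  # body slope (negative)
        vcv = PhyloCovariance(idx, np.eye(n))
        return slopes, traits, vcv

    def test_star_tree_matches_ols(self):
        slopes, traits, vcv = self.synthetic(seed=1)
        table = conformance_intensity_gls(slopes, traits, vcv, rule="bergmann", lam=0.0)
        X = np.column_stack([np.ones(len(traits)), traits.to_numpy()])
        coef, *_ = np.linalg.lstsq(X, -slopes.to_numpy(), rcond=None)
        np.testing.assert_allclose(table["coef"].to_numpy(), coef, atol=1e-6)

    def test_positive_mass_effect_recovered(self):
        """Bigger-bodied families show stronger Bergmann signal by construction."""
        slopes, traits, vcv = self.synthetic(seed=2, effect=0.02)
        table = conformance_intensity_gls(slopes, traits, vcv, rule="bergmann")
        row = table.loc["mean_ln_body_mass"]
        assert row["coef"] > 0
        assert row["coef"] / row["se"] > 2

    def test_constant_response(self):
        slopes, traits, vcv = self.synthetic(seed=3)
        const = pd.Series(np.full(len(slopes), -0.42), index=slopes.index)
        table = conformance_intensity_gls(const, traits, vcv, rule="bergmann", lam=0.0)
        np.testing.assert_allclose(table["coef"].iloc[1:], 0.0, atol=1e-8)
        assert table["coef"].iloc[0] == pytest.approx(0.42)

    def test_allen_model_uses_bill_size(self):
        slopes, traits, vcv = self.synthetic(seed=4)
        traits["mean_bill_size"] = np.random.default_rng(5).normal(1, 0.5, len(traits))
        table = conformance_intensity_gls(slopes, traits, vcv, rule="allen")
        assert "mean_bill_size" in table.index
        assert "mean_ln_body_mass" not in table.index

    def test_lambda_estimated_on_phylogenetic_data(self):
        """Residuals simulated on the tree push λ̂ toward 1."""
        n = 60
        tree = simulate_pure_birth(n, seed=13)
        vcv = scale_unit_height(phylo_vcv(tree))
        rng = np.random.default_rng(14)
        idx = vcv.labels
        traits = pd.DataFrame(
            {
                "mean_ln_body_mass": rng.normal(4, 1, n),
                "temperature_range": rng.uniform(5, 35, n),
                "ln_n_species": rng.uniform(2.3, 5, n),
            },
            index=idx,
        )
        L = np.linalg.cholesky(vcv.matrix + 1e-10 * np.eye(n))
        phylo_resid = L @ rng.standard_normal(n)
        slopes = pd.Series(-(0.02 * traits["mean_ln_body_mass"] + 0.1 * phylo_resid), index=idx)
        table = conformance_intensity_gls(slopes, traits, vcv, rule="bergmann")
        assert table.attrs["lambda"] > 0.5

    def test_too_few_families(self):
        slopes, traits, vcv = self.synthetic(n=5)
        with pytest.raises(ValueError, match="at least 10"):
            conformance_intensity_gls(slopes, traits, vcv)

    def test_perfect_collinearity_rejected(self):
        slopes, traits, vcv = self.synthetic(seed=6)
        traits["mean_relative_bill_size"] = 2.0 * traits["mean_ln_body_mass"]
        with pytest.raises(np.linalg.LinAlgError):
            conformance_intensity_gls(slopes, traits, vcv, rule="bergmann")
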