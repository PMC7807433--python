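import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from coobnet.composition import (
    aitchison_distance,
    aldex_effect,
    clr_transform,
    czm_impute,
    diet_node_summary,
    pca_biplot,
    permanova,
)


class TestCZM:
    def test_zero_free_input_is_closure(self):
        x = np.array([[2, 3, 5], [1, 1, 2]])
        comp = czm_impute(x)
        assert np.allclose(comp[0], [0.2, 0.3, 0.5])
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_multiplicative_formula(self):
        # sample (0, 9, 1), depth 10, label 0.65:
        # zero -> 0.65/10 = 0.065; nonzeros scaled by (1 - 0.065)
        comp = czm_impute(np.array([[0, 9, 1]]), label=0.65)
        assert comp[0, 0] == pytest.approx(0.065)
        assert comp[0, 1] == pytest.approx(0.9 * 0.935)
        assert comp[0, 2] == pytest.approx(0.1 * 0.935)

    def test_output_strictly_positive_rows_sum_one(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, (10, 20))
        x[:, 0] += 1  # no all-zero sample
        comp = czm_impute(x)
        assert comp.min() > 0
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            czm_impute(np.array([[0, 0, 0]]))


class TestClr:
    def test_uniform_row_maps_to_zero(self):
        assert np.allclose(clr_transform(np.array([[0.25] * 4])), 0.0)

    def test_two_part_closed_form(self):
        out = clr_transform(np.array([[1.0, 8.0]]))
        assert out[0, 0] == pytest.approx(-np.log(8) / 2)
        assert out[0, 1] == pytest.approx(np.log(8) / 2)
        assert out[0, 1] == pytest.approx(1.0397, abs=1e-4)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(1)
        x = rng.random((20, 15)) + 0.01
        assert np.allclose(clr_transform(x).sum(axis=1), 0.0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.random((5, 8)) + 0.1
        assert np.allclose(clr_transform(x), clr_transform(x * 37.5))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            clr_transform(np.array([[0.0, 1.0]]))


class TestPCA:
    def test_collinear_samples_single_component(self):
        base = np.array([1.0, -2.0, 1.0, 0.0])
        clr = np.vstack([k * base for k in range(5)])
        pca = pca_biplot(clr)
        assert pca.explained_variance[0] == pytest.approx(1.0)

    def test_score_distances_equal_aitchison(self):
        rng = np.random.default_rng(3)
        comp = rng.random((10, 6)) + 0.05
        comp = comp / comp.sum(axis=1, keepdims=True)
        clr = clr_transform(comp)
        pca = pca_biplot(clr)
        d_scores = squareform(pdist(pca.sample_scores.values))
        assert np.allclose(d_scores, aitchison_distance(clr), atol=1e-8)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(4)
        clr = rng.normal(size=(12, 7))
        a = pca_biplot(clr)
        b = pca_biplot(clr.copy())
        assert np.allclose(a.sample_scores.values, b.sample_scores.values)
        load = a.otu_loadings.values
        top = np.argmax(np.abs(load), axis=0)
        assert all(load[top[k], k] > 0 for k in range(load.shape[1]))

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pca_biplot(np.ones((1, 4)))


class TestPermanova:
    def gaussian_clusters(self, delta, seed=0, n=10, nested=False):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n, 4))
        b = rng.normal(delta, 1, (n, 4))
        X = np.vstack([a, b])
        labels = np.array(["g1"] * n + ["g2"] * n)
        species = np.array(
            [f"{g}_sp{i % 2}" for i, g in enumerate(labels)]
        )
        d = squareform(pdist(X))
        return d, labels, species

    def test_separated_clusters_min_p(self):
        d, labels, _ = self.gaussian_clusters(delta=50.0)
        res = permanova(d, labels, n_perm=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_sample_order_invariance_of_f(self):
        d, labels, _ = self.gaussian_clusters(delta=2.0)
        perm = np.random.default_rng(0).permutation(len(labels))
        res1 = permanova(d, labels, n_perm=49, seed=0)
        res2 = permanova(d[np.ix_(perm, perm)], labels[perm], n_perm=49, seed=0)
        assert res1.pseudo_f == pytest.approx(res2.pseudo_f)

    def test_r_squared_components_sum_to_one(self):
        d, labels, species = self.gaussian_clusters(delta=1.0)
        res = permanova(d, labels, species, n_perm=49, seed=0)
        assert sum(res.r_squared.values()) == pytest.approx(1.0)
        assert set(res.r_squared) == {"primary", "nested", "residual"}

    def test_matches_scikit_bio_one_factor(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

        d, labels, _ = self.gaussian_clusters(delta=1.5, seed=2)
        ours = permanova(d, labels, n_perm=99, seed=0)
        theirs = sk_permanova(
            DistanceMatrix(d), grouping=list(labels), permutations=99
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_not_nested_rejected(self):
        d, labels, _ = self.gaussian_clusters(delta=1.0)
        bad_species = np.array(["s1"] * len(labels))  # spans both diets
        with pytest.raises(ValueError, match="nested"):
            permanova(d, labels, bad_species)

    def test_singleton_level_rejected(self):
        d = squareform(pdist(np.random.default_rng(0).normal(size=(5, 3))))
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "a", "a", "b"])

    def test_pairwise_contrasts_cover_level_pairs(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(k * 3, 1, (6, 3)) for k in range(3)])
        labels = np.repeat(["a", "b", "c"], 6)
        d = squareform(pdist(X))
        res = permanova(d, labels, n_perm=99, seed=0, pairwise=True)
        assert len(res.pairwise) == 3
        assert "q" in res.pairwise.columns

    def test_block_permutation_strategy_runs(self):
        d, labels, species = self.gaussian_clusters(delta=1.0)
        res = permanova(d, labels, species, n_perm=49, seed=0, strategy="blocks")
        assert 0 < res.p_value <= 1


class TestAldexEffect:
    def planted_counts(self, shift, seed=0, n_per=25, n_otus=80):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(2, 1, n_otus)
        rows = []
        labels = []
        for g, mult in (("c", 1.0), ("h", shift)):
            for _ in range(n_per):
                mean = base.copy()
                mean[:5] *= mult if g == "h" else 1.0
                p = mean * rng.lognormal(0, 0.4, n_otus)
                p = p / p.sum()
                rows.append(rng.multinomial(20000, p))
                labels.append(g)
        return np.array(rows), np.array(labels)

    def test_null_effects_small(self):
        vals = []
        for seed in range(5):
            counts, labels = self.planted_counts(1.0, seed=seed, n_per=20, n_otus=40)
            eff = aldex_effect(counts, labels, n_mc=32, seed=seed)
            vals.append(np.median(np.abs(eff["effect"])))
        assert np.median(vals) < 0.2

    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(5):
            counts, labels = self.planted_counts(8.0, seed=seed)
            eff = aldex_effect(counts, labels, levels=("c", "h"), n_mc=64, seed=seed)
            planted = eff.iloc[:5]
            if (planted["effect"] > 1).all() and (planted["welch_q"] < 0.05).all():
                hits += 1
        assert hits >= 4

    def test_label_swap_negates_effect(self):
        counts, labels = self.planted_counts(4.0, seed=1, n_per=10, n_otus=30)
        a = aldex_effect(counts, labels, levels=("c", "h"), n_mc=16, seed=7)
        b = aldex_effect(counts, labels, levels=("h", "c"), n_mc=16, seed=7)
        assert np.allclose(a["effect"].values, -b["effect"].values)
        assert np.allclose(a["diff_btw"].values, -b["diff_btw"].values)

    def test_deterministic_given_seed(self):
        counts, labels = self.planted_counts(2.0, seed=2, n_per=8, n_otus=20)
        a = aldex_effect(counts, labels, n_mc=16, seed=3)
        b = aldex_effect(counts, labels, n_mc=16, seed=3)
        assert a.equals(b)

    def test_singleton_group_rejected(self):
        counts = np.random.default_rng(0).integers(1, 50, (4, 10))
        with pytest.raises(ValueError):
            aldex_effect(counts, ["a", "b", "b", "b"])


class TestDietNodeSummary:
    def test_all_equal_composition_all_hollow(self, net_factory):
        net = net_factory([("O1", "O2", "copresence")])
        clr = pd.DataFrame(
            np.zeros((4, 3)), index=list("abcd"), columns=["O1", "O2", "O3"]
        )
        groups = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        out = diet_node_summary(clr, groups, net)
        assert not out["filled"].any()
        assert np.allclose(out["median_clr"], 0.0)

    def test_single_sample_group_median_is_that_sample(self, net_factory):
        net = net_factory([("O1", "O2", "copresence")])
        clr = pd.DataFrame(
            [[1.5, -1.5], [0.2, -0.2]], index=["a", "b"], columns=["O1", "O2"]
        )
        groups = pd.Series(["solo", "other"], index=["a", "b"])
        out = diet_node_summary(clr, groups, net)
        solo = out[(out["group"] == "solo") & (out["otu_id"] == "O1")]
        assert solo["median_clr"].iloc[0] == pytest.approx(1.5)
        assert bool(solo["filled"].iloc[0])

    def test_missing_node_rejected(self, net_factory):
        net = net_factory([("O1", "OX", "copresence")])
        clr = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["O1", "O2"])
        with pytest.raises(ValueError, match="OX"):
            diet_node_summary(clr, pd.Series(["x", "y"], index=["a", "b"]), net)
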