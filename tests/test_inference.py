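import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coobnet.datatypes import COPRESENCE, EXCLUSION
from coobnet.inference import (
    CoOccurrenceModel,
    MEASURES,
    bh_adjust,
    brown_merge,
    build_network,
    merge_and_adjust,
    pairwise_association_scores,
    reboot_significance,
    select_candidate_edges,
    symmetrized_kl,
)


def score_all(matrix):
    return {m: pairwise_association_scores(matrix, m) for m in MEASURES}


class TestMeasures:
    def test_linear_pair_has_perfect_correlations(self):
        x = np.array([[1.0, 2, 3, 4], [2.0, 4, 6, 8], [5.0, 1, 4, 2]])
        pear = pairwise_association_scores(x, "pearson").values
        spear = pairwise_association_scores(x, "spearman").values
        assert pear[0, 1] == pytest.approx(1.0)
        assert spear[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_extremes(self):
        x = np.array([[1.0, 0, 1, 0], [0.0, 1, 0, 1], [1.0, 0, 1, 0]])
        bc = pairwise_association_scores(x, "bray_curtis").values
        assert bc[0, 1] == pytest.approx(1.0)  # disjoint support
        assert bc[0, 2] == pytest.approx(0.0)  # identical rows

    def test_symmetrized_kl_closed_form(self):
        # D = (KL(p||q) + KL(q||p)) / 2 for p=(.5,.5), q=(.9,.1)
        d = symmetrized_kl([0.5, 0.5], [0.9, 0.1], eps_frac=0.0)
        kl_pq = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        kl_qp = 0.9 * np.log(0.9 / 0.5) + 0.1 * np.log(0.1 / 0.5)
        assert d == pytest.approx(0.5 * (kl_pq + kl_qp))
        assert d == pytest.approx(0.4394, abs=1e-4)

    def test_constant_row_correlation_undefined(self):
        x = np.array([[1.0, 1, 1, 1], [1.0, 2, 3, 4]])
        pear = pairwise_association_scores(x, "pearson").values
        assert np.isnan(pear[0, 1])

    def test_score_matrices_symmetric(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 12))
        for m in MEASURES:
            v = pairwise_association_scores(x, m).values
            assert np.allclose(v, v.T, equal_nan=True)

    def test_sample_relabeling_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.random((5, 15))
        perm = rng.permutation(15)
        for m in MEASURES:
            a = pairwise_association_scores(x, m).values
            b = pairwise_association_scores(x[:, perm], m).values
            assert np.allclose(a, b, equal_nan=True)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pairwise_association_scores(np.ones((3, 3)), "pearson")


class TestCandidateSelection:
    def toy_matrix(self, seed=0):
        """3 OTUs over 40 samples; pair (0,1) strongly coupled, the
        third OTU mildly and positively coupled to both (so no pair
        qualifies as a mutual exclusion)."""
        rng = np.random.default_rng(seed)
        base = rng.lognormal(0, 0.3, 40)
        u = base * rng.lognormal(0, 0.05, 40)
        v = base * rng.lognormal(0, 0.05, 40)
        w = base ** 0.4 * rng.lognormal(0, 0.2, 40)
        return np.vstack([u, v, w])

    def test_dominant_pair_selected_alone(self):
        x = self.toy_matrix()
        # brute-force check that (0,1) tops every measure's copresence rank
        cands = select_candidate_edges(score_all(x), ["A", "B", "C"], n_top=1)
        assert len(cands) == 1
        assert (cands[0].otu_a, cands[0].otu_b) == ("A", "B")
        assert cands[0].direction == COPRESENCE

    def test_large_n_top_intersects_on_direction_only(self):
        x = self.toy_matrix()
        cands = select_candidate_edges(score_all(x), ["A", "B", "C"], n_top=1000)
        # every pair consistently directed in all measures is a candidate
        assert any((c.otu_a, c.otu_b) == ("A", "B") for c in cands)

    def test_copresence_only_mode_excludes_exclusions(self):
        rng = np.random.default_rng(2)
        x = rng.random((6, 30))
        cands = select_candidate_edges(
            score_all(x), list("ABCDEF"), n_top=1000, mode="copresence_only"
        )
        assert all(c.direction == COPRESENCE for c in cands)

    def test_invalid_n_top_rejected(self):
        with pytest.raises(ValueError):
            select_candidate_edges(score_all(np.ones((2, 4))), ["A", "B"], n_top=0)

    def test_composite_row_never_candidate(self):
        x = self.toy_matrix()
        eligible = np.array([True, True, False])
        cands = select_candidate_edges(
            score_all(x), ["A", "B", "__filtered_sum__"], n_top=1000,
            eligible=eligible,
        )
        assert all("__filtered_sum__" not in (c.otu_a, c.otu_b) for c in cands)


def exhaustive_monotone_p(u, v, col_sums):
    """Oracle: exact one-sided Spearman permutation p with the same
    permute-one-row-and-renormalize null, enumerated over all n! shuffles."""
    n = len(u)
    obs = stats.spearmanr(u, v).statistic
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        up = u[list(perm)]
        s = col_sums - u + up
        r = stats.spearmanr(up / s, v / s).statistic
        if r >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


class TestReboot:
    def monotone_matrix(self):
        u = np.array([0.10, 0.15, 0.20, 0.25, 0.30])
        v = np.array([0.05, 0.10, 0.20, 0.30, 0.40])
        rest = 1.0 - u - v
        return np.vstack([u, v, rest])

    def test_exhaustive_permutation_oracle_agreement(self):
        x = self.monotone_matrix()
        p_exact = exhaustive_monotone_p(x[0], x[1], x.sum(axis=0))
        assert p_exact == pytest.approx(1 / 120, abs=1e-9)
        cands = select_candidate_edges(score_all(x), ["u", "v", "r"], n_top=1)
        (cand,) = [c for c in cands if (c.otu_a, c.otu_b) == ("u", "v")]
        reboot_significance(x, [cand], n_perm=1000, n_boot=100, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / 1000)
        assert abs(cand.p_values["spearman"] - p_exact) <= 3 * se + 1e-3

    def test_null_pair_p_values_not_extreme(self):
        # independent rows, candidacy imposed (not selected on the data):
        # one-sided permutation p should average near 1/2
        from coobnet.inference import CandidateEdge, align_scores

        ps = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.lognormal(0, 0.5, (3, 40))
            x = x / x.sum(axis=0)
            scores = score_all(x)
            raw = {m: float(scores[m].values[0, 1]) for m in MEASURES}
            al = {m: float(align_scores(m, raw[m])) for m in MEASURES}
            cand = CandidateEdge(
                0, 1, "a", "b", COPRESENCE, raw, al,
                float(np.mean(list(al.values()))),
            )
            reboot_significance(x, [cand], n_perm=200, n_boot=50, seed=seed)
            ps.append(cand.p_values["pearson"])
        assert 0.25 < np.mean(ps) < 0.75

    def test_strong_pair_is_stable(self):
        stable = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = rng.lognormal(0, 0.5, 60)
            x = np.vstack(
                [base * rng.lognormal(0, 0.03, 60),
                 base * rng.lognormal(0, 0.03, 60),
                 rng.lognormal(0, 0.5, 60)]
            )
            x = x / x.sum(axis=0)
            cands = select_candidate_edges(score_all(x), ["a", "b", "c"], n_top=1)
            reboot_significance(x, cands, n_perm=300, n_boot=300, seed=seed)
            if cands and cands[0].stable:
                stable += 1
        assert stable >= 9

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            reboot_significance(np.ones((2, 5)), [], n_perm=10)


class TestBrownMerge:
    def test_zero_covariance_equals_fisher(self):
        p = [0.05, 0.05]
        merged = brown_merge(p, cov=np.zeros((2, 2)))
        x = -2 * np.sum(np.log(p))
        fisher = float(stats.chi2.sf(x, 4))
        assert merged == fisher  # machine precision: identical code path
        assert merged == pytest.approx(np.exp(-x / 2) * (1 + x / 2))
        assert merged == pytest.approx(0.0175, abs=5e-4)

    def test_fully_dependent_returns_common_p(self):
        # analytic limit: cov_ij = 4 for all pairs -> c = k, k' = 2
        for p0 in (0.01, 0.2, 0.7):
            cov = np.full((4, 4), 4.0)
            merged = brown_merge([p0] * 4, cov=cov)
            assert merged == pytest.approx(p0, rel=1e-10)

    def test_single_p_passthrough(self):
        assert brown_merge([0.123]) == 0.123

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            merged = brown_merge([0.0, 0.05], n_perm=999)
        assert 0 < merged < 1

    def test_empirical_null_covariance_path(self):
        rng = np.random.default_rng(0)
        base = rng.random(500)
        nulls = np.vstack([base, np.clip(base + rng.normal(0, 0.05, 500), 1e-3, 1)])
        merged = brown_merge([0.02, 0.02], null_pvals=nulls)
        fisher = float(stats.chi2.sf(-2 * np.log(0.02) * 2, 4))
        assert merged > fisher  # dependence discounts the evidence


class TestBHAdjust:
    def test_step_up_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_m_total_matches_padding_with_ones(self):
        p = [0.001, 0.01, 0.04]
        q_direct = bh_adjust(p, m_total=10)
        q_padded = bh_adjust(list(p) + [1.0] * 7)[:3]
        assert np.allclose(q_direct, q_padded)


class TestBuildNetwork:
    def fake_candidates(self):
        from coobnet.inference import CandidateEdge

        mk = lambda a, b, q, stable: CandidateEdge(
            0, 1, a, b, COPRESENCE, {}, {}, 0.5, {}, stable, q / 2, q
        )
        return [mk("a", "b", 0.01, True), mk("a", "c", 0.002, True),
                mk("b", "d", 0.2, True), mk("c", "d", 0.01, False)]

    def test_alpha_and_stability_filters(self):
        net = build_network(self.fake_candidates(), alpha=0.05)
        assert net.edge_keys() == {
            ("a", "b", COPRESENCE), ("a", "c", COPRESENCE)
        }
        assert "d" not in net.node_ids  # isolated OTUs absent

    def test_all_insignificant_gives_empty_network(self):
        net = build_network(self.fake_candidates(), alpha=0.0001)
        assert net.n_edges == 0 and net.n_nodes == 0


class TestModelEndToEnd:
    def test_planted_recovery_single_seed(self):
        from coobnet.simulate import (
            GroupSpec, PlantedPair, SimConfig, disjoint_pairs,
            generate_community, ground_truth_eval,
        )

        rng = np.random.default_rng(42)
        idx = disjoint_pairs(50, 8, rng)
        pairs = [PlantedPair(a, b, 0.8) for a, b in idx]
        cfg = SimConfig(
            n_otus=50, groups=[GroupSpec("L", "Africa", 80)],
            planted_pairs=pairs, seed=42,
        )
        table, _, truth = generate_community(cfg)
        model = CoOccurrenceModel.from_otu_table(table)
        res = model.fit(n_perm=400, n_boot=400, seed=1)
        score = ground_truth_eval(res.network, truth)
        assert score.recall >= 0.7
        # a fast, reduced-size sanity check; the full-strength benchmark
        # (100 OTUs, 1000 permutations) carries the tighter bound
        assert score.precision is not None and score.precision >= 0.5

    def test_summary_shape(self, small_table):
        model = CoOccurrenceModel.from_otu_table(small_table, name="toy")
        res = model.fit(n_perm=50, n_boot=50, seed=0)
        row = res.summary()
        assert row.loc[0, "dataset"] == "toy"
        assert row.loc[0, "n_samples"] == small_table.n_samples
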