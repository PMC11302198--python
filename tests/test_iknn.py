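import numpy as np
import pytest

from stroopsense import (
    NeighborhoodConfig,
    filter_points,
    informativeness,
    kernel_distance,
    lambda_weight,
    mean_informativeness_score,
)
from stroopsense.errors import (
    ClassDepletionError,
    DegenerateLabelsError,
    InvalidParameterError,
)
from ._oracles import brute_sbar

LOW_DIM = NeighborhoodConfig(bandwidth_rule="literal", standardize=False)


class TestKernel:
    def test_zero_distance_gives_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert kernel_distance(x, x) == 1.0

    def test_closed_forms(self):
        assert kernel_distance(np.zeros(2), np.array([1.0, 1.0]), bandwidth=2.0) == (
            pytest.approx(np.exp(-1.0))
        )
        # literal bandwidth, squared gap 0.5
        assert kernel_distance(
            np.array([0.0]), np.array([np.sqrt(0.5)]), bandwidth=1.0
        ) == pytest.approx(np.exp(-0.5))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            kernel_distance(np.zeros(2), np.zeros(3))


class TestLambdaWeight:
    def test_all_same_label_gives_one(self):
        sim = np.ones((4, 4))
        labels = np.array(["a", "a", "a", "a"])
        assert lambda_weight(1, np.array([1, 2, 3]), labels, sim) == 1.0

    def test_coincident_opposite_neighbor_zeroes(self):
        sim = np.ones((3, 3))  # a coincident opposite-class point has similarity 1
        labels = np.array(["a", "a", "b"])
        assert lambda_weight(1, np.array([1, 2]), labels, sim) == 0.0

    def test_three_neighbor_toy(self):
        """One opposite-class neighbor at similarity e^-1: weight 1 - e^-1."""
        sim = np.full((4, 4), np.exp(-1.0))
        np.fill_diagonal(sim, 1.0)
        labels = np.array(["a", "a", "a", "b"])
        w = lambda_weight(1, np.array([1, 2, 3]), labels, sim)
        assert w == pytest.approx(1.0 - np.exp(-1.0))


class TestInformativeness:
    @pytest.mark.parametrize("k", [3, 5, 7, 10])
    def test_probabilities_sum_to_one(self, k):
        rng = np.random.default_rng(k)
        x = rng.normal(size=(25, 4))
        labels = np.array(["a", "b"] * 12 + ["a"])
        for i in (0, 7, 24):
            _, probs = informativeness(i, k, x, labels, LOW_DIM)
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(probs >= 0)

    def test_uniform_eta_collapses_to_distance(self):
        """All k neighbors share one label: eta = 1 everywhere, P proportional to d."""
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 0.5, (6, 3)), rng.normal(10, 0.5, (3, 3))])
        labels = np.array(["a"] * 6 + ["b"] * 3)
        nbrs, probs = informativeness(0, 3, x, labels, LOW_DIM)
        assert set(labels[nbrs]) == {"a"}
        d = np.array([np.exp(-np.sum((x[0] - x[j]) ** 2)) for j in nbrs])
        assert np.allclose(probs, d / d.sum(), atol=1e-12)


class TestMeanScore:
    def test_deep_inside_class_scores_zero(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 0.5, (15, 3)), rng.normal(8, 0.5, (15, 3))])
        labels = np.array(["a"] * 15 + ["b"] * 15)
        scores = mean_informativeness_score(x, labels)
        assert np.all(scores.s_bar == 0.0)

    def test_surrounded_point_scores_one(self):
        """A lone point whose 10 nearest neighbors all carry the opposite label."""
        rng = np.random.default_rng(2)
        x = np.vstack(
            [np.zeros((1, 3)), rng.normal(0, 0.3, (14, 3)), rng.normal(9, 0.3, (10, 3))]
        )
        labels = np.array(["b"] + ["a"] * 14 + ["b"] * 10)
        scores = mean_informativeness_score(x, labels)
        assert scores.s_bar[0] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle_equivalence(self, seed):
        """Independent loop-based scoring agrees to 1e-12 on 30-point, 5-dim instances."""
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=(30, 5))
        labels = rng.choice(["a", "b"], size=30)
        while len(set(labels)) < 2:
            labels = rng.choice(["a", "b"], size=30)
        for config in (LOW_DIM, NeighborhoodConfig()):
            got = mean_informativeness_score(x, labels, config).s_bar
            want = brute_sbar(
                x,
                labels,
                bandwidth=1.0 if config.bandwidth_rule == "literal" else None,
                standardize=config.standardize,
            )
            assert np.allclose(got, want, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_label_flip_complement(self, seed):
        """Flipping only y_i maps s-bar(x_i) to 1 - s-bar(x_i), exactly."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(25, 4))
        labels = np.array(["a", "b"] * 12 + ["a"])
        base = mean_informativeness_score(x, labels).s_bar
        i = 7
        flipped = labels.copy()
        flipped[i] = "b" if labels[i] == "a" else "a"
        got = mean_informativeness_score(x, flipped).s_bar
        # i is never its own neighbor, so y_i enters only the final comparison
        # of i's score; the vote over i's neighbors is unchanged and s flips.
        assert got[i] == pytest.approx(1.0 - base[i], abs=1e-12)

    def test_rigid_transform_invariance(self):
        """Rotation + translation of the (already standardized) matrix leaves s-bar fixed."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 4))
        x = (x - x.mean(0)) / x.std(0)
        labels = rng.choice(["a", "b"], size=30)
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        cfg = NeighborhoodConfig(standardize=False)
        base = mean_informativeness_score(x, labels, cfg).s_bar
        moved = x @ q + 3.0
        assert np.allclose(
            mean_informativeness_score(moved, labels, cfg).s_bar, base, atol=1e-9
        )

    def test_single_class_raises(self):
        x = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(DegenerateLabelsError):
            mean_informativeness_score(x, np.array(["a"] * 20))

    def test_k_exceeding_points_raises(self):
        x = np.random.default_rng(0).normal(size=(8, 3))
        labels = np.array(["a", "b"] * 4)
        with pytest.raises(InvalidParameterError):
            mean_informativeness_score(x, labels)  # default k includes 10 >= 8


class TestFiltering:
    def test_default_enumeration_is_25_pairs(self):
        assert len(NeighborhoodConfig().pairs) == 25

    def test_discard_fraction_zero_retains_all(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 3))
        labels = np.array(["a", "b"] * 15)
        res = filter_points(x, labels, NeighborhoodConfig(discard_fraction=0.0))
        assert len(res.retained) == 30 and len(res.discarded) == 0

    def test_discard_count_round_half_up(self):
        """152 points at 5%: round(7.6) = 8 discarded."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=(152, 4))
        labels = np.array(["a", "b"] * 76)
        res = filter_points(x, labels)
        assert len(res.discarded) == 8
        assert len(res.retained) == 144

    def test_cg_only_scope_discards_only_controls(self):
        rng = np.random.default_rng(6)
        x = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(1, 1, (30, 3))])
        labels = np.array(["CG"] * 40 + ["EG"] * 30)
        res = filter_points(
            x, labels, NeighborhoodConfig(scope="cg-only", discard_fraction=0.1)
        )
        assert len(res.discarded) == 4  # round(0.1 * 40)
        assert all(labels[i] == "CG" for i in res.discarded)

    def test_discarded_are_worst_ranked(self):
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(0, 1, (35, 3)), rng.normal(1.5, 1, (35, 3))])
        labels = np.array(["a"] * 35 + ["b"] * 35)
        res = filter_points(x, labels, NeighborhoodConfig(discard_fraction=0.1))
        worst = res.scores.s_bar[res.discarded].min()
        assert np.all(res.scores.s_bar[res.retained] <= worst)

    def test_class_depletion_refused(self):
        rng = np.random.default_rng(8)
        # one isolated "b" point surrounded by "a"s: discarding it empties its class
        x = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(0, 1, (1, 3))])
        labels = np.array(["a"] * 20 + ["b"])
        with pytest.raises(ClassDepletionError):
            filter_points(
                x, labels, NeighborhoodConfig(k_values=(3, 5), discard_fraction=0.05)
            )

    def test_flipped_points_score_worse(self):
        """Planted noise: 5% label-flipped points out-score clean points in
        mean s-bar in at least 95% of 20 seeds."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            n = 60
            x = np.vstack([rng.normal(0, 1, (n, 4)), rng.normal(2.5, 1, (n, 4))])
            labels = np.array(["a"] * n + ["b"] * n)
            flip = rng.choice(2 * n, size=6, replace=False)
            noisy = labels.copy()
            noisy[flip] = np.where(labels[flip] == "a", "b", "a")
            s = mean_informativeness_score(x, noisy).s_bar
            clean = np.setdiff1d(np.arange(2 * n), flip)
            wins += s[flip].mean() > s[clean].mean()
        assert wins >= 19
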