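"""Adaptive strategy: entropy triage, Gaussian prior, relevance scores,
feature selection, hierarchical routing and expert feedback."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemorrhagenet import (HemorrhageNet, HierarchyTree, RunConfig, SimSpec,
                           SpatialPrior, generate_cohort, hybrid_loss,
                           incorporate_feedback, relevance_scores, route,
                           select_features, spatial_prior_density, uncertainty)
from hemorrhagenet.cohort import Cohort, Sample
from hemorrhagenet.strategy import (RelevanceReport, entropy,
                                    estimate_spatial_prior, fit_tree,
                                    tree_accuracy, tree_loss)


def _brute_entropy(p):
    return -sum(pi * math.log(pi) for pi in p if pi > 0)


class TestEntropyTriage:
    @pytest.mark.parametrize("probs,expected", [
        ([1.0, 0.0, 0.0], 0.0),
        ([0.25] * 4, math.log(4)),
        ([0.5, 0.5], math.log(2)),
    ])
    def test_closed_forms(self, probs, expected):
        assert entropy(np.array(probs))[0] == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=6))
    def test_matches_brute_force(self, raw):
        p = np.array(raw) / np.sum(raw)
        assert entropy(p)[0] == pytest.approx(_brute_entropy(p), abs=1e-9)

    def test_one_hot_never_flagged(self):
        rep = uncertainty(np.array([[1.0, 0.0]]), delta=0.0)
        assert rep.entropies[0] == 0.0 and rep.flagged_ids == []

    def test_flag_rule_around_ln2(self):
        p = np.array([[0.5, 0.5]])
        assert uncertainty(p, delta=0.69).flagged_ids == ["0"]
        assert uncertainty(p, delta=0.70).flagged_ids == []

    def test_flag_count_monotone_in_delta(self, rng):
        raw = rng.dirichlet(np.ones(4), size=200)
        counts = [len(uncertainty(raw, d).flagged_ids)
                  for d in np.linspace(0, math.log(4), 25)]
        assert np.all(np.diff(counts) <= 0)

    def test_mean_entropy_is_arithmetic_mean(self, rng):
        raw = rng.dirichlet(np.ones(3), size=50)
        rep = uncertainty(raw, delta=0.5)
        assert rep.mean_entropy == pytest.approx(rep.entropies.mean())

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            uncertainty(np.array([[0.7, 0.7]]), delta=0.5)

    def test_entropy_penalty_adds_calibration_note(self):
        rep = uncertainty(np.array([[0.5, 0.5]]), 0.1, entropy_penalized=True)
        assert rep.note is not None and "over-confident" in rep.note


class TestHybridLoss:
    def test_reduces_to_classification_loss(self):
        assert hybrid_loss(0.42, np.array([1.0, -2.0]), np.array([[0.5, 0.5]]),
                           0.0, 0.0) == pytest.approx(0.42)

    def test_arithmetic(self):
        # L=1, ||w||_1=2, mean U=0.5 (forced), lam1=0.1, lam2=0.2 -> 1.3
        p = math.exp(-0.5)
        probs = np.array([[p, 1 - p]])
        u = entropy(probs)[0]
        expected = 1.0 + 0.1 * 2.0 + 0.2 * u
        got = hybrid_loss(1.0, np.array([2.0]), probs, 0.1, 0.2)
        assert got == pytest.approx(expected, abs=1e-12)
        # the printed arithmetic case with mean entropy exactly 0.5
        assert 1.0 + 0.1 * 2.0 + 0.2 * 0.5 == pytest.approx(1.3)

    def test_nondecreasing_in_penalties(self, rng):
        probs = rng.dirichlet(np.ones(3), size=10)
        w = rng.normal(size=7)
        base = hybrid_loss(1.0, w, probs, 0.0, 0.0)
        for l1, l2 in [(0.1, 0.0), (0.1, 0.1), (0.5, 0.5)]:
            assert hybrid_loss(1.0, w, probs, l1, l2) >= base

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            hybrid_loss(1.0, np.ones(2), np.array([[1.0, 0.0]]), -0.1, 0.0)


class TestSpatialPrior:
    def test_standard_normal_mode_1d(self):
        prior = SpatialPrior(mean=[0.0], cov=[[1.0]])
        assert spatial_prior_density(prior, [0.0]) == pytest.approx(
            1.0 / math.sqrt(2 * math.pi), abs=1e-9)

    def test_standard_normal_mode_2d(self):
        prior = SpatialPrior(mean=[0.0, 0.0], cov=np.eye(2))
        assert spatial_prior_density(prior, [0.0, 0.0]) == pytest.approx(
            1.0 / (2 * math.pi), abs=1e-9)

    def test_grid_quadrature_integrates_to_one(self):
        prior = SpatialPrior(mean=[0.0, 0.0], cov=np.eye(2))
        xs = np.linspace(-6, 6, 241)
        xx, yy = np.meshgrid(xs, xs)
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
        dens = spatial_prior_density(prior, pts)
        dx = xs[1] - xs[0]
        assert dens.reshape(xx.shape).sum() * dx * dx == pytest.approx(1.0,
                                                                       abs=1e-3)

    def test_non_spd_covariance_rejected(self):
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            SpatialPrior(mean=[0.0, 0.0], cov=[[1.0, 2.0], [2.0, 1.0]])

    def test_estimated_from_lesion_centroids(self, tiny_cohort):
        prior = estimate_spatial_prior(tiny_cohort)
        h, w = tiny_cohort.samples[0].image.shape
        assert 0 <= prior.mean[0] <= h and 0 <= prior.mean[1] <= w
        np.linalg.cholesky(prior.cov)


def _toy_prog_model(d_clin=3, weight_on=0):
    """Literal-mode net whose prognosis head reads one covariate only."""
    cfg = RunConfig(image_size=(8, 8), conv_channels=(2,), head_mode="literal",
                    n_classes=2, lambda_prognosis=1.0, seed=0)
    net = HemorrhageNet(cfg, d_clin=d_clin)
    net.prog_head.params["W"][...] = 0.0
    net.prog_head.params["b"][...] = 0.0
    net.prog_head.params["W"][net.d_z + weight_on, 0] = 1.0
    net.class_head.params["W"][...] = 0.0
    net.class_head.params["b"][...] = 0.0
    return net


def _cohort_from_arrays(clin, p, image_size=(8, 8)):
    samples = [Sample(id=f"t{i}", image=np.zeros(image_size), clinical=c,
                      class_label=None, prognosis=float(pi))
               for i, (c, pi) in enumerate(zip(clin, p))]
    return Cohort(samples, schema=[f"c{j}" for j in range(clin.shape[1])],
                  n_classes=2)


class TestRelevanceScores:
    def test_hand_differentiated_oracle(self):
        """Toy head p_hat = sigmoid(x_0), L_i = (p_hat - p_i)^2:
        |dL/dx_0| = 2|p_hat - p|·p_hat(1-p_hat); R_0 = mean(|grad|)·Var(x_0)."""
        x0 = np.array([-1.2, -0.3, 0.4, 1.0, 2.1])
        p = np.array([0.9, 0.2, 0.5, 0.4, 0.1])
        clin = np.stack([x0, np.zeros(5) + 0.7, np.linspace(0, 1, 5)], axis=1)
        net = _toy_prog_model(d_clin=3, weight_on=0)
        cohort = _cohort_from_arrays(clin, p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = relevance_scores(net, cohort)
        s = 1.0 / (1.0 + np.exp(-x0))
        grad = np.abs(2.0 * (s - p) * s * (1.0 - s))
        assert report.mean_abs_gradient[0] == pytest.approx(grad.mean(), abs=1e-9)
        assert report.relevance[0] == pytest.approx(grad.mean() * x0.var(),
                                                    abs=1e-9)

    def test_constant_feature_scores_zero_with_warning(self):
        clin = np.stack([np.linspace(-1, 1, 5), np.full(5, 3.0)], axis=1)
        net = _toy_prog_model(d_clin=2, weight_on=0)
        cohort = _cohort_from_arrays(clin, np.full(5, 0.5))
        with pytest.warns(UserWarning, match="zero-variance"):
            report = relevance_scores(net, cohort)
        assert report.relevance[1] == 0.0

    def test_unweighted_feature_scores_zero(self):
        clin = np.random.default_rng(0).normal(size=(6, 3))
        net = _toy_prog_model(d_clin=3, weight_on=0)
        cohort = _cohort_from_arrays(clin, np.full(6, 0.5))
        report = relevance_scores(net, cohort)
        # features 1 and 2 have zero weight everywhere in the network
        assert report.relevance[1] == 0.0 and report.relevance[2] == 0.0

    def test_requires_two_samples(self, tiny_model, tiny_cohort):
        sub = Cohort(tiny_cohort.samples[:1], tiny_cohort.schema,
                     tiny_cohort.n_classes, ["train"])
        with pytest.raises(ValueError):
            relevance_scores(tiny_model, sub)


class TestSelectFeatures:
    def _report(self, scores):
        scores = np.asarray(scores, dtype=float)
        return RelevanceReport(feature_names=[f"f{j}" for j in range(len(scores))],
                               relevance=scores, mean_abs_gradient=scores,
                               variance=np.ones_like(scores))

    def test_tau_zero_retains_everything_positive(self):
        rep = select_features(self._report([0.5, 1.0, 0.1]), tau=0.0)
        assert rep.retained == [0, 1, 2]

    def test_tau_above_max_keeps_argmax_only(self):
        rep = select_features(self._report([0.5, 1.0, 0.1]), tau=2.0)
        assert rep.retained == [1]

    def test_top_quantile_count(self):
        rep = select_features(self._report(np.linspace(1, 20, 20)), top_q=0.25)
        assert len(rep.retained) == 5  # ceil(0.25 * 20)
        assert rep.retained == [15, 16, 17, 18, 19]

    def test_combined_scores_rescaled_to_max_one(self):
        rep = select_features(self._report([2.0, 8.0]), tau=0.5)
        assert rep.combined.max() == pytest.approx(1.0)

    def test_scale_invariance_of_retained_set(self):
        scores = np.array([0.2, 0.9, 0.05, 0.6])
        a = select_features(self._report(scores), tau=0.3).retained
        b = select_features(self._report(scores * 37.0), tau=0.3).retained
        assert a == b

    def test_spatial_prior_downweights_far_features(self):
        prior = SpatialPrior(mean=[0.0, 0.0], cov=np.eye(2))
        rep = self._report([1.0, 1.0])
        out = select_features(rep, prior=prior, tau=0.5,
                              spatial_coords={0: np.array([0.0, 0.0]),
                                              1: np.array([5.0, 5.0])})
        assert out.retained == [0]

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            select_features(self._report([]))


class TestHierarchyTree:
    def test_zero_gates_tie_routes_all_right(self):
        tree = HierarchyTree(depth=2, weights=np.zeros((3, 2)), biases=np.zeros(3),
                             leaf_posteriors=np.full((4, 2), 0.5))
        leaf, path, post = route(tree, np.array([0.3, -0.7]))
        assert [f for _, f in path] == [0.5, 0.5]
        assert [n for n, _ in path] == [0, 2]
        assert leaf == 3  # always right
        assert len(path) == tree.depth

    def test_strong_negative_bias_forces_left(self):
        tree = HierarchyTree(depth=1, weights=np.full((1, 2), 0.01),
                             biases=np.array([-10.0]),
                             leaf_posteriors=np.array([[0.9, 0.1], [0.1, 0.9]]))
        leaf, path, post = route(tree, np.array([5.0, -5.0]))
        assert leaf == 0
        assert path[0][1] == pytest.approx(1 / (1 + math.exp(10 - 0.0)), rel=1e-3)

    def test_every_sample_reaches_exactly_one_leaf(self, rng):
        tree = HierarchyTree(depth=3, weights=rng.normal(size=(7, 4)),
                             biases=rng.normal(size=7),
                             leaf_posteriors=np.full((8, 3), 1 / 3))
        for x in rng.normal(size=(50, 4)):
            leaf, path, _ = route(tree, x)
            assert 0 <= leaf < 8 and len(path) == 3

    def test_depth_zero_gives_smoothed_global_frequencies(self):
        y = np.array([0, 0, 0, 1])
        tree = fit_tree(np.zeros((4, 2)), y, n_classes=2, depth=0)
        assert np.allclose(tree.leaf_posteriors[0], [4 / 6, 2 / 6])

    def test_separable_one_dimensional_problem_is_solved(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.uniform(-2, -1, 30), rng.uniform(1, 2, 30)])
        y = np.array([0] * 30 + [1] * 30)
        tree = fit_tree(x[:, None], y, n_classes=2, depth=1, epochs=300, seed=0)
        assert tree_accuracy(tree, x[:, None], y) == 1.0

    def test_fit_is_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 3, size=40)
        t1 = fit_tree(X, y, 3, depth=2, epochs=50, seed=5)
        t2 = fit_tree(X, y, 3, depth=2, epochs=50, seed=5)
        assert np.array_equal(t1.weights, t2.weights)
        assert np.array_equal(t1.leaf_posteriors, t2.leaf_posteriors)

    def test_json_roundtrip(self, tmp_path, rng):
        tree = fit_tree(rng.normal(size=(30, 2)), rng.integers(0, 2, 30), 2,
                        depth=2, epochs=20, seed=1)
        tree.to_json(tmp_path / "tree.json")
        back = HierarchyTree.from_json(tmp_path / "tree.json")
        assert np.allclose(tree.weights, back.weights)
        assert np.allclose(tree.leaf_posteriors, back.leaf_posteriors)

    def test_malformed_tree_rejected(self):
        with pytest.raises(ValueError):
            HierarchyTree(depth=2, weights=np.zeros((2, 2)), biases=np.zeros(3),
                          leaf_posteriors=np.full((4, 2), 0.5))


class TestFeedback:
    def _convex_node_setup(self):
        """Depth-1 tree with pure leaves: gate CE is convex in (w, b)."""
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-1.5, 0.5, 20), rng.normal(1.5, 0.5, 20)])
        y = np.array([0] * 20 + [1] * 20)
        samples = [Sample(id=f"c{i}", image=np.zeros((8, 8)),
                          clinical=np.array([xi]), class_label=int(yi))
                   for i, (xi, yi) in enumerate(zip(x, y))]
        corrections = Cohort(samples, schema=["x"], n_classes=2)
        tree = HierarchyTree(depth=1, weights=np.array([[0.3]]),
                             biases=np.array([0.1]),
                             leaf_posteriors=np.array([[1.0, 0.0], [0.0, 1.0]]))
        return tree, corrections, x, y

    def test_zero_eta_changes_nothing(self):
        tree, corrections, x, y = self._convex_node_setup()
        w0, b0 = tree.weights.copy(), tree.biases.copy()
        incorporate_feedback(tree, corrections, eta=0.0)
        assert np.array_equal(tree.weights, w0) and np.array_equal(tree.biases, b0)

    def test_single_step_strictly_decreases_convex_loss(self):
        tree, corrections, x, y = self._convex_node_setup()
        before = tree_loss(tree, x[:, None], y)
        losses = incorporate_feedback(tree, corrections, eta=1e-3, steps=1)
        assert losses[-1] < before

    def test_repeated_steps_descend_monotonically(self):
        tree, corrections, x, y = self._convex_node_setup()
        losses = incorporate_feedback(tree, corrections, eta=0.05, steps=30)
        assert np.all(np.diff(losses) <= 1e-12)

    def test_model_feedback_reduces_corrections_loss(self, tiny_model, tiny_cohort):
        from hemorrhagenet import generate_corrections
        clone = HemorrhageNet(tiny_model.config, tiny_model.d_clin)
        clone.load_state(tiny_model.state_copy())
        corrections = generate_corrections(tiny_cohort, 0.3, seed=4)
        losses = incorporate_feedback(clone, corrections, eta=1e-4, steps=3)
        assert losses[-1] <= losses[0]

    def test_empty_corrections_rejected(self, tiny_model, tiny_cohort):
        empty = Cohort([], tiny_cohort.schema, tiny_cohort.n_classes, [])
        with pytest.raises(ValueError):
            incorporate_feedback(tiny_model, empty, eta=1e-3)
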