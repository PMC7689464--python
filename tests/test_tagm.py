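import numpy as np
import pytest

import vesicleshift as vs
from vesicleshift.errors import VesicleShiftError
from vesicleshift.tagm import match_discard_classes


def _two_cluster_data(rng, n_unknown=60, sep=20.0):
    """Two unit-variance Gaussian clusters separated by sep sigma."""
    c0, c1 = np.zeros(2), np.array([sep, 0.0])
    markers = np.vstack(
        [c0 + rng.normal(0, 1, (10, 2)), c1 + rng.normal(0, 1, (10, 2))]
    )
    labels = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
    truth = rng.integers(0, 2, n_unknown)
    unknowns = np.where(truth[:, None] == 0, c0, c1) + rng.normal(
        0, 1, (n_unknown, 2)
    )
    X = np.vstack([markers, unknowns])
    all_labels = np.concatenate([labels, np.array([None] * n_unknown, dtype=object)])
    return X, all_labels, truth


class TestDefaultPriors:
    def test_scale_matrix_formula(self, rng):
        # D=2, unit variances, K=4  ->  S0 = diag(1,1) / 4
        X = rng.normal(0, 1, size=(4000, 2))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        priors = vs.default_priors(X, 4)
        np.testing.assert_allclose(priors.S0, np.diag([0.25, 0.25]), atol=1e-9)

    def test_dirichlet_and_location_defaults(self, rng):
        X = rng.normal(3.0, 2.0, size=(200, 5))
        priors = vs.default_priors(X, 7)
        np.testing.assert_array_equal(priors.beta0, np.ones(7))
        np.testing.assert_allclose(priors.mu0, X.mean(0))
        np.testing.assert_allclose(priors.t_location, X.mean(0))
        assert priors.nu0 == 7.0  # D + 2
        assert priors.lambda0 == 0.01


class TestFitTAGM:
    def test_k1_conjugate_posterior_mode(self, rng):
        """With one class and no outlier component, the fitted mean is the
        closed-form normal-inverse-Wishart posterior-mode mean."""
        X = rng.normal(2.0, 1.0, size=(50, 3))
        labels = np.array(["A", "A"] + [None] * 48, dtype=object)
        priors = vs.default_priors(X, 1)
        fit = vs.fit_tagm_map(X, labels, priors, fix_epsilon=0.0)
        n = len(X)
        expected = (priors.lambda0 * priors.mu0 + n * X.mean(0)) / (
            priors.lambda0 + n
        )
        np.testing.assert_allclose(fit.means[0], expected, atol=1e-8)

    def test_separated_clusters_fully_allocated(self, rng):
        X, labels, truth = _two_cluster_data(rng)
        fit = vs.fit_tagm_map(X, labels)
        post = vs.posterior_localisation(fit, X[20:])
        assigned = np.array([{"A": 0, "B": 1}[c] for c in post.map_class])
        np.testing.assert_array_equal(assigned, truth)
        # posterior among organelle classes (outlier mass conditioned out)
        among_classes = post.probabilities / (
            1.0 - post.outlier_probability[:, None]
        )
        assert np.all(among_classes.max(axis=1) > 0.999)

    def test_log_posterior_monotone(self, rng):
        X, labels, _ = _two_cluster_data(rng)
        fit = vs.fit_tagm_map(X, labels)
        diffs = np.diff(fit.log_posterior_trace)
        floor = -1e-6 * (1.0 + np.abs(fit.log_posterior_trace[:-1]))
        assert np.all(diffs >= floor)

    def test_epsilon_small_without_outliers(self, rng):
        X, labels, _ = _two_cluster_data(rng)
        fit = vs.fit_tagm_map(X, labels)
        assert fit.epsilon <= 0.05

    def test_label_permutation_invariance(self, rng):
        X, labels, _ = _two_cluster_data(rng)
        renamed = np.array(
            [{"A": "Z_late", "B": "A_early"}.get(l, None) for l in labels],
            dtype=object,
        )
        f1 = vs.fit_tagm_map(X, labels)
        f2 = vs.fit_tagm_map(X, renamed)
        m1 = {lab: f1.means[i] for i, lab in enumerate(f1.class_labels)}
        m2 = {lab: f2.means[i] for i, lab in enumerate(f2.class_labels)}
        np.testing.assert_allclose(m1["A"], m2["Z_late"], atol=1e-9)
        np.testing.assert_allclose(m1["B"], m2["A_early"], atol=1e-9)

    def test_parameter_recovery_on_generative_model(self):
        """Fitted class means lie within 3 standard errors of truth
        (model-matched simulation: K=6, D=12, 200 proteins per class)."""
        rng = np.random.default_rng(21)
        K, D, n_per = 6, 12, 200
        true_means = rng.normal(0, 5, size=(K, D))
        sigma = 0.8
        X, labels = [], []
        for k in range(K):
            X.append(true_means[k] + rng.normal(0, sigma, (n_per, D)))
            labels += [f"class{k}"] * 20 + [None] * (n_per - 20)
        X = np.vstack(X)
        labels = np.array(labels, dtype=object)
        fit = vs.fit_tagm_map(X, labels)
        from scipy.stats import chi2

        crit = chi2.ppf(0.999, D)
        for k, lab in enumerate(sorted({l for l in labels if l})):
            i = list(fit.class_labels).index(lab)
            dev = fit.means[i] - true_means[k]
            z2 = n_per * dev @ np.linalg.solve(fit.covariances[i], dev)
            assert z2 < crit

    def test_too_few_markers_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        labels = np.array(["A"] + [None] * 9, dtype=object)
        with pytest.raises(VesicleShiftError):
            vs.fit_tagm_map(X, labels)


class TestPosterior:
    def test_probabilities_sum_to_one(self, rng):
        X, labels, _ = _two_cluster_data(rng)
        fit = vs.fit_tagm_map(X, labels)
        post = vs.posterior_localisation(fit, X)
        total = post.probabilities.sum(axis=1) + post.outlier_probability
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_protein_at_class_mean_gets_that_class(self, rng):
        X, labels, _ = _two_cluster_data(rng)
        fit = vs.fit_tagm_map(X, labels)
        post = vs.posterior_localisation(fit, fit.means)
        assert list(post.map_class) == list(fit.class_labels)

    def test_far_point_flagged_as_outlier(self, rng):
        X, labels, _ = _two_cluster_data(rng)
        fit = vs.fit_tagm_map(X, labels)
        far = np.array([[10.0, 200.0]])  # ~10x cluster spread off-axis
        post = vs.posterior_localisation(fit, far)
        assert post.outlier_probability[0] > 0.5


class TestPrefilter:
    @pytest.fixture()
    def posterior(self, rng):
        X, labels, _ = _two_cluster_data(rng)
        renamed = np.array(
            [{"A": "mitochondria", "B": "golgi"}.get(l, None) for l in labels],
            dtype=object,
        )
        fit = vs.fit_tagm_map(X, renamed)
        ids = [f"P{i}" for i in range(len(X))]
        return vs.posterior_localisation(fit, X, protein_ids=ids)

    def test_mito_discarded_golgi_retained(self, posterior):
        retained = vs.prefilter_discard(posterior, {"mitochondria"})
        kept_classes = {
            posterior.map_class[posterior.protein_ids.index(p)] for p in retained
        }
        assert kept_classes == {"golgi"}

    def test_empty_discard_set_is_identity(self, posterior):
        assert vs.prefilter_discard(posterior, set()) == posterior.protein_ids

    def test_unknown_class_raises(self, posterior):
        with pytest.raises(VesicleShiftError):
            vs.prefilter_discard(posterior, {"lysosome"})

    def test_markers_of_kept_classes_always_retained(self, posterior):
        markers = vs.MarkerMap({"P0": "golgi", "P1": "mitochondria"})
        retained = vs.prefilter_discard(
            posterior, {"mitochondria"}, markers=markers
        )
        assert "P0" in retained  # curated golgi marker stays
        assert "P1" not in retained  # curated mito marker removed

    def test_pattern_matching_of_discard_labels(self):
        classes = ("Mitochondria", "Nucleus/chromatin", "Golgi", "ER")
        assert match_discard_classes(classes) == {
            "Mitochondria",
            "Nucleus/chromatin",
        }
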