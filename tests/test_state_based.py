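"""State-based estimators: clustering, HMMs, dictionary learning."""

import warnings

import numpy as np
import pytest

from multidfc import (CAP, CHMM, DHMM, SWC, WL, fractional_occupancy,
                      generate_markov_bold, ksvd_one_sparse,
                      markov_covariance_spec, markov_mean_pattern_spec,
                      two_level_kmeans, z_standardize)
from multidfc.errors import ParameterError, ValidationError
from multidfc.validation import (covariance_to_correlation, label_accuracy,
                                 match_patterns, match_state_fc)


class TestFractionalOccupancy:
    def test_balanced_two_states(self):
        np.testing.assert_allclose(
            fractional_occupancy(np.array([1, 1, 2, 2]), 2), [0.5, 0.5]
        )

    def test_single_occupied_state(self):
        np.testing.assert_allclose(
            fractional_occupancy(np.full(10, 3), 4), [0, 0, 1, 0]
        )

    def test_out_of_range_raises(self):
        with pytest.raises(ValidationError):
            fractional_occupancy(np.array([0, 1]), 2)

    def test_markov_chain_matches_stationary_distribution(self):
        """Empirical FO of a long 2-state chain approaches the stationary
        eigenvector of its transition matrix."""
        from multidfc.simulate import SyntheticSpec, _simulate_chain

        transition = np.array([[0.9, 0.1], [0.1, 0.9]])
        rng = np.random.default_rng(5)
        labels = _simulate_chain(rng, transition, np.array([0.5, 0.5]), 10_000) + 1
        fo = fractional_occupancy(labels, 2)
        vals, vecs = np.linalg.eig(transition.T)
        pi = np.abs(np.real(vecs[:, np.argmin(np.abs(vals - 1))]))
        pi /= pi.sum()
        assert np.max(np.abs(fo - pi)) < 0.05


class TestTwoLevelKMeans:
    def test_planted_clouds_recovered(self):
        """Two well-separated point clouds are recovered by the two-stage
        procedure for every seed."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 60
            cloud_a = rng.normal(0.0, 0.05, (n, 3)) + np.array([1.0, 0.0, 0.0])
            cloud_b = rng.normal(0.0, 0.05, (n, 3)) + np.array([-1.0, 0.5, 0.0])
            subjects = [
                np.vstack([cloud_a[:30], cloud_b[:30]]),
                np.vstack([cloud_a[30:], cloud_b[30:]]),
            ]
            centroids, labels = two_level_kmeans(subjects, 2, 2, seed=seed)
            order = np.argsort(centroids[:, 0])[::-1]
            assert np.linalg.norm(centroids[order[0]] - [1, 0, 0]) < 0.1
            assert np.linalg.norm(centroids[order[1]] - [-1, 0.5, 0]) < 0.1
            truth = np.array([0] * 30 + [1] * 30)
            acc = label_accuracy(truth + 1, labels[0] + 1)
            assert acc == 1.0

    def test_identical_samples_single_group(self):
        samples = [np.ones((20, 4))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, labels = two_level_kmeans(samples, 3, 2, seed=0)
        assert len(set(labels[0].tolist())) == 1

    def test_k_group_exceeding_pool_raises(self):
        with pytest.raises(ParameterError):
            two_level_kmeans([np.random.default_rng(0).normal(size=(5, 2))], 2, 10, 0)


@pytest.fixture(scope="module")
def markov_data():
    spec = markov_covariance_spec(
        n_subjects=4, n_rois=12, n_timepoints=800, self_transition=0.95, seed=21
    )
    ts_list, truths = generate_markov_bold(spec)
    return spec, [z_standardize(ts) for ts in ts_list], truths


class TestCAP:
    def test_state_fc_rank_one_outer_product(self, markov_data):
        _, ts_list, _ = markov_data
        cap = CAP(n_states=3, n_subject_clusters=5, seed=1).fit(ts_list)
        for k in range(3):
            fc = cap.state_set_.state_fc[k]
            c = cap.centroids_[k]
            np.testing.assert_allclose(fc, np.outer(c, c), atol=1e-12)
            assert np.linalg.matrix_rank(fc, tol=1e-8) <= 1
            np.testing.assert_allclose(np.trace(fc), np.dot(c, c))

    def test_recovers_planted_activity_patterns(self):
        """Centroids align (cosine > 0.95) with the true conditional mean
        activity of each planted state."""
        spec = markov_mean_pattern_spec(n_subjects=4, n_rois=12, n_timepoints=800, seed=3)
        ts_list, truths = generate_markov_bold(spec)
        ts_list = [z_standardize(ts) for ts in ts_list]
        cap = CAP(n_states=3, n_subject_clusters=5, seed=4).fit(ts_list)
        x = np.vstack([ts.values for ts in ts_list])
        labels = np.concatenate(truths)
        oracle = np.stack([x[labels == k].mean(0) for k in (1, 2, 3)])
        _, cos = match_patterns(oracle, cap.centroids_, sign_invariant=False)
        assert cos > 0.95


class TestSWC:
    def test_feature_length_and_unit_diagonal(self, markov_data):
        _, ts_list, _ = markov_data
        swc = SWC(n_states=3, n_subject_clusters=5, seed=2).fit(ts_list)
        assert swc.centroids_.shape[1] == 12 * 11 // 2
        for fc in swc.state_set_.state_fc:
            np.testing.assert_allclose(np.diag(fc), 1.0)

    def test_apply_reproduces_fit_time_labels(self, markov_data):
        """A subject included in the group fit gets identical labels when
        the fitted model is re-applied (nearest-centroid rule)."""
        _, ts_list, _ = markov_data
        swc = SWC(n_states=3, n_subject_clusters=5, seed=2).fit(ts_list)
        feats = [swc._window_features(ts)[0] for ts in ts_list]
        _, fit_labels = two_level_kmeans(feats, 5, 3, seed=swc.seed)
        course, _ = swc.apply(ts_list[0])
        np.testing.assert_array_equal(course.labels, fit_labels[0] + 1)

    def test_at_most_k_distinct_slices(self, markov_data):
        _, ts_list, _ = markov_data
        swc = SWC(n_states=3, n_subject_clusters=5, seed=2).fit(ts_list)
        _, dfc = swc.apply(ts_list[1])
        uniq = {tuple(np.round(sl[np.tril_indices(12, -1)], 12)) for sl in dfc.values}
        assert len(uniq) <= 3


class TestCHMM:
    def test_recovers_planted_regimes(self):
        spec = markov_covariance_spec(
            n_subjects=5, n_rois=12, n_timepoints=1200, self_transition=0.95, seed=31
        )
        ts_list, truths = generate_markov_bold(spec)
        ts_list = [z_standardize(ts) for ts in ts_list]
        chmm = CHMM(n_states=3, seed=32).fit(ts_list)
        est = np.concatenate([chmm.apply(ts)[0].labels for ts in ts_list])
        acc = label_accuracy(np.concatenate(truths), est)
        assert acc > 0.9
        corr = match_state_fc(
            spec.state_covariances,
            covariance_to_correlation(chmm.state_set_.state_fc),
        )[1]
        assert corr > 0.85

    def test_transition_rows_stochastic(self, markov_data):
        _, ts_list, _ = markov_data
        chmm = CHMM(n_states=3, seed=33).fit(ts_list)
        np.testing.assert_allclose(chmm.model_.transmat_.sum(axis=1), 1.0, atol=1e-10)

    def test_single_regime_matches_sample_covariance(self, rng):
        """On stationary Gaussian data the occupancy-weighted mixture moment
        of the fitted states reproduces the sample covariance, and each
        state keeps the sample correlation structure.  (EM may split a
        single regime into amplitude pseudo-states, so only the pooled
        moment is tight.)"""
        from multidfc.simulate import stationary_spec

        spec = stationary_spec(n_subjects=3, n_rois=6, n_timepoints=900, seed=35)
        ts_list, _ = generate_markov_bold(spec)
        ts_list = [z_standardize(ts) for ts in ts_list]
        chmm = CHMM(n_states=2, seed=36).fit(ts_list)
        x = np.vstack([ts.values for ts in ts_list])
        s = np.cov(x.T, bias=True)
        labels = np.concatenate([chmm.apply(ts)[0].labels for ts in ts_list])
        fo = np.bincount(labels - 1, minlength=2) / labels.size
        means = chmm.model_.means_
        pooled = sum(
            fo[k] * (chmm.state_set_.state_fc[k] + np.outer(means[k], means[k]))
            for k in range(2)
        )
        assert np.linalg.norm(pooled - s) < 0.05 * np.linalg.norm(s)


class TestDHMM:
    def test_fit_apply_contract(self, markov_data):
        _, ts_list, _ = markov_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dhmm = DHMM(n_states=3, n_obs=2, n_subject_clusters=5, seed=41).fit(ts_list)
        course, dfc = dhmm.apply(ts_list[0])
        k = dhmm.state_set_.n_states
        assert k <= 3
        assert course.labels.min() >= 1 and course.labels.max() <= k
        assert dfc.n_timepoints == 25  # (800 - 78)//30 + 1 windows
        # every dFC slice is one of the state FC matrices
        for sl in dfc.values:
            assert any(np.allclose(sl, fc) for fc in dhmm.state_set_.state_fc)

    def test_state_fc_is_mean_of_assigned_slices(self, markov_data):
        _, ts_list, _ = markov_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dhmm = DHMM(n_states=3, n_obs=2, n_subject_clusters=5, seed=41).fit(ts_list)
        obs_fc = dhmm.swc_.state_set_.state_fc
        hidden, slices = [], []
        for ts in ts_list:
            labels0, _ = dhmm.swc_._assign(ts)
            h = dhmm.model_.predict(labels0[:, None])
            hidden.append(h)
            slices.append(obs_fc[labels0])
        hidden = np.concatenate(hidden)
        slices = np.concatenate(slices)
        occupied = sorted(set(hidden.tolist()))
        for new, old in enumerate(occupied):
            np.testing.assert_allclose(
                dhmm.state_set_.state_fc[new], slices[hidden == old].mean(0)
            )

    def test_default_observation_count_follows_ratio(self):
        assert DHMM(n_states=12).n_obs == 8  # round(12 * 16/24)


class TestKSVD:
    def test_atoms_unit_norm_rank_one_states(self, markov_data):
        _, ts_list, _ = markov_data
        wl = WL(n_states=3, seed=51).fit(ts_list)
        np.testing.assert_allclose(
            np.linalg.norm(wl.dictionary_, axis=0), 1.0, atol=1e-10
        )
        for fc in wl.state_set_.state_fc:
            np.testing.assert_allclose(np.trace(fc), 1.0, atol=1e-10)
            assert np.linalg.matrix_rank(fc, tol=1e-8) == 1

    def test_recovers_planted_orthogonal_atoms(self, rng):
        atoms = np.zeros((2, 8))
        atoms[0, :4] = 0.5
        atoms[1, 4:] = 0.5
        signs = rng.choice([-1.0, 1.0], size=500)
        which = rng.integers(0, 2, size=500)
        x = signs[:, None] * atoms[which] * 3.0 + 0.05 * rng.standard_normal((500, 8))
        d, coef, labels, _ = ksvd_one_sparse(x, 2, seed=7)
        _, cos = match_patterns(atoms, d.T)
        assert cos > 0.99
        assert label_accuracy(which + 1, labels + 1) > 0.99

    def test_objective_non_increasing(self, rng):
        x = rng.standard_normal((300, 10))
        _, _, _, info = ksvd_one_sparse(x, 4, seed=3)
        obj = np.asarray(info["objective"])
        assert np.all(np.diff(obj) <= 1e-8)

    def test_one_atom_per_timepoint(self, markov_data):
        _, ts_list, _ = markov_data
        wl = WL(n_states=3, seed=51).fit(ts_list)
        course, dfc = wl.apply(ts_list[0])
        assert course.labels.shape == (800,)
        assert dfc.n_timepoints == 800


class TestDeterminism:
    def test_same_seed_identical_fits(self, markov_data):
        _, ts_list, _ = markov_data
        for cls, kwargs in [
            (CAP, {"n_subject_clusters": 5}),
            (SWC, {"n_subject_clusters": 5}),
            (CHMM, {}),
            (WL, {}),
        ]:
            a = cls(n_states=3, seed=77, **kwargs).fit(ts_list)
            b = cls(n_states=3, seed=77, **kwargs).fit(ts_list)
            np.testing.assert_array_equal(
                a.state_set_.state_fc, b.state_set_.state_fc
            )
            np.testing.assert_array_equal(
                a.apply(ts_list[0])[0].labels, b.apply(ts_list[0])[0].labels
            )
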