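import numpy as np
import pytest

from gazepheno import subgroup as sg


class TestGaussianNaiveBayes:
    def test_forced_separation_perfect(self, rng):
        xa = rng.normal(0, 1, (20, 1))
        xb = rng.normal(10, 1, (20, 1))
        X = np.vstack([xa, xb])
        y = np.array(["A"] * 20 + ["B"] * 20)
        pred = sg.gnb_fit_predict(X, y, np.array([[0.5], [9.5]]))
        assert pred.tolist() == ["A", "B"]

    def test_hand_log_likelihood_ratio(self):
        # class A ~ N(0,1), class B ~ N(4,1), equal priors; x = 1 -> A
        X = np.array([[-1.0], [1.0], [3.0], [5.0]])
        y = np.array(["A", "A", "B", "B"])
        pred = sg.gnb_fit_predict(X, y, np.array([[1.0]]))
        assert pred[0] == "A"

    def test_posterior_tie_goes_to_majority(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0], [-1.5], [1.5]])
        y = np.array(["A", "A", "B", "B", "A", "B"])
        # symmetric classes, test point at 0 is equidistant; counts tie too,
        # so the first-listed class wins
        pred = sg.gnb_fit_predict(X, y, np.array([[0.0]]))
        assert pred[0] == "A"

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sg.gnb_fit_predict(np.zeros((4, 2)), np.array(["A"] * 4),
                               np.zeros((1, 2)))

    def test_matches_sklearn_reference(self, rng):
        from sklearn.naive_bayes import GaussianNB

        X = rng.normal(size=(60, 4))
        y = np.where(X[:, 0] + rng.normal(0, 1, 60) > 0, "P", "Q")
        if len(np.unique(y)) < 2 or min(np.sum(y == "P"),
                                        np.sum(y == "Q")) < 2:
            pytest.skip("degenerate draw")
        T = rng.normal(size=(40, 4))
        ours = sg.gnb_fit_predict(X, y, T)
        ref = GaussianNB().fit(X, y).predict(T)
        assert np.mean(ours == ref) > 0.95


class TestMixtureClustering:
    def test_planted_two_clusters_recovered(self, rng):
        X = np.vstack([rng.normal(0, 1, (60, 4)), rng.normal(8, 1, (40, 4))])
        for init_k in (5, 10):
            assign = sg.fit_mixture_clusters(X, init_k=init_k, seed=0)
            labels, counts = np.unique(assign, return_counts=True)
            assert len(labels) == 2
            assert sorted(counts.tolist()) == [40, 60]

    def test_identical_participants_single_cluster(self, rng):
        X = np.zeros((20, 4)) + rng.normal(0, 1e-9, (20, 4))
        assign = sg.fit_mixture_clusters(X, init_k=5, seed=0)
        assert len(np.unique(assign)) == 1

    def test_too_few_participants_rejected(self, rng):
        with pytest.raises(ValueError):
            sg.fit_mixture_clusters(rng.normal(size=(3, 4)), init_k=5)


class TestMergeSmallClusters:
    def test_small_cluster_dissolved_conserving_members(self, rng):
        X = np.vstack([rng.normal(0, 0.5, (60, 2)),
                       rng.normal(6, 0.5, (40, 2)),
                       rng.normal([0.4, 0.4], 0.1, (2, 2))])
        assign = np.array([0] * 60 + [1] * 40 + [2] * 2)
        merged = sg.merge_small_clusters(assign, X, min_size=4)
        labels, counts = np.unique(merged, return_counts=True)
        assert labels.tolist() == [0, 1]
        assert counts.sum() == 102
        assert counts[0] == 62  # small members joined the nearest mean

    def test_no_small_clusters_identity(self, rng):
        X = rng.normal(size=(20, 2))
        assign = np.array([0] * 10 + [1] * 10)
        np.testing.assert_array_equal(
            sg.merge_small_clusters(assign, X, min_size=4), assign)

    def test_tie_goes_to_lowest_cluster_index(self):
        X = np.array([[-1.0], [-1.0], [-1.0], [-1.0],
                      [1.0], [1.0], [1.0], [1.0], [0.0]])
        assign = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2])
        merged = sg.merge_small_clusters(assign, X, min_size=4)
        assert merged[-1] == 0

    def test_no_large_cluster_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            sg.merge_small_clusters(np.array([0, 1, 2]), X, min_size=4)


class TestCrossValidation:
    def _timeline(self, rng, shift=0.0, n_asd=18, n_td=36):
        from gazepheno.core import GROUP_ASD, GROUP_TD
        from gazepheno.timeline import TraitTimeline

        feats = {}
        base = rng.normal(size=(n_asd + n_td, 8)) * 5 + 70
        base[:n_asd, :] -= shift
        for ep in ("EpA", "EpB"):
            feats[ep] = base + rng.normal(0, 0.5, base.shape)
        groups = np.array([GROUP_ASD] * n_asd + [GROUP_TD] * n_td)
        pids = [f"p{i}" for i in range(n_asd + n_td)]
        return TraitTimeline(pids=pids, groups=groups,
                             episode_ids=["EpA", "EpB"],
                             episode_seconds=600.0, features=feats, metas={})

    def test_holdout_sizes_one_third(self, rng):
        tl = self._timeline(rng)
        res = sg.crossvalidated_classification(tl, n_iter=30, seed=0)
        counts = [v for v in res.participant_frequency.values()
                  if np.isfinite(v)]
        assert len(counts) == 54
        assert 0 <= res.mean_accuracy <= 1

    def test_identical_groups_near_majority_fraction(self, rng):
        tl = self._timeline(rng, shift=0.0)
        res = sg.crossvalidated_classification(tl, n_iter=300, seed=1)
        majority = 12 / 18  # held out: 6 ASD, 12 TD
        assert abs(res.mean_accuracy - majority) < 0.12

    def test_separated_groups_near_perfect(self, rng):
        tl = self._timeline(rng, shift=40.0)
        res = sg.crossvalidated_classification(tl, n_iter=100, seed=2)
        assert res.mean_accuracy > 0.95

    def test_null_calibrated_when_groups_identical(self, rng):
        tl = self._timeline(rng, shift=0.0)
        res = sg.crossvalidated_classification(tl, n_iter=200, seed=3)
        null, chance_95, p = sg.classification_null(
            tl, res.mean_accuracy, n_iter=200, seed=4)
        assert 0.05 < p
        assert res.mean_accuracy < chance_95

    def test_same_seed_reproducible(self, rng):
        tl = self._timeline(rng, shift=5.0)
        r1 = sg.crossvalidated_classification(tl, n_iter=50, seed=7)
        r2 = sg.crossvalidated_classification(tl, n_iter=50, seed=7)
        assert r1.mean_accuracy == r2.mean_accuracy


class TestWindowedClustering:
    def _planted_timeline(self, rng, n_per=30, sep=6.0):
        from gazepheno.core import GROUP_ASD, GROUP_TD
        from gazepheno.timeline import TraitTimeline

        base = np.vstack([rng.normal(70, 2, (n_per, 8)),
                          rng.normal(70 + sep, 2, (n_per, 8))])
        feats = {ep: base + rng.normal(0, 0.5, base.shape)
                 for ep in ("EpA", "EpB")}
        groups = np.array([GROUP_ASD, GROUP_TD] * n_per)
        return TraitTimeline(pids=[f"p{i}" for i in range(2 * n_per)],
                             groups=groups, episode_ids=["EpA", "EpB"],
                             episode_seconds=600.0, features=feats, metas={})

    def test_planted_split_recovered_in_every_window(self, rng):
        tl = self._planted_timeline(rng)
        res = sg.windowed_cluster_frequencies(tl, window_minutes=4.0,
                                              step_minutes=1.0, seed=0)
        assert np.all(res.n_clusters_per_window == 2)
        # every participant assigned to its planted cluster in every window
        planted = np.array([0] * 30 + [1] * 30)
        freq_max = res.assignment_frequency.max(axis=1)
        assert np.all(freq_max > 0.75)
        major = res.cluster_ids[res.assignment_frequency.argmax(axis=1)]
        assert len(np.unique(major[planted == 0])) == 1
        assert len(np.unique(major[planted == 1])) == 1
        assert major[0] != major[-1]

    def test_window_equal_timeline_single_window(self, rng):
        tl = self._planted_timeline(rng)
        res = sg.windowed_cluster_frequencies(
            tl, window_minutes=tl.total_seconds / 60.0, step_minutes=1.0,
            seed=0)
        assert res.n_windows == 1
        assert set(np.unique(res.assignment_frequency)) <= {0.0, 1.0}

    def test_window_exceeding_timeline_rejected(self, rng):
        tl = self._planted_timeline(rng)
        with pytest.raises(ValueError):
            sg.windowed_cluster_frequencies(tl, window_minutes=100.0)

    def test_assignment_frequencies_sum_to_one(self, rng):
        tl = self._planted_timeline(rng)
        res = sg.windowed_cluster_frequencies(tl, window_minutes=5.0,
                                              step_minutes=1.0, seed=1)
        np.testing.assert_allclose(res.assignment_frequency.sum(axis=1), 1.0)
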