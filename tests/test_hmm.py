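"""Context HMM: initialization, EM behaviour, Viterbi and summaries."""

import numpy as np
import pytest

import geomob
from geomob import clustering, hmm
from geomob.ingest import Trajectory, split_trajectories

from _oracles import viterbi_enumeration_oracle


def _traj(coords, user_id="u"):
    coords = np.asarray(coords, dtype=float)
    ts = np.arange(len(coords)).astype("datetime64[s]").astype("datetime64[ns]")
    return Trajectory(user_id, coords[:, 0].copy(), coords[:, 1].copy(), ts)


def _toy_model(means, covs, transition, initial, k=None):
    means = np.asarray(means, dtype=float)
    return hmm.UserModel(user_id="toy", means=means,
                         covariances=np.asarray(covs, dtype=float),
                         transition=np.asarray(transition, dtype=float),
                         initial=np.asarray(initial, dtype=float),
                         occupancy=np.full(len(means), 1.0 / len(means)),
                         log_likelihood=np.nan, n_events=0)


class TestInitFromClusters:
    def test_six_clusters_give_six_states(self, world10):
        events, _ = geomob.simulate_user(world10, 6, 600, seed=61)
        traj = split_trajectories(events)[0]
        assignment = clustering.dbscan(traj.coords, eps=0.5,
                                       min_pts=clustering.min_points_for_user(600))
        assert assignment.n_clusters == 6
        init = hmm.init_from_clusters(traj, assignment)
        assert init.k == 6
        init.validate()

    def test_all_noise_falls_back_to_single_state(self):
        coords = np.array([[0, 0], [3, 3], [6, 0], [9, 3]], dtype=float)
        traj = _traj(coords)
        assignment = clustering.ClusterAssignment(
            labels=np.full(4, -1), n_clusters=0, eps=0.5, min_pts=2)
        init = hmm.init_from_clusters(traj, assignment)
        assert init.k == 1
        np.testing.assert_allclose(init.means[0], coords.mean(axis=0))

    def test_hand_labelled_toy_centroids(self):
        coords = np.array([[0, 0], [0, 2], [0, 1], [10, 10], [10, 12], [10, 11]],
                          dtype=float)
        assignment = clustering.ClusterAssignment(
            labels=np.array([0, 0, 0, 1, 1, 1]), n_clusters=2, eps=0.5, min_pts=2)
        init = hmm.init_from_clusters(_traj(coords), assignment)
        np.testing.assert_allclose(init.means, [[0, 1], [10, 11]])
        assert init.transition[0, 0] == pytest.approx(0.9)
        np.testing.assert_allclose(init.initial, [0.5, 0.5])


class TestFitEM:
    def test_single_state_closed_form(self, rng):
        coords = rng.normal([1.0, 2.0], 0.3, size=(200, 2))
        traj = _traj(coords)
        res = geomob.ContextHMM(traj).fit()
        assert res.k == 1
        np.testing.assert_allclose(res.params.means[0], coords.mean(axis=0),
                                   atol=1e-9)
        d = coords - coords.mean(axis=0)
        ml_cov = hmm.floor_covariance(d.T @ d / len(coords))
        np.testing.assert_allclose(res.params.covariances[0], ml_cov, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_nondecreasing_every_iteration(self, world10, seed):
        events, _ = geomob.simulate_user(world10, 3, 250, seed=seed)
        traj = split_trajectories(events)[0]
        history = []
        model = geomob.ContextHMM(traj)
        init = model.initialize()
        hmm.fit_em(traj, init, callback=history.append)
        history = np.asarray(history)
        assert np.all(np.diff(history) >= -1e-8)

    def test_fit_improves_on_init(self, world10):
        events, _ = geomob.simulate_user(world10, 3, 250, seed=62)
        traj = split_trajectories(events)[0]
        model = geomob.ContextHMM(traj)
        init = model.initialize()
        fitted, _, _ = hmm.fit_em(traj, init)
        assert fitted.log_likelihood >= hmm.log_likelihood_of(init, traj.coords) - 1e-8

    def test_two_state_parameter_recovery(self, world10):
        events, truth = geomob.simulate_user(world10, 2, 2000, self_prob=0.9,
                                             emission_sd=0.1, seed=63)
        traj = split_trajectories(events)[0]
        res = geomob.ContextHMM(traj).fit()
        assert res.k == 2
        # match fitted states to truth by nearest mean
        order = np.argmin(
            ((res.params.means[:, None, :] - truth.means[None, :, :]) ** 2
             ).sum(axis=2), axis=1)
        assert set(order) == {0, 1}
        err = np.abs(res.params.means - truth.means[order]).max()
        assert err < 0.05
        self_trans = np.diag(res.params.transition)
        assert np.all(np.abs(self_trans - 0.9) < 0.05)

    def test_stochasticity_invariants_after_fit(self, fitted50):
        _, models = fitted50
        for m in models:
            m.validate()

    def test_loglik_matches_independent_hmm_library(self, world10):
        """Forward log-likelihood under fixed parameters agrees with hmmlearn."""
        import hmmlearn.hmm as hmmlearn
        events, truth = geomob.simulate_user(world10, 3, 200, seed=64)
        traj = split_trajectories(events)[0]
        model = _toy_model(truth.means, truth.covariances, truth.transition,
                           truth.initial)
        ours = hmm.log_likelihood_of(model, traj.coords)
        gh = hmmlearn.GaussianHMM(n_components=3, covariance_type="full",
                                  init_params="")
        gh.startprob_ = truth.initial
        gh.transmat_ = truth.transition
        gh.means_ = truth.means
        gh.covars_ = truth.covariances
        assert ours == pytest.approx(gh.score(traj.coords), rel=1e-8)


class TestViterbi:
    def test_single_state_all_zero_path(self):
        coords = np.random.default_rng(0).normal(size=(10, 2))
        model = _toy_model([[0, 0]], [np.eye(2)], [[1.0]], [1.0])
        np.testing.assert_array_equal(hmm.viterbi(_traj(coords), model),
                                      np.zeros(10, dtype=int))

    def test_matches_exhaustive_enumeration_on_toy(self):
        means = [[0.0, 0.0], [1.0, 1.0]]
        covs = [np.eye(2) * 0.5, np.eye(2) * 0.5]
        transition = [[0.8, 0.2], [0.3, 0.7]]
        initial = [0.6, 0.4]
        coords = np.array([[0.1, -0.2], [0.9, 1.1], [0.4, 0.6], [0.0, 0.1],
                           [1.2, 0.8], [1.0, 1.0]])
        model = _toy_model(means, covs, transition, initial)
        expected = viterbi_enumeration_oracle(initial, transition, means, covs,
                                              coords)
        np.testing.assert_array_equal(hmm.viterbi(_traj(coords), model), expected)

    def test_matches_enumeration_on_randomized_models(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            K = int(rng.integers(1, 4))
            T = int(rng.integers(2, 9))
            means = rng.uniform(-2, 2, (K, 2))
            covs = np.array([np.eye(2) * rng.uniform(0.1, 1.0) for _ in range(K)])
            transition = rng.dirichlet(np.ones(K) * rng.uniform(0.5, 3), size=K)
            initial = rng.dirichlet(np.ones(K))
            coords = rng.uniform(-2, 2, (T, 2))
            model = _toy_model(means, covs, transition, initial)
            got = hmm.viterbi(_traj(coords), model)
            expected = viterbi_enumeration_oracle(initial, transition, means,
                                                  covs, coords)
            np.testing.assert_array_equal(got, expected, err_msg=f"seed={seed}")

    def test_well_separated_states_reduce_to_nearest_mean(self, rng):
        means = np.array([[0.0, 0.0], [5.0, 5.0]])
        covs = np.array([np.eye(2) * 0.05 ** 2] * 2)
        model = _toy_model(means, covs, [[0.5, 0.5], [0.5, 0.5]], [0.5, 0.5])
        labels = rng.integers(0, 2, size=40)
        coords = means[labels] + rng.normal(0, 0.05, (40, 2))
        path = hmm.viterbi(_traj(coords), model)
        nearest = np.argmin(((coords[:, None, :] - means[None]) ** 2).sum(axis=2),
                            axis=1)
        np.testing.assert_array_equal(path, nearest)


class TestPathSummaries:
    def test_small_example(self):
        occ, counts = hmm.path_summaries(np.array([0, 0, 1, 1]), 2)
        np.testing.assert_allclose(occ, [0.5, 0.5])
        np.testing.assert_array_equal(counts, [[1, 1], [0, 1]])

    def test_constant_path(self):
        occ, counts = hmm.path_summaries(np.zeros(7, dtype=int), 2)
        np.testing.assert_allclose(occ, [1.0, 0.0])
        assert counts[0, 0] == 6 and counts.sum() == 6

    def test_matches_brute_force_pair_tally(self, rng):
        path = rng.integers(0, 4, size=200)
        occ, counts = hmm.path_summaries(path, 4)
        for i in range(4):
            assert occ[i] == np.mean(path == i)
            for j in range(4):
                brute = sum(1 for t in range(199)
                            if path[t] == i and path[t + 1] == j)
                assert counts[i, j] == brute


class TestResultsObject:
    def test_summary_mentions_fit_facts(self, world10):
        events, _ = geomob.simulate_user(world10, 2, 150, seed=65)
        res = geomob.ContextHMM(split_trajectories(events)[0]).fit()
        text = res.summary()
        assert "states (K):      2" in text
        assert "log-likelihood" in text

    def test_serialization_round_trip(self, tmp_path, fitted50):
        _, models = fitted50
        p = tmp_path / "models.json"
        hmm.write_models_json(models, p)
        back = hmm.read_models_json(p)
        assert len(back) == len(models)
        np.testing.assert_allclose(back[0].transition, models[0].transition)
        hmm.write_states_csv(models, tmp_path / "states.csv")
        hmm.write_transitions_csv(models, tmp_path / "tmat.csv")
        states = hmm.read_states_csv(tmp_path / "states.csv")
        tmats = hmm.read_transitions_csv(tmp_path / "tmat.csv")
        m0 = models[0]
        np.testing.assert_allclose(states[m0.user_id]["means"], m0.means)
        np.testing.assert_allclose(tmats[m0.user_id], m0.transition, atol=1e-12)
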