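"""Truncated EM machinery and the MCA model operations."""

import itertools

import numpy as np
import pytest

from maxcause import em, mca
from maxcause.mca import ModelParams

from conftest import brute_force_posterior, mean_max


class TestAnnealSchedule:
    def setup_method(self):
        self.cfg = em.ETConfig(H_prime=10, gamma=6, n_iterations=70)

    def test_starts_at_ten(self):
        assert em.anneal_temperature(0, self.cfg) == 10.0

    def test_second_half_is_one(self):
        for it in range(35, 70):
            assert em.anneal_temperature(it, self.cfg) == 1.0

    def test_linear_midpoint(self):
        mid = (35 - 1) / 2  # halfway through the annealing phase
        assert em.anneal_temperature(int(mid), self.cfg) == pytest.approx(5.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            em.anneal_temperature(70, self.cfg)


class TestSelectCandidates:
    def test_matching_column_ranks_first(self, tiny_model):
        W = tiny_model.W
        for h in range(W.shape[1]):
            cand = em.select_candidates(W[:, h], W, 3)
            assert h in cand

    def test_full_H_prime_selects_everything(self, tiny_model):
        y = np.ones(tiny_model.W.shape[0])
        cand = em.select_candidates(y, tiny_model.W, tiny_model.W.shape[1])
        np.testing.assert_array_equal(cand, np.arange(tiny_model.W.shape[1]))

    def test_matches_brute_force_top_k(self, rng):
        W = np.abs(rng.normal(size=(12, 20)))
        y = np.abs(rng.normal(size=12))
        scores = np.array(
            [y @ W[:, h] / (np.linalg.norm(y) * np.linalg.norm(W[:, h])) for h in range(20)]
        )
        expected = np.sort(np.argsort(-scores, kind="stable")[:7])
        np.testing.assert_array_equal(em.select_candidates(y, W, 7), expected)

    def test_zero_norm_input_returns_first_indices(self, tiny_model):
        cand = em.select_candidates(np.zeros(9), tiny_model.W, 3)
        np.testing.assert_array_equal(cand, [0, 1, 2])


class TestEnumerateStates:
    def test_state_count_for_paper_settings(self):
        states = em.enumerate_states(np.arange(10), 6, 1000)
        n_restricted = sum(
            len(list(itertools.combinations(range(10), k))) for k in range(7)
        )
        assert n_restricted == 848
        assert len(states) == 848 + (1000 - 10)

    def test_full_enumeration_when_untruncated(self):
        states = em.enumerate_states(np.arange(5), 5, 5)
        assert len(states) == 2**5
        assert len(np.unique(states, axis=0)) == 2**5

    def test_gamma_one_keeps_zero_and_singletons(self):
        states = em.enumerate_states(np.array([0, 2, 4]), 1, 5)
        assert len(states) == 6
        assert sorted(states.sum(axis=1).tolist()) == [0, 1, 1, 1, 1, 1]


class TestPosteriorWeights:
    def test_matches_exhaustive_oracle(self, tiny_model, rng):
        H = tiny_model.W.shape[1]
        states = em.enumerate_states(np.arange(H), H, H)
        for _ in range(5):
            y = np.abs(rng.normal(size=9))
            post = em.posterior_weights(y, states, tiny_model, T=1.0)
            ref_states, ref_w = brute_force_posterior(y, tiny_model, mean_max)
            lookup = {tuple(s.astype(int)): w for s, w in zip(ref_states, ref_w)}
            for s, w in zip(post.states, post.weights):
                assert w == pytest.approx(lookup[tuple(s)], abs=1e-10)

    def test_weights_normalized(self, tiny_model, rng):
        H = tiny_model.W.shape[1]
        states = em.enumerate_states(np.arange(H), 3, H)
        post = em.posterior_weights(np.abs(rng.normal(size=9)), states, tiny_model, T=2.0)
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_high_temperature_approaches_prior(self, tiny_model):
        H = tiny_model.W.shape[1]
        states = em.enumerate_states(np.arange(H), H, H)
        hot = tiny_model.replace(sigma=tiny_model.sigma * 1e4)  # T*sigma^2 huge
        post = em.posterior_weights(np.ones(9), states, hot, T=1.0)
        k = states.sum(axis=1)
        prior = tiny_model.pi**k * (1 - tiny_model.pi) ** (H - k)
        np.testing.assert_allclose(post.weights, prior / prior.sum(), rtol=1e-3)


class TestSuperpositionAndJoint:
    def test_single_active_returns_column(self, tiny_model):
        s = np.zeros(6)
        s[2] = 1
        np.testing.assert_array_equal(
            mca.logmax_superposition(tiny_model.W, s), tiny_model.W[:, 2]
        )

    def test_disjoint_supports_sum_equals_max(self):
        W = np.zeros((6, 2))
        W[:3, 0] = [1.0, 2.0, 3.0]
        W[3:, 1] = [4.0, 5.0, 6.0]
        s = np.ones(2)
        np.testing.assert_array_equal(mca.logmax_superposition(W, s), W.sum(axis=1))

    def test_duplicate_column_is_idempotent(self, tiny_model):
        W = np.hstack([tiny_model.W, tiny_model.W[:, [0]]])
        s_one = np.zeros(7)
        s_one[0] = 1
        s_dup = s_one.copy()
        s_dup[6] = 1
        np.testing.assert_array_equal(
            mca.logmax_superposition(W, s_one), mca.logmax_superposition(W, s_dup)
        )

    def test_non_binary_state_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            mca.logmax_superposition(tiny_model.W, np.full(6, 0.5))

    def test_log_joint_closed_form_at_zero_residual(self, tiny_model):
        s = np.zeros(6)
        s[1] = s[4] = 1
        y = mca.logmax_superposition(tiny_model.W, s)
        D, H, k = 9, 6, 2
        expected = (
            k * np.log(tiny_model.pi)
            + (H - k) * np.log(1 - tiny_model.pi)
            - (D / 2) * np.log(2 * np.pi * tiny_model.sigma**2)
        )
        assert mca.log_joint(y, s, tiny_model) == pytest.approx(expected, rel=1e-12)

    def test_sparser_state_wins_at_equal_residual(self, tiny_model):
        # pi < 0.5: fewer active units -> higher prior, equal likelihood
        y = np.zeros(9)
        s1 = np.zeros(6)
        s1[0] = 1
        s2 = s1.copy()
        s2[1] = 1
        shift = mca.log_joint(y, s1, tiny_model) - mca.log_joint(y, s2, tiny_model)
        resid1 = np.sum(mca.logmax_superposition(tiny_model.W, s1) ** 2)
        resid2 = np.sum(mca.logmax_superposition(tiny_model.W, s2) ** 2)
        prior_gap = np.log((1 - tiny_model.pi) / tiny_model.pi)
        assert shift == pytest.approx(
            prior_gap + (resid2 - resid1) / (2 * tiny_model.sigma**2), rel=1e-10
        )


class TestSoftmaxFieldAndDerivative:
    def test_single_active_unit(self, tiny_model):
        s = np.zeros(6)
        s[3] = 1
        Wbar, A = mca.softmax_field_and_derivative(tiny_model.W, s, rho=20.0)
        np.testing.assert_allclose(Wbar, tiny_model.W[:, 3], rtol=1e-12)
        np.testing.assert_allclose(A[:, 3], 1.0)
        assert np.all(A[:, [0, 1, 2, 4, 5]] == 0)

    def test_two_equal_active_closed_form(self):
        w = 0.7
        W = np.full((4, 2), w)
        Wbar, A = mca.softmax_field_and_derivative(W, np.ones(2), rho=20.0)
        np.testing.assert_allclose(Wbar, w * 2 ** (1 / 20), rtol=1e-12)
        np.testing.assert_allclose(A, 2 ** (1 / 20 - 1), rtol=1e-12)

    def test_large_rho_approaches_hard_max(self, rng):
        # rows are permutations of well-separated values, so the argmax is
        # unambiguous and the rho-softened responsibilities can concentrate
        base = np.geomspace(0.1, 1.0, 5)
        W = np.stack([rng.permutation(base) * rng.uniform(0.5, 2.0) for _ in range(20)])
        s = np.ones(5)
        Wbar, A = mca.softmax_field_and_derivative(W, s, rho=200.0)
        hard = W.max(axis=1)
        indicator = (W == hard[:, None]).astype(float)
        assert np.max(np.abs(Wbar - hard) / hard) < 1e-2
        assert np.max(np.abs(A - indicator)) < 1e-2


class TestMStep:
    def test_delta_posteriors_recover_class_means(self, bars_gt):
        # noise-free single-cause data with all posterior mass on the truth
        W = bars_gt.fields
        D, H = W.shape
        states = np.eye(H)
        posts = []
        Y = W.T.copy()  # one exemplar per cause
        params = ModelParams(W=np.abs(np.random.default_rng(0).normal(size=(D, H))), pi=0.2, sigma=0.1)
        for h in range(H):
            posts.append(
                em.TruncatedPosterior(
                    candidates=np.array([h]), states=states[[h]].astype(int), weights=np.array([1.0])
                )
            )
        new = mca.m_step(Y, posts, params, rho=20.0)
        # with singleton delta posteriors the update is the assigned-data mean
        # wherever the previous field was positive (a.s. everywhere here)
        assert np.all(params.W > 1e-12)
        np.testing.assert_allclose(new.W, W, rtol=1e-10, atol=1e-12)

    def test_all_mass_on_zero_state_hits_pi_floor(self, tiny_model):
        Y = np.zeros((4, 9))
        zero = np.zeros((1, 6), dtype=int)
        posts = [
            em.TruncatedPosterior(candidates=np.array([], int), states=zero, weights=np.array([1.0]))
            for _ in range(4)
        ]
        new = mca.m_step(Y, posts, tiny_model, rho=20.0)
        assert new.pi == pytest.approx(1.0 / (10 * 4 * 6))

    def test_perfect_reconstruction_drives_sigma_to_floor(self, tiny_model):
        s = np.zeros(6, dtype=int)
        s[2] = 1
        y = mca.logmax_superposition(tiny_model.W, s)
        post = em.TruncatedPosterior(
            candidates=np.array([2]), states=s[None, :], weights=np.array([1.0])
        )
        new = mca.m_step(y[None, :], [post], tiny_model, rho=20.0)
        assert new.sigma == pytest.approx(1e-8)


class TestInitialize:
    def test_pi_from_30_over_H(self):
        Y = np.abs(np.random.default_rng(0).normal(size=(50, 4)))
        cfg = em.ETConfig(H_prime=4, gamma=2, n_iterations=1, seed=0)
        assert em.initialize(Y, 1000, cfg).pi == pytest.approx(0.03)

    def test_zero_variance_data(self):
        Y = np.ones((10, 4))
        cfg = em.ETConfig(H_prime=2, gamma=2, n_iterations=1, seed=0)
        p = em.initialize(Y, 5, cfg)
        np.testing.assert_allclose(p.W, 1.0)
        assert p.sigma == pytest.approx(1e-6)

    def test_seeded_determinism(self):
        Y = np.abs(np.random.default_rng(0).normal(size=(50, 4)))
        cfg = em.ETConfig(H_prime=4, gamma=2, n_iterations=1, seed=7)
        p1, p2 = em.initialize(Y, 6, cfg), em.initialize(Y, 6, cfg)
        np.testing.assert_array_equal(p1.W, p2.W)


class TestEngineAgainstReference:
    def test_batch_engine_equals_per_datapoint_em(self, exhaustive_cfg):
        """The compiled batch engine must reproduce the reference operations."""
        from maxcause import synth

        gt = synth.make_ground_truth_fields("bars", (3, 3), 6, seed=0, pi=0.25, sigma=0.05)
        Y, _ = synth.sample_mca_dataset(gt, 120, seed=1)
        H = 6
        p_engine, _ = em.fit_et(Y, H, exhaustive_cfg, model="mca")
        p_ref = em.initialize(Y, H, exhaustive_cfg)
        states = em.enumerate_states(np.arange(H), 6, H)
        for _ in range(exhaustive_cfg.n_iterations):
            posts = [em.posterior_weights(Y[n], states, p_ref, T=1.0) for n in range(len(Y))]
            p_ref = mca.m_step(Y, posts, p_ref, rho=20.0)
        np.testing.assert_allclose(p_engine.W, p_ref.W, atol=1e-8)
        assert p_engine.pi == pytest.approx(p_ref.pi, abs=1e-10)
        assert p_engine.sigma == pytest.approx(p_ref.sigma, abs=1e-10)

    def test_nonnegativity_preserved_by_every_iteration(self):
        from maxcause import synth

        gt = synth.make_ground_truth_fields("bars", (4, 4), 8, seed=0, pi=0.2, sigma=0.05)
        Y, _ = synth.sample_mca_dataset(gt, 200, seed=2)
        cfg = em.ETConfig(H_prime=6, gamma=3, n_iterations=8, seed=0)
        params, _ = em.fit_et(Y, 8, cfg, model="mca")
        assert params.W.min() >= 0

    def test_free_energy_increases_after_annealing(self):
        """Post-annealing, the truncated free energy climbs and stays up.

        The W update is the rho-softened fixed-point step rather than an
        exact maximizer, so near convergence the free energy can oscillate
        by a few parts in 1e4 (a limit cycle of the approximate M-step);
        the sequence must still show no net decrease and no step may fall
        by more than that oscillation scale.
        """
        from maxcause import synth

        gt = synth.make_ground_truth_fields("bars", (4, 4), 8, seed=0, pi=0.2, sigma=0.05)
        Y, _ = synth.sample_mca_dataset(gt, 800, seed=3)
        cfg = em.ETConfig(
            H_prime=8, gamma=8, n_iterations=16, seed=0, anneal_T_start=5.0, anneal_fraction=0.25
        )
        _, monitor = em.fit_et(Y, 8, cfg, model="mca", n_restarts=3)
        F = monitor["free_energy"]
        # free energy is logged for the incoming parameters, so entries from
        # the post-annealing phase onward reflect T=1 EM steps
        tail = F[5:]
        for a, b in zip(tail, tail[1:]):
            assert b >= a - 1e-3 * max(1.0, abs(a))
        assert tail[-1] >= tail[0]
        assert max(tail) > F[5] - 1e-9  # the climb is real, not flat noise


class TestFitRecoverySmall:
    def test_bars_recovery_quick(self, bars_gt):
        from maxcause import synth
        from conftest import best_permutation_cosine

        Y, _ = synth.sample_mca_dataset(bars_gt, 800, seed=4)
        cfg = em.ETConfig(H_prime=8, gamma=4, n_iterations=30, seed=0, anneal_T_start=3.0)
        params, monitor = mca.fit_mca(Y, 10, cfg, n_restarts=3)
        assert best_permutation_cosine(bars_gt.fields, params.W) > 0.95
        assert len(monitor["free_energy"]) == 30
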