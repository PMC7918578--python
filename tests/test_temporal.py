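"""Transition estimation, emission coupling, and Viterbi decoding."""

import itertools

import numpy as np
import pytest

from surgspeech.corpus import N_PHASES
from surgspeech.temporal import (
    EmissionSeq,
    TransitionModel,
    estimate_transitions,
    posteriors_to_emissions,
    viterbi,
)


def brute_force_viterbi(tm, em, n_states):
    """Exhaustive enumeration over the first `n_states` states.

    On score ties the kept path is the one that is lexicographically
    smallest when read from the end, matching a backtracking decoder
    that prefers the lowest state index at every step.  Scores accumulate
    in the same association order as the dynamic program so that exact
    float comparisons agree.
    """
    with np.errstate(divide="ignore"):
        logA = np.log(tm.A)
        logpi = np.log(tm.pi)
        logB = np.log(em.scores)
    T = logB.shape[0]
    best_path, best_score = None, -np.inf
    for path in itertools.product(range(n_states), repeat=T):
        score = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            score = score + logA[path[t - 1], path[t]]
            score = score + logB[t, path[t]]
        if score > best_score or (
            score == best_score
            and tuple(reversed(path)) < tuple(reversed(best_path))
        ):
            best_path, best_score = path, score
    return [s + 1 for s in best_path], best_score


def _uniform_tm():
    A = np.full((N_PHASES, N_PHASES), 1 / N_PHASES)
    pi = np.full(N_PHASES, 1 / N_PHASES)
    return TransitionModel(A, pi, alpha=0.0)


class TestEstimateTransitions:
    def test_hand_arithmetic_oracle(self):
        """[[1,1,2]] with alpha=1: A[1->1] = A[1->2] = (1+1)/(2+8)."""
        tm = estimate_transitions([[1, 1, 2]], alpha=1.0)
        assert tm.A[0, 0] == pytest.approx(0.2)
        assert tm.A[0, 1] == pytest.approx(0.2)
        assert tm.A[0, 2] == pytest.approx(0.1)  # unseen target
        assert tm.pi[0] == pytest.approx(2 / 9)  # (1+1)/(1+8)
        np.testing.assert_allclose(tm.A.sum(axis=1), 1.0)
        assert tm.pi.sum() == pytest.approx(1.0)

    def test_large_alpha_tends_to_uniform(self):
        tm = estimate_transitions([[1, 2, 3]], alpha=1e9)
        np.testing.assert_allclose(tm.A, 1 / 8, atol=1e-6)
        np.testing.assert_allclose(tm.pi, 1 / 8, atol=1e-6)

    def test_alpha_zero_forbids_unseen_transitions(self):
        with pytest.warns(UserWarning):  # most states never observed
            tm = estimate_transitions([[1, 2], [1, 2]], alpha=0.0)
        assert tm.A[0, 1] == 1.0
        assert tm.A[0, 0] == 0.0

    def test_zero_count_rows_uniform_with_warning(self):
        with pytest.warns(UserWarning, match="never leave"):
            tm = estimate_transitions([[1, 2]], alpha=0.0)
        np.testing.assert_allclose(tm.A[2], 1 / 8)  # phase 3 never seen

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_transitions([])
        with pytest.raises(ValueError):
            estimate_transitions([[]])

    def test_extra_boost_loosens_pseudo_phase_transitions(self):
        tm = estimate_transitions([[1, 2, 3]], alpha=0.01)
        boosted = tm.boost_extra(0.5)
        assert (boosted.A[:, 7] > tm.A[:, 7]).all()
        np.testing.assert_allclose(boosted.A.sum(axis=1), 1.0)


class TestEmissions:
    def test_posterior_mode_floors(self):
        post = np.array([[1.0, 0.0]])
        em = posteriors_to_emissions(post, [1, 2], mode="posterior", floor=1e-6)
        assert em.scores[0, 0] == 1.0
        assert em.scores[0, 1] == 1e-6
        assert (em.scores[0, 2:] == 1e-6).all()  # unseen phases at floor

    def test_scaled_likelihood_divides_by_prior(self):
        post = np.array([[0.5, 0.5]])
        em = posteriors_to_emissions(
            post, [1, 2], class_priors=[0.5, 0.25], mode="scaled_likelihood"
        )
        # prior(1) = 2 * prior(2) with equal posteriors -> b(2) = 2 * b(1)
        assert em.scores[0, 1] == pytest.approx(2 * em.scores[0, 0])

    def test_uniform_priors_preserve_viterbi_path(self, rng):
        post = rng.dirichlet(np.ones(8), size=6)
        tm = _uniform_tm()
        p1 = viterbi(tm, posteriors_to_emissions(post, range(1, 9), mode="posterior"))
        p2 = viterbi(tm, posteriors_to_emissions(
            post, range(1, 9), class_priors=np.full(8, 1 / 8),
            mode="scaled_likelihood"))
        assert p1.phases == p2.phases

    def test_zero_prior_rejected(self):
        with pytest.raises(ValueError, match="priors"):
            posteriors_to_emissions(
                np.array([[1.0, 0.0]]), [1, 2], class_priors=[1.0, 0.0],
                mode="scaled_likelihood",
            )

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            posteriors_to_emissions(np.ones((1, 2)) / 2, [1, 2], mode="map")


class TestViterbi:
    def test_uniform_transitions_reduce_to_argmax(self, rng):
        em = EmissionSeq(rng.random((10, 8)) + 1e-3, "test")
        tl = viterbi(_uniform_tm(), em)
        assert tl.phases == [int(i) + 1 for i in em.scores.argmax(axis=1)]

    def test_absorbing_transitions_give_constant_path(self, rng):
        A = np.eye(N_PHASES)
        pi = np.zeros(N_PHASES)
        pi[4] = 1.0
        tm = TransitionModel(A, pi, alpha=0.0)
        em = EmissionSeq(rng.random((7, 8)) + 1e-3, "test")
        assert viterbi(tm, em).phases == [5] * 7

    def test_log_score_equals_path_objective(self, rng):
        tm = estimate_transitions([[1, 2, 3, 8, 4]], alpha=0.1)
        em = EmissionSeq(rng.random((5, 8)) + 1e-3, "test")
        tl = viterbi(tm, em)
        states = [p - 1 for p in tl.phases]
        score = np.log(tm.pi[states[0]]) + np.log(em.scores[0, states[0]])
        for t in range(1, 5):
            score += np.log(tm.A[states[t - 1], states[t]])
            score += np.log(em.scores[t, states[t]])
        assert tl.log_score == pytest.approx(score)

    def test_matches_brute_force_small_instance(self, rng):
        A = np.zeros((N_PHASES, N_PHASES))
        A[:3, :3] = rng.dirichlet(np.ones(3), size=3)
        A[3:] = 1 / N_PHASES
        pi = np.zeros(N_PHASES)
        pi[:3] = rng.dirichlet(np.ones(3))
        tm = TransitionModel(A, pi, alpha=0.0)
        scores = np.full((4, N_PHASES), 1e-12)
        scores[:, :3] = rng.random((4, 3)) + 1e-3
        em = EmissionSeq(scores, "test")
        expected_path, expected_score = brute_force_viterbi(tm, em, 3)
        tl = viterbi(tm, em)
        assert tl.phases == expected_path
        assert tl.log_score == pytest.approx(expected_score)

    def test_matches_hmmlearn_decoder(self, rng):
        """Independent cross-check against hmmlearn's Viterbi."""
        import hmmlearn.hmm

        tm = estimate_transitions(
            [[1, 1, 2, 3, 8, 4, 5], [1, 2, 2, 3, 4, 6, 7]], alpha=0.05
        )
        n_symbols = 5
        E = rng.dirichlet(np.ones(n_symbols), size=8)  # row-stochastic
        obs = rng.integers(0, n_symbols, size=12)

        model = hmmlearn.hmm.CategoricalHMM(n_components=8)
        model.startprob_ = tm.pi
        model.transmat_ = tm.A
        model.emissionprob_ = E
        ref_states = model.predict(obs.reshape(-1, 1))

        em = EmissionSeq(E[:, obs].T, "categorical")
        ours = viterbi(tm, em)
        assert ours.phases == [int(s) + 1 for s in ref_states]

    def test_optimality_witness_beats_argmax_path(self, rng):
        """The decoded path scores at least as high as the raw per-step
        argmax path under the same model, over 20 seeded instances."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            tm = estimate_transitions([[1, 2, 3, 4, 5, 6, 7]], alpha=0.05)
            em = EmissionSeq(r.random((8, 8)) + 1e-6, "test")
            tl = viterbi(tm, em)

            def path_score(states):
                with np.errstate(divide="ignore"):
                    s = np.log(tm.pi[states[0]]) + np.log(em.scores[0, states[0]])
                    for t in range(1, len(states)):
                        s += np.log(tm.A[states[t - 1], states[t]])
                        s += np.log(em.scores[t, states[t]])
                return s

            argmax_states = list(em.scores.argmax(axis=1))
            assert tl.log_score >= path_score(argmax_states) - 1e-12

    def test_monotone_decoding_when_backward_transitions_forbidden(self, rng):
        """alpha = 0 on a single strictly ordered training sequence makes
        backward jumps impossible; decoded paths are monotone."""
        with pytest.warns(UserWarning):  # phase 7 never leaves
            tm = estimate_transitions([[1, 2, 3, 4, 5, 6, 7]], alpha=0.0)
        tm.A[6] = 0.0
        tm.A[6, 6] = 1.0  # make the terminal phase absorbing
        for _ in range(5):
            em = EmissionSeq(rng.random((10, 8)) + 1e-9, "test")
            phases = viterbi(tm, em).phases
            assert phases == sorted(phases)

    def test_empty_emissions_rejected(self):
        with pytest.raises(ValueError):
            viterbi(_uniform_tm(), EmissionSeq(np.ones((0, 8)), "t"))
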