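"""Discrete HMM: exhaustive-path oracles, EM guarantees, VQ, classification."""

import itertools

import numpy as np
import pytest

from frcc.errors import InsufficientDataError
from frcc.hmm import (
    Codebook,
    HmmModel,
    baum_welch_fit,
    classify,
    forward_loglik,
    sample,
    vq_assign,
    vq_fit,
    viterbi,
)


def brute_force_loglik(obs, model):
    """Sum P(path, obs) over every state path (independent oracle)."""
    total = 0.0
    for path in itertools.product(range(model.n_states), repeat=len(obs)):
        p = model.pi[path[0]] * model.B[path[0], obs[0]]
        for t in range(1, len(obs)):
            p *= model.A[path[t - 1], path[t]] * model.B[path[t], obs[t]]
        total += p
    return np.log(total)


def brute_force_viterbi(obs, model):
    best, best_p = None, -np.inf
    for path in itertools.product(range(model.n_states), repeat=len(obs)):
        p = model.pi[path[0]] * model.B[path[0], obs[0]]
        for t in range(1, len(obs)):
            p *= model.A[path[t - 1], path[t]] * model.B[path[t], obs[t]]
        logp = np.log(p) if p > 0 else -np.inf
        if logp > best_p:  # strict: first (lexicographically lowest) tie wins
            best, best_p = path, logp
    return np.array(best), best_p


@pytest.fixture()
def model_345():
    """Fixed N=3, M=4 model with printed-in-test matrices."""
    A = np.array([[0.6, 0.3, 0.1],
                  [0.2, 0.5, 0.3],
                  [0.3, 0.3, 0.4]])
    B = np.array([[0.7, 0.1, 0.1, 0.1],
                  [0.1, 0.6, 0.2, 0.1],
                  [0.25, 0.25, 0.25, 0.25]])
    pi = np.array([0.5, 0.3, 0.2])
    return HmmModel(A=A, B=B, pi=pi)


class TestModelValidation:
    def test_rows_must_be_stochastic(self):
        with pytest.raises(ValueError):
            HmmModel(A=np.array([[0.5, 0.4], [0.5, 0.5]]),
                     B=np.full((2, 3), 1 / 3), pi=np.array([0.5, 0.5]))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            HmmModel(A=np.array([[1.5, -0.5], [0.5, 0.5]]),
                     B=np.full((2, 3), 1 / 3), pi=np.array([0.5, 0.5]))


class TestForward:
    def test_single_state_closed_form(self):
        model = HmmModel(A=np.ones((1, 1)), B=np.array([[0.2, 0.3, 0.5]]),
                         pi=np.ones(1))
        obs = [0, 2, 1, 2]
        expected = sum(np.log(model.B[0, o]) for o in obs)
        assert forward_loglik(obs, model) == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_enumeration(self, model_345):
        obs = np.array([0, 2, 1, 3, 0])
        assert forward_loglik(obs, model_345) == pytest.approx(
            brute_force_loglik(obs, model_345), abs=1e-10)

    def test_uniform_model_closed_form(self):
        n, m, T = 3, 4, 7
        model = HmmModel(A=np.full((n, n), 1 / n), B=np.full((n, m), 1 / m),
                         pi=np.full(n, 1 / n))
        obs = np.array([0, 1, 2, 3, 0, 1, 2])
        assert forward_loglik(obs, model) == pytest.approx(T * np.log(1 / m),
                                                           abs=1e-12)

    def test_out_of_range_symbol(self, model_345):
        with pytest.raises(ValueError):
            forward_loglik([0, 4], model_345)


class TestViterbi:
    def test_deterministic_chain(self):
        # permutation-like transitions force the unique consistent path
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        B = np.array([[1.0, 0.0], [0.0, 1.0]])
        model = HmmModel(A=A, B=B, pi=np.array([1.0, 0.0]))
        path, logp = viterbi([0, 1, 0, 1], model)
        assert np.array_equal(path, [0, 1, 0, 1])
        assert logp == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_argmax(self, model_345):
        obs = np.array([1, 1, 3, 0, 2])
        path, logp = viterbi(obs, model_345)
        bf_path, bf_logp = brute_force_viterbi(obs, model_345)
        assert logp == pytest.approx(bf_logp, abs=1e-10)
        assert np.array_equal(path, bf_path)

    def test_tie_broken_toward_lower_state(self):
        n, m = 3, 2
        model = HmmModel(A=np.full((n, n), 1 / n), B=np.full((n, m), 1 / m),
                         pi=np.full(n, 1 / n))
        path, _ = viterbi([0, 1, 0], model)
        assert np.array_equal(path, [0, 0, 0])

    def test_path_probability_bounded_by_total(self, model_345):
        rng = np.random.default_rng(2)
        for _ in range(10):
            obs = rng.integers(0, 4, size=6)
            _, logp = viterbi(obs, model_345)
            assert logp <= forward_loglik(obs, model_345) + 1e-12


class TestBaumWelch:
    def test_loglik_monotone(self, model_345):
        rng = np.random.default_rng(12)
        seqs = [sample(model_345, 40, rng) for _ in range(20)]
        fitted = baum_welch_fit(seqs, n_states=3, n_symbols=4, seed=5, max_iter=30)
        history = np.array(fitted.train_history)
        assert (np.diff(history) >= -1e-8).all()

    def test_stochasticity_preserved(self, model_345):
        rng = np.random.default_rng(13)
        seqs = [sample(model_345, 30, rng) for _ in range(10)]
        fitted = baum_welch_fit(seqs, n_states=3, n_symbols=4, seed=1, max_iter=15)
        np.testing.assert_allclose(fitted.A.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(fitted.B.sum(axis=1), 1.0, atol=1e-10)
        assert fitted.pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_iterations_returns_seeded_init(self):
        fitted = baum_welch_fit([[0, 1, 0]], n_states=2, n_symbols=2,
                                seed=7, max_iter=0)
        again = baum_welch_fit([[0, 1, 0]], n_states=2, n_symbols=2,
                               seed=7, max_iter=0)
        assert np.array_equal(fitted.A, again.A)
        assert np.array_equal(fitted.B, again.B)
        assert fitted.train_history == []

    def test_parameter_recovery(self):
        """2-state/3-symbol generator recovered within 0.05 entrywise."""
        truth = HmmModel(
            A=np.array([[0.9, 0.1], [0.2, 0.8]]),
            B=np.array([[0.8, 0.15, 0.05], [0.05, 0.15, 0.8]]),
            pi=np.array([0.6, 0.4]),
        )
        rng = np.random.default_rng(31)
        seqs = [sample(truth, 50, rng) for _ in range(200)]
        fitted = baum_welch_fit(seqs, n_states=2, n_symbols=3, seed=3,
                                max_iter=200, tol=1e-9, n_restarts=5)
        errs = []
        for perm in ([0, 1], [1, 0]):
            errs.append(max(
                np.abs(fitted.A[np.ix_(perm, perm)] - truth.A).max(),
                np.abs(fitted.B[perm] - truth.B).max(),
            ))
        assert min(errs) < 0.05

    def test_empty_corpus_rejected(self):
        with pytest.raises(InsufficientDataError):
            baum_welch_fit([], n_states=2, n_symbols=2, seed=0)

    def test_matches_hmmlearn_likelihood(self, model_345):
        """Cross-check the forward algorithm against hmmlearn."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        ref = hmmlearn.CategoricalHMM(n_components=3)
        ref.startprob_ = model_345.pi
        ref.transmat_ = model_345.A
        ref.emissionprob_ = model_345.B
        obs = np.array([0, 2, 1, 3, 0, 1, 1, 2])
        assert forward_loglik(obs, model_345) == pytest.approx(
            ref.score(obs.reshape(-1, 1)), abs=1e-10)


class TestVectorQuantization:
    def test_recovers_separated_blobs(self):
        rng = np.random.default_rng(17)
        k, per, sigma = 4, 200, 0.05
        means = np.array([[0, 0], [5, 0], [0, 5], [5, 5.0]])
        X = np.vstack([m + sigma * rng.standard_normal((per, 2)) for m in means])
        book = vq_fit(X, k, seed=1)
        tol = 3 * sigma / np.sqrt(per)
        for m in means:
            assert np.linalg.norm(book.centroids - m, axis=1).min() < tol

    def test_inertia_non_increasing(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((300, 5))
        book = vq_fit(X, 6, seed=2)
        assert (np.diff(book.inertia_history) <= 1e-9).all()

    def test_k_equals_t_zero_error(self):
        rng = np.random.default_rng(19)
        X = rng.standard_normal((8, 3))
        book = vq_fit(X, 8, seed=0)
        assert book.inertia_history[-1] == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_points_documented_tiebreak(self):
        X = np.ones((10, 2))
        book = vq_fit(X, 2, seed=0)
        assert book.centroids.shape == (2, 2)
        np.testing.assert_allclose(book.centroids, 1.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            vq_fit(np.ones((3, 2)), 4, seed=0)


class TestClassify:
    @pytest.fixture()
    def separated_pair(self):
        m_true = HmmModel(A=np.array([[0.9, 0.1], [0.1, 0.9]]),
                          B=np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05]]),
                          pi=np.array([0.5, 0.5]))
        m_lie = HmmModel(A=np.array([[0.5, 0.5], [0.5, 0.5]]),
                         B=np.array([[0.05, 0.05, 0.9], [0.9, 0.05, 0.05]]),
                         pi=np.array([0.5, 0.5]))
        book = Codebook(centroids=np.array([[0.0, 0], [1, 0], [0, 1.0]]))
        return book, m_true, m_lie

    def test_samples_from_true_model_recognized(self, separated_pair):
        book, m_true, m_lie = separated_pair
        rng = np.random.default_rng(23)
        hits = 0
        for _ in range(100):
            obs = sample(m_true, 200, rng)
            feats = book.centroids[obs]  # vectors quantizing back to obs
            hits += classify(feats, book, m_true, m_lie) == 0
        assert hits > 90

    def test_tie_goes_to_omega1(self, separated_pair):
        book, m_true, _ = separated_pair
        feats = book.centroids[[0, 1, 0]]
        assert classify(feats, book, m_true, m_true, labels=("w1", "w2")) == "w1"

    def test_single_frame_sequence(self, separated_pair):
        book, m_true, m_lie = separated_pair
        assert classify(book.centroids[[0]], book, m_true, m_lie) in (0, 1)

    def test_symbol_alphabet_must_match(self, separated_pair):
        book, m_true, _ = separated_pair
        other = HmmModel(A=np.ones((1, 1)), B=np.full((1, 4), 0.25), pi=np.ones(1))
        with pytest.raises(ValueError):
            classify(book.centroids[[0]], book, m_true, other)


def test_vq_assign_roundtrip():
    book = Codebook(centroids=np.array([[0.0, 0.0], [10.0, 10.0]]))
    X = np.array([[0.1, -0.1], [9.8, 10.2], [0.0, 0.4]])
    assert np.array_equal(vq_assign(X, book), [0, 1, 0])
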