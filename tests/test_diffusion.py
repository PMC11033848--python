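"""Forward kernels, closed-form posteriors and the training loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import promptdiff as pd
from promptdiff.diffusion import (LossBreakdown, forward_noise_step,
                                  make_schedule, training_loss)
from promptdiff.nn import Tensor


class TestSchedule:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(T=st.integers(1, 200), kind=st.sampled_from(["sigmoid", "linear",
                                                        "cosine"]))
    def test_invariants(self, T, kind):
        s = make_schedule(T, kind)
        assert len(s.beta) == len(s.alpha) == len(s.alpha_bar) == T
        assert np.all((s.beta > 0) & (s.beta < 1))
        assert np.allclose(s.alpha, 1 - s.beta)
        assert np.all(np.diff(s.alpha_bar) < 0) or T == 1
        assert np.all((s.alpha_bar > 0) & (s.alpha_bar < 1))

    def test_alpha_bar_is_running_product(self):
        s = make_schedule(10)
        prod = 1.0
        for t in range(1, 11):
            prod *= s.alpha_at(t)
            assert abs(s.alpha_bar_at(t) - prod) <= 1e-12 * abs(prod)

    def test_default_length_and_single_step(self):
        assert make_schedule().T == 1000
        s = make_schedule(1, "explicit", {"beta": [0.1]})
        assert np.isclose(s.alpha_bar_at(1), 0.9)

    def test_beta_tilde_bounds(self):
        s = make_schedule(50)
        assert s.beta_tilde_at(1) == 0.0  # alpha_bar(0) := 1
        for t in range(1, 51):
            assert s.beta_tilde_at(t) <= s.beta_at(t) + 1e-15

    def test_rejects_bad_params(self):
        with pytest.raises(ValueError):
            make_schedule(0)
        with pytest.raises(ValueError, match="t=2"):
            make_schedule(3, "explicit", {"beta": [0.1, 1.5, 0.1]})


class TestForwardNoise:
    def test_no_noise_limit(self, vocab):
        s = make_schedule(5, "explicit", {"beta": [1e-9] * 5})
        x0 = np.array([[1.0, 2.0, 3.0], [0.0, -1.0, 0.5]])
        h0 = vocab.one_hot(["C", "O"])
        rng = np.random.default_rng(0)
        x_t, h_t = pd.forward_noise(x0, h0, 1, s, rng)
        assert np.allclose(x_t, x0, atol=1e-4)
        assert np.array_equal(h_t, h0)

    def test_terminal_marginal_is_noise(self, vocab):
        """At alpha_bar ~ 0 coordinates are standard normal and types
        uniform, within Monte-Carlo error."""
        s = make_schedule(3, "explicit", {"beta": [0.9, 0.9, 0.9]})
        x0 = np.array([[5.0, -5.0, 2.0]])
        h0 = vocab.one_hot(["C"])
        rng = np.random.default_rng(1)
        n = 10_000
        xs = np.empty((n, 3))
        counts = np.zeros(vocab.K)
        for i in range(n):
            x_t, h_t = pd.forward_noise(x0, h0, 3, s, rng)
            xs[i] = x_t[0]
            counts += h_t[0]
        ab = s.alpha_bar_at(3)
        se_mean = np.sqrt(1 - ab) / np.sqrt(n)
        assert np.all(np.abs(xs.mean(0) - np.sqrt(ab) * x0[0]) < 3 * se_mean
                      + 3 * abs(np.sqrt(ab)) * 0)
        freq = counts / n
        p_c = ab + (1 - ab) / vocab.K      # the original type
        p_other = (1 - ab) / vocab.K
        se = np.sqrt(p_other * (1 - p_other) / n)
        expected = np.full(vocab.K, p_other)
        expected[vocab.index("C")] = p_c
        assert np.all(np.abs(freq - expected) < 3 * se + 3e-3)

    def test_kernel_composition_matches_marginal(self, vocab):
        """Composing T=5 single-step kernels reproduces the closed-form
        marginal mean and variance within 3 standard errors."""
        s = make_schedule(5, "linear", {"beta_min": 0.05, "beta_max": 0.3})
        x0 = np.array([[2.0, 0.0, -1.0]])
        h0 = vocab.one_hot(["N"])
        rng = np.random.default_rng(2)
        n = 10_000
        xs = np.empty((n, 3))
        for i in range(n):
            x, h = x0, h0
            for t in range(1, 6):
                x, h = forward_noise_step(x, h, t, s, rng)
            xs[i] = x[0]
        ab = s.alpha_bar_at(5)
        mean_th = np.sqrt(ab) * x0[0]
        var_th = 1 - ab
        se_mean = np.sqrt(var_th / n)
        se_var = var_th * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(xs.mean(0) - mean_th) < 3 * se_mean)
        assert np.all(np.abs(xs.var(0) - var_th) < 3 * se_var)

    def test_rejects_bad_inputs(self, vocab):
        s = make_schedule(5)
        x0 = np.zeros((1, 3))
        h0 = vocab.one_hot(["C"])
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            pd.forward_noise(x0, h0, 6, s, rng)
        with pytest.raises(ValueError):
            pd.forward_noise(x0, h0 * 0.5, 1, s, rng)


def brute_force_theta_post(h_t, h0, t, schedule):
    """Bayes-rule enumeration over all K previous-step states."""
    K = len(h_t)
    ab_prev = schedule.alpha_bar_at(t - 1)
    b = schedule.beta_at(t)
    post = np.zeros(K)
    for j in range(K):
        # q(h_t | h_{t-1}=e_j) evaluated at the observed h_t, times the
        # closed-form marginal prior q(h_{t-1}=e_j | h0)
        lik = (1 - b) * h_t[j] + b / K
        prior = ab_prev * h0[j] + (1 - ab_prev) / K
        post[j] = lik * prior
    return post / post.sum()


class TestPosterior:
    def test_zero_noise_limit(self, vocab):
        s = make_schedule(3, "explicit", {"beta": [1e-10, 0.1, 0.1]})
        x0 = np.array([[1.0, 1.0, 1.0]])
        h0 = vocab.one_hot(["C"])
        post = pd.posterior_params(x0 * 0.9, x0, h0, h0, 1, s)
        assert np.allclose(post.mu_tilde, x0, atol=1e-6)
        assert np.allclose(post.theta_post, h0, atol=1e-9)
        assert post.beta_tilde == 0.0

    def test_matches_bayes_enumeration(self):
        """theta_post from the printed product formula equals explicit
        Bayes-rule enumeration for every (h_t, h0, t), K<=5, T<=10."""
        for K in (2, 3, 5):
            vocab = pd.AtomVocabulary(tuple("CNOFS"[:K]))
            s = make_schedule(10, "linear", {"beta_min": 0.02, "beta_max": 0.4})
            eye = np.eye(K)
            x = np.zeros((1, 3))
            for t in range(1, 11):
                for i in range(K):
                    for j in range(K):
                        post = pd.posterior_params(x, x, eye[[i]], eye[[j]],
                                                   t, s)
                        oracle = brute_force_theta_post(eye[i], eye[j], t, s)
                        assert np.max(np.abs(post.theta_post[0] - oracle)) \
                            < 1e-10
            assert vocab.K == K

    def test_theta_rows_normalized(self, vocab):
        s = make_schedule(10)
        rng = np.random.default_rng(3)
        h_t = vocab.one_hot(["C", "O", "N"])
        h0 = vocab.one_hot(["S", "O", "C"])
        post = pd.posterior_params(rng.normal(size=(3, 3)),
                                   rng.normal(size=(3, 3)), h_t, h0, 5, s)
        assert np.all(post.theta_post >= 0)
        assert np.allclose(post.theta_post.sum(1), 1.0, atol=1e-10)

    def test_fixed_point_collapse(self, vocab):
        """x_t = x0 collapses mu~ to x0 times the coefficient sum."""
        s = make_schedule(10)
        t = 7
        x0 = np.array([[1.0, -2.0, 0.5]])
        h0 = vocab.one_hot(["C"])
        post = pd.posterior_params(x0, x0, h0, h0, t, s)
        coef = (np.sqrt(s.alpha_bar_at(t - 1)) * s.beta_at(t)
                + np.sqrt(s.alpha_at(t)) * (1 - s.alpha_bar_at(t - 1))) \
            / (1 - s.alpha_bar_at(t))
        assert np.allclose(post.mu_tilde, coef * x0, atol=1e-12)

    def test_t_zero_rejected(self, vocab):
        s = make_schedule(5)
        h = vocab.one_hot(["C"])
        with pytest.raises(ValueError):
            pd.posterior_params(np.zeros((1, 3)), np.zeros((1, 3)), h, h, 0, s)


class TestTrainingLoss:
    def _perfect_logits(self, labels, n_classes=5):
        logits = np.full((len(labels), n_classes), -1e4)
        logits[np.arange(len(labels)), labels] = 1e4
        return logits

    def test_identity_case_is_zero(self, vocab, toy_schedule):
        x0 = np.random.default_rng(0).normal(size=(2, 3))
        h0 = vocab.one_hot(["C", "O"])
        h_t = vocab.one_hot(["N", "O"])
        labels = np.array([0, 2, 1])
        lb = training_loss(x0, x0, h_t, h0, h0, self._perfect_logits(labels),
                           labels, 5, toy_schedule, pd.LossWeights())
        assert lb.total == pytest.approx(0.0, abs=1e-12)
        assert lb.coord == 0.0 and lb.types == pytest.approx(0.0, abs=1e-12)

    def test_kl_zero_for_matching_h0(self, vocab, toy_schedule):
        h0 = vocab.one_hot(["C", "S"])
        h_t = vocab.one_hot(["O", "S"])
        x = np.zeros((2, 3))
        lb = training_loss(x, x + 1.0, h_t, h0, h0,
                           self._perfect_logits([0]), [0], 9, toy_schedule,
                           pd.LossWeights(lambda_h=5.0))
        assert lb.types == pytest.approx(0.0, abs=1e-12)
        assert lb.coord > 0

    def test_kl_matches_hand_sum(self, toy_schedule):
        """2 atoms, K=3: L^h equals the term-by-term KL summation."""
        vocab3 = pd.AtomVocabulary(("C", "N", "O"))
        h0 = vocab3.one_hot(["C", "N"])
        h0_hat = np.array([[0.7, 0.2, 0.1], [0.1, 0.6, 0.3]])
        h_t = vocab3.one_hot(["O", "N"])
        t = 4
        x = np.zeros((2, 3))
        lb = training_loss(x, x, h_t, h0, h0_hat, self._perfect_logits([0]),
                           [0], t, toy_schedule,
                           pd.LossWeights(1.0, 1.0, 1.0))
        from promptdiff.diffusion import _theta_post
        kl = 0.0
        for i in range(2):
            p = _theta_post(h_t[i], h0[i], t, toy_schedule)
            q = _theta_post(h_t[i], h0_hat[i], t, toy_schedule)
            kl += np.sum(p * np.log(p / q))
        assert lb.types == pytest.approx(kl / 2, rel=1e-9)

    def test_decomposition_exact(self, vocab, toy_schedule):
        rng = np.random.default_rng(4)
        x0, x0h = rng.normal(size=(2, 2, 3))
        h0 = vocab.one_hot(["C", "O"])
        h0h = np.abs(rng.normal(size=(2, vocab.K))) + 0.1
        h0h /= h0h.sum(1, keepdims=True)
        h_t = vocab.one_hot(["N", "F"])
        logits = rng.normal(size=(3, 5))
        labels = [0, 1, 4]
        w = pd.LossWeights(0.7, 2.0, 0.3)
        lb = training_loss(x0, x0h, h_t, h0, h0h, logits, labels, 8,
                           toy_schedule, w)
        assert lb.total == pytest.approx(
            w.lambda_x * lb.coord + w.lambda_h * lb.types
            + w.lambda_c * lb.classification, rel=1e-12)
        for term in ("coord", "types", "classification"):
            assert getattr(lb, term) >= 0

    def test_zero_weight_removes_gradient(self, vocab, toy_schedule):
        from promptdiff.diffusion import loss_terms
        rng = np.random.default_rng(5)
        x0 = rng.normal(size=(2, 3))
        x0h = Tensor.param(rng.normal(size=(2, 3)))
        h0 = vocab.one_hot(["C", "O"])
        h_t = vocab.one_hot(["N", "O"])
        logits = Tensor.param(rng.normal(size=(1, 5)))
        lx, lh, lc = loss_terms(x0, x0h, h_t, h0, h0, logits, [2], 5,
                                toy_schedule)
        total = 0.0 * lx + 1.0 * lc   # lambda_x = 0
        total.backward()
        assert np.all(x0h.grad == 0)
        assert np.any(logits.grad != 0)

    def test_invalid_inputs_rejected(self, vocab, toy_schedule):
        with pytest.raises(ValueError):
            pd.LossWeights(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            pd.LossWeights(0.0, 0.0, 0.0)
        x = np.zeros((1, 3))
        h = vocab.one_hot(["C"])
        with pytest.raises(ValueError):
            training_loss(x, x, h, h, h, np.zeros((1, 5)), [7], 5,
                          toy_schedule, pd.LossWeights())


def test_vocabulary_contract():
    v = pd.AtomVocabulary()
    assert v.K == 9 and v.index("Cl") == 6
    assert v.decode(v.one_hot(["Br", "C"])) == ["Br", "C"]
    with pytest.raises(ValueError):
        pd.AtomVocabulary(("C", "C"))
    with pytest.raises(KeyError):
        v.index("Xx")
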