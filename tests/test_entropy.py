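import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arifuse import (
    AlphaParam,
    arimoto_divergence,
    arimoto_entropy,
    arimoto_joint_entropy_independent,
    arimoto_mi,
    arimoto_mi_pseudoadditive,
    kl_divergence,
    shannon_entropy,
    shannon_mi,
    tsallis_mi,
)
from conftest import random_prob

ALPHAS = (0.5, 1.5, 2.0)


def uniform(n):
    return np.full(n, 1.0 / n)


def uniform_arimoto(n, alpha):
    """Closed-form entropy of the uniform distribution (the upper bound)."""
    return alpha / (alpha - 1.0) * (1.0 - n ** ((1.0 - alpha) / alpha))


prob_vectors = st.lists(
    st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=16
).map(lambda xs: np.array(xs) / np.sum(xs))


class TestShannonFamily:
    def test_entropy_examples(self):
        assert shannon_entropy([1.0, 0.0, 0.0]) == 0.0
        assert shannon_entropy([0.5, 0.5]) == pytest.approx(1.0)
        assert shannon_entropy(uniform(256)) == pytest.approx(8.0)

    def test_kl_examples(self):
        assert kl_divergence([0.3, 0.7], [0.3, 0.7]) == 0.0
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0)
        with pytest.warns(RuntimeWarning, match="support violation"):
            assert kl_divergence([0.5, 0.5], [1.0, 0.0]) == math.inf

    def test_mi_examples(self):
        assert shannon_mi(np.array([[0.5, 0.0], [0.0, 0.5]])) == pytest.approx(1.0)
        outer = np.outer([0.3, 0.7], [0.6, 0.4])
        assert shannon_mi(outer) == pytest.approx(0.0, abs=1e-12)

    def test_self_mi_equals_entropy(self, scene):
        from arifuse import joint_hist, marginal_hist

        j = joint_hist(scene, scene)
        assert shannon_mi(j) == pytest.approx(shannon_entropy(marginal_hist(scene)))

    def test_mi_bounded_by_marginal_entropies(self, rng):
        for _ in range(20):
            j = rng.random((6, 6))
            j /= j.sum()
            mi = shannon_mi(j)
            assert mi >= 0
            assert mi <= min(shannon_entropy(j.sum(1)), shannon_entropy(j.sum(0))) + 1e-12


class TestArimotoEntropy:
    def test_degenerate_is_zero(self):
        assert arimoto_entropy([1.0, 0.0, 0.0, 0.0], 2.0) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize(
        "n, alpha, expected",
        [(4, 0.5, 3.0), (2, 2.0, 2.0 - math.sqrt(2.0))],
    )
    def test_uniform_closed_form(self, n, alpha, expected):
        assert arimoto_entropy(uniform(n), alpha) == pytest.approx(expected, abs=1e-12)

    def test_shannon_limit_in_nats(self):
        for alpha in (1 - 1e-8, 1 + 1e-8):
            assert arimoto_entropy([0.5, 0.5], alpha) == pytest.approx(math.log(2), abs=1e-5)

    def test_alpha_validation(self):
        with pytest.raises(ValueError, match="positive"):
            arimoto_entropy([0.5, 0.5], 0.0)
        with pytest.raises(ValueError, match="positive"):
            AlphaParam(-1.5)

    @settings(max_examples=100, derandomize=True)
    @given(p=prob_vectors, alpha=st.sampled_from(ALPHAS))
    def test_nonneg_symmetric_bounded(self, p, alpha):
        h = arimoto_entropy(p, alpha)
        assert h >= -1e-12
        assert h <= uniform_arimoto(len(p), alpha) + 1e-10
        shuffled = np.random.default_rng(0).permutation(p)
        assert arimoto_entropy(shuffled, alpha) == pytest.approx(h, abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(
        p1=prob_vectors, p2=prob_vectors, t=st.floats(0.01, 0.99),
        alpha=st.sampled_from(ALPHAS),
    )
    def test_concavity(self, p1, p2, t, alpha):
        n = min(len(p1), len(p2))
        p1 = p1[:n] / p1[:n].sum()
        p2 = p2[:n] / p2[:n].sum()
        mix = arimoto_entropy(t * p1 + (1 - t) * p2, alpha)
        assert mix >= t * arimoto_entropy(p1, alpha) + (1 - t) * arimoto_entropy(p2, alpha) - 1e-10

    def test_pseudo_additivity_on_outer_products(self, rng):
        for n1, n2 in [(2, 3), (4, 4), (8, 5)]:
            for alpha in ALPHAS:
                p = random_prob(rng, n1)
                q = random_prob(rng, n2)
                joint = np.outer(p, q).ravel()
                combined = arimoto_joint_entropy_independent(
                    arimoto_entropy(p, alpha), arimoto_entropy(q, alpha), alpha
                )
                assert arimoto_entropy(joint, alpha) == pytest.approx(combined, abs=1e-10)

    def test_pseudo_additive_trivia(self):
        assert arimoto_joint_entropy_independent(0.0, 0.0, 2.0) == 0.0
        assert arimoto_joint_entropy_independent(0.7, 0.0, 2.0) == 0.7


class TestArimotoDivergence:
    def test_identity_is_zero(self, rng):
        for alpha in ALPHAS:
            p = random_prob(rng, 6)
            assert arimoto_divergence(p, p, alpha) == pytest.approx(0.0, abs=1e-12)

    def test_hand_derived_value(self):
        expected = 2.0 * (math.sqrt(1.64) - 1.0)
        assert arimoto_divergence([0.9, 0.1], [0.5, 0.5], 2.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_kl_limit(self):
        p, q = [0.9, 0.1], [0.5, 0.5]
        kl_nats = kl_divergence(p, q, log_base=math.e)
        assert kl_nats == pytest.approx(0.368064, abs=1e-6)
        for alpha in (1 - 1e-5, 1 + 1e-5):
            assert arimoto_divergence(p, q, alpha) == pytest.approx(kl_nats, abs=1e-4)

    def test_nonnegative(self, rng):
        for alpha in ALPHAS:
            for _ in range(50):
                p = random_prob(rng, 5)
                q = random_prob(rng, 5)
                assert arimoto_divergence(p, q, alpha) >= -1e-12

    def test_support_violation_is_inf(self):
        with pytest.warns(RuntimeWarning, match="support violation"):
            assert arimoto_divergence([0.5, 0.5], [1.0, 0.0], 2.0) == math.inf

    def test_as_printed_variant_breaks_identity(self):
        # the uncorrected exponent does not vanish at p = q, which is why
        # the corrected form is the default
        p = [0.9, 0.1]
        assert arimoto_divergence(p, p, 2.0, as_printed=True) != pytest.approx(0.0, abs=1e-3)


class TestArimotoMI:
    def test_independent_joint_is_zero(self, rng):
        for alpha in ALPHAS:
            j = np.outer(random_prob(rng, 4), random_prob(rng, 5))
            assert arimoto_mi(j, alpha) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_hand_value(self):
        j = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert arimoto_mi(j, 2.0) == pytest.approx(2.0 * (math.sqrt(2.0) - 1.0), abs=1e-12)

    def test_shannon_limit(self):
        j = np.array([[0.5, 0.0], [0.0, 0.5]])
        for alpha in (1 - 1e-5, 1 + 1e-5):
            assert arimoto_mi(j, alpha) == pytest.approx(math.log(2.0), abs=1e-4)

    def test_pseudoadditive_form_agrees_at_limit_only(self, rng):
        j = rng.random((4, 4))
        j /= j.sum()
        mi_nats = shannon_mi(j, log_base=math.e)
        assert arimoto_mi_pseudoadditive(j, 1.0) == pytest.approx(mi_nats, abs=1e-9)
        # the divergence form drives the metric; the two genuinely differ at alpha != 1
        assert arimoto_mi_pseudoadditive(j, 2.0) != pytest.approx(arimoto_mi(j, 2.0), abs=1e-6)


class TestTsallisMI:
    def test_independent_joint_is_zero(self, rng):
        j = np.outer(random_prob(rng, 3), random_prob(rng, 6))
        assert tsallis_mi(j, 1.85) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_hand_value(self):
        j = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert tsallis_mi(j, 2.0) == pytest.approx(1.0, abs=1e-12)

    def test_shannon_limit(self, rng):
        j = rng.random((5, 5))
        j /= j.sum()
        mi_nats = shannon_mi(j, log_base=math.e)
        for q in (1 - 1e-5, 1 + 1e-5):
            assert tsallis_mi(j, q) == pytest.approx(mi_nats, abs=1e-4)
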