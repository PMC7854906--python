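"""Loss components: cross-entropies, multi-kernel MMD, combined objectives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegadapt.losses import (
    KernelBank,
    classification_loss,
    discriminator_objective,
    domain_adversarial_loss,
    generator_objective,
    l2_term,
    median_heuristic_bank,
    mk_kernel,
    mmd2,
    mmd2_feature_grads,
)


def mmd2_double_sum(s, t, bank, c):
    """Explicit O(n^2) oracle."""
    ns, nt = len(s), len(t)
    kss = sum(mk_kernel(s[i], s[j], bank) for i in range(ns) for j in range(ns))
    ktt = sum(mk_kernel(t[i], t[j], bank) for i in range(nt) for j in range(nt))
    kst = sum(mk_kernel(s[i], t[j], bank) for i in range(ns) for j in range(nt))
    return kss / ns**2 - c * kst / (ns * nt) + ktt / nt**2


class TestClassificationLoss:
    def test_one_hot_correct_is_zero(self):
        scores = np.eye(3)[[0, 1, 2]]
        assert classification_loss(scores, [0, 1, 2]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_four_classes_is_ln4(self):
        scores = np.full((10, 4), 0.25)
        assert classification_loss(scores, np.arange(10) % 4) == pytest.approx(np.log(4.0))

    def test_reordering_invariant(self, rng):
        scores = rng.dirichlet(np.ones(3), size=20)
        labels = rng.integers(0, 3, 20)
        perm = rng.permutation(20)
        assert classification_loss(scores, labels) == pytest.approx(
            classification_loss(scores[perm], labels[perm])
        )

    def test_label_out_of_range_raises(self):
        with pytest.raises(ValueError, match="out of range"):
            classification_loss(np.full((2, 3), 1 / 3), [0, 3])


class TestDomainAdversarialLoss:
    def test_uniform_two_domains_is_ln2(self):
        scores = np.full((8, 2), 0.5)
        h = domain_adversarial_loss(scores, [0, 1] * 4)
        assert h == pytest.approx(np.log(2.0))

    def test_confident_correct_approaches_zero(self):
        scores = np.array([[1 - 1e-9, 1e-9], [1e-9, 1 - 1e-9]])
        assert domain_adversarial_loss(scores, [0, 1]) < 1e-6

    def test_relabeling_symmetry(self, rng):
        scores = rng.dirichlet(np.ones(2), size=12)
        labels = rng.integers(0, 2, 12)
        flipped = domain_adversarial_loss(scores[:, ::-1], 1 - labels)
        assert domain_adversarial_loss(scores, labels) == pytest.approx(flipped)

    def test_domain_label_out_of_range_raises(self):
        with pytest.raises(ValueError, match="out of range"):
            domain_adversarial_loss(np.full((1, 2), 0.5), [2])


class TestMKKernel:
    def test_zero_distance_with_normalized_weights_is_one(self):
        bank = KernelBank((0.5, 2.0, 8.0), (1.0, 1.0, 1.0))
        x = np.array([1.0, -2.0])
        assert mk_kernel(x, x, bank) == pytest.approx(1.0)

    def test_single_kernel_unit_distance(self):
        bank = KernelBank((1.0,), (1.0,))
        assert mk_kernel(np.zeros(1), np.ones(1), bank) == pytest.approx(np.exp(-0.5))

    def test_strictly_decreasing_in_distance(self):
        bank = KernelBank((1.0, 4.0), (0.3, 0.7))
        vals = [mk_kernel(np.zeros(1), np.array([d]), bank) for d in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(vals) < 0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            mk_kernel(np.zeros(2), np.zeros(3), KernelBank((1.0,), (1.0,)))

    def test_bank_validation(self):
        with pytest.raises(ValueError):
            KernelBank((1.0,), (1.0, 2.0))
        with pytest.raises(ValueError):
            KernelBank((-1.0,), (1.0,))
        with pytest.raises(ValueError):
            KernelBank((1.0,), (0.0,))


class TestMMD2:
    bank1 = KernelBank((1.0,), (1.0,))

    def test_identical_sets_give_zero(self, rng):
        s = rng.standard_normal((10, 3))
        assert abs(mmd2(s, s.copy(), self.bank1)) < 1e-9

    def test_singletons_distance_one(self):
        # oracle: explicit 4-term double sum = 2 - 2 e^{-1/2}
        got = mmd2(np.array([[0.0]]), np.array([[1.0]]), self.bank1, cross_coefficient=2)
        assert got == pytest.approx(2 - 2 * np.exp(-0.5), abs=1e-12)
        assert got == pytest.approx(0.78694, abs=1e-5)

    def test_singletons_distance_two(self):
        got = mmd2(np.array([[0.0]]), np.array([[2.0]]), self.bank1, cross_coefficient=2)
        assert got == pytest.approx(2 - 2 * np.exp(-2.0), abs=1e-12)
        assert got == pytest.approx(1.72933, abs=1e-5)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        ns=st.integers(1, 50),
        nt=st.integers(1, 50),
        c=st.sampled_from([1, 2]),
    )
    def test_matches_double_sum_oracle(self, seed, ns, nt, c):
        rng = np.random.default_rng(seed)
        s = rng.standard_normal((ns, 4))
        t = rng.standard_normal((nt, 4)) + 0.3
        bank = KernelBank((0.5, 2.0), (0.4, 0.6))
        assert mmd2(s, t, bank, c) == pytest.approx(mmd2_double_sum(s, t, bank, c), abs=1e-10)

    def test_default_estimator_nonnegative(self, rng):
        for _ in range(30):
            s = rng.standard_normal((rng.integers(2, 20), 3))
            t = rng.standard_normal((rng.integers(2, 20), 3))
            assert mmd2(s, t, self.bank1, 2) >= -1e-9

    def test_vanishes_for_same_distribution_at_large_n(self, rng):
        s = rng.standard_normal((500, 2))
        t = rng.standard_normal((500, 2))
        assert mmd2(s, t, self.bank1, 2) < 0.02

    def test_monotone_in_gaussian_mean_shift(self):
        mus = [0.0, 0.5, 1.0, 2.0]
        means = []
        for mu in mus:
            vals = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                s = rng.standard_normal((100, 1))
                t = rng.standard_normal((100, 1)) + mu
                vals.append(mmd2(s, t, self.bank1, 2))
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            mmd2(np.empty((0, 2)), np.zeros((3, 2)), self.bank1)

    def test_feature_grads_match_value(self, rng):
        s, t = rng.standard_normal((8, 3)), rng.standard_normal((5, 3))
        bank = KernelBank((0.7, 3.0), (0.5, 0.5))
        val, gs, gt = mmd2_feature_grads(s, t, bank)
        assert val == pytest.approx(mmd2(s, t, bank), abs=1e-12)
        assert gs.shape == s.shape and gt.shape == t.shape


class TestMedianHeuristicBank:
    def test_two_points_squared_distance_four(self):
        pts = np.array([[0.0], [2.0]])
        bank = median_heuristic_bank(pts[:1], pts[1:], n_kernels=1)
        assert bank.sigmas == (4.0,)

    def test_five_kernels_spacing_two_ratios(self, rng):
        s = rng.standard_normal((10, 2))
        t = rng.standard_normal((10, 2))
        bank = median_heuristic_bank(s, t, n_kernels=5, spacing=2.0)
        center = bank.sigmas[2]
        np.testing.assert_allclose(
            np.array(bank.sigmas) / center, [0.25, 0.5, 1.0, 2.0, 4.0], atol=1e-12
        )
        assert bank.weights == (0.2,) * 5

    def test_feature_scaling_scales_bandwidths_quadratically(self, rng):
        s = rng.standard_normal((8, 3))
        t = rng.standard_normal((6, 3))
        b1 = median_heuristic_bank(s, t)
        b2 = median_heuristic_bank(3.0 * s, 3.0 * t)
        np.testing.assert_allclose(np.array(b2.sigmas), 9.0 * np.array(b1.sigmas), rtol=1e-12)

    def test_identical_points_raise(self):
        pts = np.ones((4, 2))
        with pytest.raises(ValueError, match="identical"):
            median_heuristic_bank(pts[:2], pts[2:])


class TestCombinedObjectives:
    def test_weights_off_reduces_to_classification(self):
        assert generator_objective(1.7, 0.6, 0.2, 10.0, 0, 0, 0) == pytest.approx(1.7)

    def test_linear_combination_example(self):
        # 1 + 0.1*(-0.6) + 0.1*0.2 + 0.01*10 = 1.06
        assert generator_objective(1.0, 0.6, 0.2, 10.0, 0.1, 0.1, 0.01) == pytest.approx(1.06)

    def test_partial_derivative_wrt_lambda_m_is_mmd(self):
        base = generator_objective(1.0, 0.6, 0.2, 10.0, 0.1, 0.3, 0.01)
        bumped = generator_objective(1.0, 0.6, 0.2, 10.0, 0.1, 0.3 + 1e-6, 0.01)
        assert (bumped - base) / 1e-6 == pytest.approx(0.2, abs=1e-6)

    def test_discriminator_objective_examples(self):
        assert discriminator_objective(np.log(2.0), 1.0, 10.0) == pytest.approx(10.0 + np.log(2.0))
        assert discriminator_objective(0.42, 5.0, 0.0) == pytest.approx(0.42)

    def test_discriminator_objective_nonnegative(self, rng):
        for _ in range(20):
            h = float(rng.uniform(0, 3))
            gp = float(rng.uniform(0, 2))
            lam = float(rng.uniform(0, 10))
            assert discriminator_objective(h, gp, lam) >= 0

    def test_l2_term_sums_squares(self):
        mats = [np.array([[1.0, 2.0]]), np.array([[2.0], [1.0]])]
        assert l2_term(mats) == pytest.approx(10.0)
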