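"""Disentanglement head: mask complementarity, dynamic small-target
weighting and the weighted auxiliary loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcanet.autograd import Tensor
from dcanet.dfm import (DecoupledFeatureModule, PriorMaskSet, dfm_loss,
                        dynamic_weights)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def masks_from_logits(logits: np.ndarray) -> PriorMaskSet:
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    m = e / e.sum(axis=1, keepdims=True)
    k = logits.shape[1] - 1
    return PriorMaskSet(fg_masks=Tensor(m[:, :k]), bg_mask=Tensor(m[:, k:]),
                        logits=Tensor(logits))


@pytest.fixture
def module():
    return DecoupledFeatureModule(np.random.default_rng(0), in_channels=8,
                                  num_fg_classes=2, branch_channels=8)


class TestBranchesAndMasks:
    def test_branch_count_and_shape(self, module):
        f = Tensor(np.random.default_rng(0).random((1, 8, 4, 4)))
        feats = module.decouple_branches(f)
        assert len(feats) == 3
        for feat in feats:
            assert feat.shape[2:] == (4, 4)

    def test_branches_share_no_weights(self, module):
        f = Tensor(np.random.default_rng(1).random((1, 8, 4, 4)))
        base = [b.data.copy() for b in module.decouple_branches(f)]
        # perturb branch 0's first conv weight
        module.branches[0].layers[0].layers[0].weight.data += 0.5
        after = [b.data.copy() for b in module.decouple_branches(f)]
        assert not np.allclose(base[0], after[0])
        np.testing.assert_array_equal(base[1], after[1])
        np.testing.assert_array_equal(base[2], after[2])

    def test_masks_complementary_per_pixel(self, module):
        f = Tensor(np.random.default_rng(2).random((2, 8, 4, 4)))
        masks = module(f)
        total = masks.all_masks.data.sum(axis=1)
        np.testing.assert_allclose(total, 1.0, atol=1e-6)
        assert (masks.all_masks.data >= 0).all()

    def test_saturated_logit_yields_binary_mask(self):
        logits = np.zeros((1, 3, 2, 2))
        logits[0, 1, 0, 0] += 1e4
        masks = masks_from_logits(logits)
        assert masks.fg_masks.data[0, 1, 0, 0] == pytest.approx(1.0)
        assert masks.fg_masks.data[0, 0, 0, 0] == pytest.approx(0.0)

    def test_uniform_logits_give_uniform_masks(self):
        masks = masks_from_logits(np.zeros((1, 4, 2, 2)))
        np.testing.assert_allclose(masks.all_masks.data, 0.25)

    def test_invalid_class_count_rejected(self):
        with pytest.raises(ValueError):
            DecoupledFeatureModule(np.random.default_rng(0), 8, 0)


class TestDynamicWeights:
    def test_equal_proportions_give_half(self):
        logits = np.zeros((1, 4, 4, 4))  # all masks equal → p_k = mu
        w = dynamic_weights(masks_from_logits(logits), alpha=5.0)
        np.testing.assert_allclose(w.beta, 0.5, atol=1e-12)

    def test_alpha_zero_disables_weighting(self, rng):
        logits = rng.normal(size=(1, 3, 4, 4))
        w = dynamic_weights(masks_from_logits(logits), alpha=0.0)
        np.testing.assert_allclose(w.beta, 0.5)

    def test_worked_two_class_case(self):
        """p=(0.01,0.20), alpha=5 → beta=(0.6166, 0.3834), summing to 1."""
        p = np.array([0.01, 0.20])
        masks = masks_from_logits(np.zeros((1, 3, 2, 2)))
        out = dynamic_weights(masks, alpha=5.0, proportions=p)
        mu = 0.105
        expected = 1.0 - sigmoid(5.0 * (p - mu))
        np.testing.assert_allclose(out.beta, expected, atol=1e-12)
        assert out.beta[0] == pytest.approx(0.61664, abs=1e-4)
        assert out.beta[1] == pytest.approx(0.38336, abs=1e-4)
        assert out.beta.sum() == pytest.approx(1.0)  # sigmoid antisymmetry
        assert out.mu == pytest.approx(mu)

    @given(st.lists(st.floats(0.001, 0.5), min_size=2, max_size=5))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_beta_bounds_and_monotonicity(self, props):
        p = np.sort(np.asarray(props))
        masks = masks_from_logits(np.zeros((1, len(p) + 1, 2, 2)))
        beta = dynamic_weights(masks, alpha=5.0, proportions=p).beta
        assert ((beta > 0) & (beta < 1)).all()
        # strictly decreasing in p wherever p strictly increases
        for i in range(len(p) - 1):
            if p[i + 1] > p[i]:
                assert beta[i + 1] < beta[i]

    def test_beta_saturates_toward_one_for_tiny_class(self):
        p = np.array([1e-6, 0.5])
        beta = dynamic_weights(masks_from_logits(np.zeros((1, 3, 2, 2))),
                               alpha=500.0, proportions=p).beta
        assert beta[0] > 0.999

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            dynamic_weights(masks_from_logits(np.zeros((1, 3, 2, 2))), alpha=-1)


class TestDFMLoss:
    def perfect_masks(self, labels, k):
        logits = np.full((1, k + 1) + labels.shape, -1e4)
        for c in range(1, k + 1):
            logits[0, c - 1][labels == c] = 1e4
        logits[0, k][labels == 0] = 1e4
        return masks_from_logits(logits)

    def test_perfect_prediction_drives_loss_below_1e3(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[:3, :3] = 1
        labels[5:, 5:] = 2
        masks = self.perfect_masks(labels, 2)
        out = dfm_loss(masks, labels, alpha=5.0, lambda_bg=0.3)
        assert out.total.item() < 1e-3
        for lk in out.per_class_losses:
            assert lk.item() < 1e-3

    def test_lambda_zero_removes_background_term(self, rng):
        labels = rng.integers(0, 3, (6, 6))
        masks = masks_from_logits(rng.normal(size=(1, 3, 6, 6)))
        out = dfm_loss(masks, labels, alpha=5.0, lambda_bg=0.0)
        manual = sum(float(b) * lk.item()
                     for b, lk in zip(out.weights.beta, out.per_class_losses))
        assert out.total.item() == pytest.approx(manual, rel=1e-12)

    def test_total_recomposes_from_breakdown(self, rng):
        labels = rng.integers(0, 4, (8, 8))
        masks = masks_from_logits(rng.normal(size=(1, 4, 8, 8)))
        out = dfm_loss(masks, labels, alpha=5.0, lambda_bg=0.3)
        manual = sum(float(b) * lk.item()
                     for b, lk in zip(out.weights.beta, out.per_class_losses))
        manual += 0.3 * out.bg_loss.item()
        assert out.total.item() == pytest.approx(manual, abs=1e-6)
        assert all(lk.item() >= 0 for lk in out.per_class_losses)
        assert out.bg_loss.item() >= 0

    def test_small_class_outweighs_large_for_equal_raw_loss(self):
        """With alpha=5 the weighted contribution of a small class exceeds a
        large class's for the same raw loss value."""
        p = np.array([0.01, 0.30])
        beta = dynamic_weights(masks_from_logits(np.zeros((1, 3, 2, 2))),
                               alpha=5.0, proportions=p).beta
        raw = 0.7
        assert beta[0] * raw > beta[1] * raw

    def test_coarse_masks_upsampled_to_labels(self, rng):
        labels = rng.integers(0, 3, (8, 8))
        masks = masks_from_logits(rng.normal(size=(1, 3, 2, 2)))
        out = dfm_loss(masks, labels, alpha=5.0, lambda_bg=0.3)
        assert np.isfinite(out.total.item())

    def test_out_of_range_labels_rejected(self, rng):
        masks = masks_from_logits(rng.normal(size=(1, 3, 4, 4)))
        with pytest.raises(ValueError):
            dfm_loss(masks, np.full((4, 4), 7), alpha=5.0)

    def test_weights_detached_from_graph(self, rng):
        """The beta factors are constants: no gradient path through them."""
        logits = Tensor(rng.normal(size=(1, 3, 4, 4)), requires_grad=True)
        from dcanet import autograd as ag

        m = ag.softmax(logits, axis=1)
        masks = PriorMaskSet(fg_masks=m[:, :2], bg_mask=m[:, 2:], logits=logits)
        labels = rng.integers(0, 3, (4, 4))
        out = dfm_loss(masks, labels, alpha=5.0)
        assert isinstance(out.weights.beta, np.ndarray)  # plain constants
        out.total.backward()
        assert logits.grad is not None and np.isfinite(logits.grad).all()
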