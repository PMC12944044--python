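"""Category-aware aggregation: context/attention algebra against
brute-force loop oracles, normalization and fusion identities."""

import numpy as np
import pytest

from dcanet import autograd as ag
from dcanet.autograd import Tensor
from dcanet.caia import CAIA, context_interaction
from dcanet.dfm import PriorMaskSet


def make_priors(mask_array: np.ndarray) -> PriorMaskSet:
    """Build a PriorMaskSet from an (N, K+1, H, W) array of soft masks."""
    k = mask_array.shape[1] - 1
    return PriorMaskSet(fg_masks=Tensor(mask_array[:, :k]),
                        bg_mask=Tensor(mask_array[:, k:]),
                        logits=Tensor(np.log(np.maximum(mask_array, 1e-12))))


def random_soft_masks(rng, n, kp1, h, w):
    raw = rng.random((n, kp1, h, w))
    return raw / raw.sum(axis=1, keepdims=True)


def context_brute_force(feats: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the class-context matrix."""
    n, c, h, w = feats.shape
    kp1 = masks.shape[1]
    ctx = np.zeros((n, c, kp1))
    for b in range(n):
        for ch in range(c):
            for k in range(kp1):
                for i in range(h):
                    for j in range(w):
                        ctx[b, ch, k] += feats[b, ch, i, j] * masks[b, k, i, j]
    return ctx


class TestContextInteraction:
    def test_matches_brute_force(self, rng):
        feats = rng.normal(size=(2, 3, 4, 4))
        masks = random_soft_masks(rng, 2, 3, 4, 4)
        ctx = context_interaction(Tensor(feats), make_priors(masks)).data
        np.testing.assert_allclose(ctx, context_brute_force(feats, masks),
                                   atol=1e-10)

    def test_hard_masks_sum_class_features(self, rng):
        feats = rng.normal(size=(1, 3, 2, 2))
        hard = np.zeros((1, 2, 2, 2))
        hard[0, 0, 0, :] = 1  # class 0 owns the first row
        hard[0, 1, 1, :] = 1
        ctx = context_interaction(Tensor(feats), make_priors(hard)).data
        np.testing.assert_allclose(ctx[0, :, 0], feats[0, :, 0, :].sum(axis=1))
        np.testing.assert_allclose(ctx[0, :, 1], feats[0, :, 1, :].sum(axis=1))

    def test_zero_features_give_zero_context(self, rng):
        masks = random_soft_masks(rng, 1, 4, 3, 3)
        ctx = context_interaction(Tensor(np.zeros((1, 5, 3, 3))),
                                  make_priors(masks)).data
        np.testing.assert_array_equal(ctx, 0.0)

    def test_priors_resized_to_feature_grid(self, rng):
        feats = rng.normal(size=(1, 2, 8, 8))
        masks = random_soft_masks(rng, 1, 3, 2, 2)
        ctx = context_interaction(Tensor(feats), make_priors(masks)).data
        assert ctx.shape == (1, 2, 3)
        assert np.isfinite(ctx).all()


class TestCategoryAttention:
    def make_caia(self, k=1, c=3, d=2, **kw):
        return CAIA(np.random.default_rng(0), enc_channels=c, prev_channels=None,
                    out_channels=c, num_fg_classes=k, embed_dim=d, **kw)

    def test_rows_sum_to_one(self, rng):
        caia = self.make_caia(k=2, c=4, d=3)
        masks = random_soft_masks(rng, 2, 3, 4, 4)
        ctx = Tensor(rng.normal(size=(2, 4, 3)))
        bundle = caia.category_attention(make_priors(masks), ctx)
        np.testing.assert_allclose(bundle.A.data.sum(axis=-1), 1.0, atol=1e-9)

    def test_identical_class_columns_give_uniform_attention(self, rng):
        caia = self.make_caia(k=2, c=4, d=3)
        masks = random_soft_masks(rng, 1, 3, 4, 4)
        col = rng.normal(size=(1, 4, 1))
        ctx = Tensor(np.repeat(col, 3, axis=2))  # identical keys/values per class
        bundle = caia.category_attention(make_priors(masks), ctx)
        np.testing.assert_allclose(bundle.A.data, 1.0 / 3.0, atol=1e-12)

    def test_matches_hand_evaluated_softmax(self, rng):
        """N=4, K=1, d=2 case recomputed with plain numpy from the module's
        own weights."""
        caia = self.make_caia(k=1, c=3, d=2)
        masks = random_soft_masks(rng, 1, 2, 2, 2)
        ctx_arr = rng.normal(size=(1, 3, 2))
        bundle = caia.category_attention(make_priors(masks), Tensor(ctx_arr))

        qw = caia.q_conv.weight.data.reshape(2, 1)
        qb = caia.q_conv.bias.data
        q = (qw @ masks[:, :1].reshape(1, 1, 4)) + qb[None, :, None]
        keys = caia.key_map.weight.data @ ctx_arr + \
            caia.key_map.bias.data[None, :, None]
        values = caia.value_map.weight.data @ ctx_arr + \
            caia.value_map.bias.data[None, :, None]
        scores = np.swapaxes(q, 1, 2) @ keys / 2.0   # divide by d
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        a = e / e.sum(axis=-1, keepdims=True)
        f_att = values @ np.swapaxes(a, 1, 2)
        np.testing.assert_allclose(bundle.A.data, a, atol=1e-10)
        np.testing.assert_allclose(bundle.F_att.data.reshape(1, 3, 4), f_att,
                                   atol=1e-10)

    def test_sqrt_scale_flag_changes_temperature(self, rng):
        masks = random_soft_masks(rng, 1, 2, 2, 2)
        ctx = Tensor(rng.normal(size=(1, 3, 2)))
        a_lin = self.make_caia(d=4).category_attention(make_priors(masks), ctx)
        a_sqrt = self.make_caia(d=4, sqrt_scale=True).category_attention(
            make_priors(masks), ctx)
        assert not np.allclose(a_lin.A.data, a_sqrt.A.data)

    def test_class_permutation_equivariance(self, rng):
        """Permuting prior-class order and context columns consistently
        leaves F_att unchanged (queries use foreground priors only, so
        permute the foreground classes)."""
        caia = self.make_caia(k=3, c=4, d=2)
        masks = random_soft_masks(rng, 1, 4, 3, 3)
        ctx = rng.normal(size=(1, 4, 4))
        base = caia.category_attention(make_priors(masks), Tensor(ctx))

        perm_fg = [2, 0, 1]
        perm_all = perm_fg + [3]
        masks_p = masks[:, perm_all]
        ctx_p = ctx[:, :, perm_all]
        # permute the learned maps consistently with the class reordering
        caia.q_conv.weight.data = caia.q_conv.weight.data[:, perm_fg]
        swapped = caia.category_attention(make_priors(masks_p), Tensor(ctx_p))
        np.testing.assert_allclose(swapped.F_att.data, base.F_att.data,
                                   atol=1e-10)


class TestCAIAForward:
    def test_zero_init_output_conv_reduces_to_decoder_feature(self, rng):
        caia = CAIA(np.random.default_rng(1), enc_channels=3, prev_channels=None,
                    out_channels=5, num_fg_classes=2, embed_dim=2,
                    zero_init_out=True)
        e = Tensor(rng.random((1, 3, 4, 4)))
        priors = make_priors(random_soft_masks(rng, 1, 3, 4, 4))
        out = caia(e, None, priors)
        e_dec = caia.build_fused(e, None)
        np.testing.assert_allclose(out.data, e_dec.data, atol=1e-12)

    def test_output_shape_matches_decoder_feature(self, rng):
        caia = CAIA(np.random.default_rng(2), enc_channels=3, prev_channels=6,
                    out_channels=5, num_fg_classes=2, embed_dim=2)
        e = Tensor(rng.random((2, 3, 8, 8)))
        prev = Tensor(rng.random((2, 6, 8, 8)))
        priors = make_priors(random_soft_masks(rng, 2, 3, 2, 2))
        out = caia(e, prev, priors)
        assert out.shape == (2, 5, 8, 8)

    def test_build_fused_responds_to_both_inputs(self, rng):
        caia = CAIA(np.random.default_rng(3), enc_channels=3, prev_channels=4,
                    out_channels=5, num_fg_classes=1, embed_dim=2)
        e = Tensor(rng.random((1, 3, 4, 4)))
        prev = Tensor(rng.random((1, 4, 4, 4)))
        base = caia.build_fused(e, prev).data
        bump = np.zeros((1, 3, 4, 4))
        bump[0, 0, 1, 1] = 0.5
        assert not np.allclose(base, caia.build_fused(e + Tensor(bump), prev).data)
        bump_prev = np.zeros((1, 4, 4, 4))
        bump_prev[0, 0, 1, 1] = 0.5
        assert not np.allclose(base,
                               caia.build_fused(e, prev + Tensor(bump_prev)).data)

    def test_resolution_mismatch_rejected(self, rng):
        caia = CAIA(np.random.default_rng(4), enc_channels=3, prev_channels=4,
                    out_channels=5, num_fg_classes=1, embed_dim=2)
        with pytest.raises(ValueError, match="resolution"):
            caia.build_fused(Tensor(rng.random((1, 3, 8, 8))),
                             Tensor(rng.random((1, 4, 4, 4))))

    def test_gradient_reaches_priors_through_queries(self, rng):
        caia = CAIA(np.random.default_rng(5), enc_channels=3, prev_channels=None,
                    out_channels=4, num_fg_classes=2, embed_dim=2,
                    detach_priors=False)
        logits = Tensor(rng.normal(size=(1, 3, 4, 4)), requires_grad=True)
        m = ag.softmax(logits, axis=1)
        priors = PriorMaskSet(fg_masks=m[:, :2], bg_mask=m[:, 2:], logits=logits)
        out = caia(Tensor(rng.random((1, 3, 4, 4))), None, priors)
        out.sum().backward()
        assert logits.grad is not None and np.any(logits.grad != 0)

    def test_detached_priors_block_gradient(self, rng):
        caia = CAIA(np.random.default_rng(6), enc_channels=3, prev_channels=None,
                    out_channels=4, num_fg_classes=2, embed_dim=2,
                    detach_priors=True)
        logits = Tensor(rng.normal(size=(1, 3, 4, 4)), requires_grad=True)
        m = ag.softmax(logits, axis=1)
        priors = PriorMaskSet(fg_masks=m[:, :2], bg_mask=m[:, 2:], logits=logits)
        caia(Tensor(rng.random((1, 3, 4, 4))), None, priors).sum().backward()
        assert logits.grad is None
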