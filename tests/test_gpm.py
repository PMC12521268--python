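"""Global-view fusion contracts: attention averaging oracle, the
multimodal normalizer's decorrelation property (against an independent
least-squares oracle), window-attention locality, and the fused output."""

import numpy as np
import pytest

from admvnet.gpm import (GPMConfig, GlobalPerceptionModule,
                         MultiHeadAttention3d, RegBNAligner, WindowAttention3d,
                         _to_tokens)
from admvnet.nn.core import Tensor

C = 8


def zero_biases(module):
    for name, p in module.named_parameters():
        if name.endswith(".b") or name.endswith("_b"):
            p.data[:] = 0.0


class TestMHA:
    def test_output_shape_preserved(self, rng):
        mha = MultiHeadAttention3d(C, 2, np.random.default_rng(0))
        x = Tensor(rng.standard_normal((2, C, 2, 2, 2)).astype(np.float32))
        assert mha(x).shape == x.shape

    def test_constant_keys_average_values(self, rng):
        """With identity value/output projections and zeroed keys the
        attention is uniform, so every token becomes the mean of the
        depthwise-mixed value stream."""
        mha = MultiHeadAttention3d(C, 2, np.random.default_rng(1), dtype=np.float64)
        eye = np.eye(C)
        mha.wv.w.data = eye.copy()
        mha.wv.b.data[:] = 0.0
        mha.wo.w.data = eye.copy()
        mha.wo.b.data[:] = 0.0
        mha.wk.w.data[:] = 0.0
        mha.wk.b.data[:] = 0.0
        x = Tensor(rng.standard_normal((2, C, 2, 2, 2)))
        kv_tokens = _to_tokens(mha.dw(mha.shallow(x))).data
        want = np.broadcast_to(kv_tokens.mean(axis=1, keepdims=True), kv_tokens.shape)
        got = _to_tokens(mha(x)).data
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_single_voxel_attention_is_identity_weighting(self, rng):
        mha = MultiHeadAttention3d(C, 2, np.random.default_rng(2), dtype=np.float64)
        x = Tensor(rng.standard_normal((1, C, 1, 1, 1)))
        # one token: softmax over a single key is exactly 1, so the output
        # is just the projected value stream
        kv = mha.dw(mha.shallow(x))
        want = mha.wo(mha.wv(_to_tokens(kv))).data
        np.testing.assert_allclose(_to_tokens(mha(x)).data, want, atol=1e-12)

    def test_bad_head_count_raises(self):
        with pytest.raises(ValueError):
            MultiHeadAttention3d(C, 3, np.random.default_rng(0))


class TestRegBN:
    def test_linear_dependence_is_removed(self, rng):
        aligner = RegBNAligner(ridge=1e-10)
        f = rng.standard_normal((16, 2, 2, 2, 2))
        m = rng.standard_normal((16, 16))
        g = (f.reshape(16, -1) @ m).reshape(f.shape)
        out = aligner(Tensor(f), Tensor(g))
        assert np.abs(out.data).max() < 1e-4

    def test_orthogonal_features_pass_through(self):
        aligner = RegBNAligner(ridge=1e-10)
        f = np.zeros((4, 3))
        g = np.zeros((4, 3))
        f[:2, 0] = [1.0, -1.0]
        g[2:, 1] = [1.0, -1.0]  # orthogonal across the batch
        out = aligner(Tensor(f), Tensor(g))
        np.testing.assert_allclose(out.data, g, atol=1e-8)

    def test_residual_uncorrelated_with_predictor_oracle(self, rng):
        """Batch n=64, d=32: output-vs-input correlation vanishes, verified
        against an independent lstsq oracle."""
        aligner = RegBNAligner(ridge=1e-6)
        f = rng.standard_normal((64, 32))
        g = f @ rng.standard_normal((32, 32)) + 0.1 * rng.standard_normal((64, 32))
        out = aligner(Tensor(f), Tensor(g)).data
        # independent oracle: affine residual via numpy lstsq with intercept
        fa = np.column_stack([f, np.ones(len(f))])
        w, *_ = np.linalg.lstsq(fa, g, rcond=None)
        np.testing.assert_allclose(out, g - fa @ w, atol=1e-4)
        fc = f - f.mean(axis=0)
        oc = out - out.mean(axis=0)
        corr = (fc.T @ oc) / (np.linalg.norm(fc, axis=0)[:, None]
                              * np.linalg.norm(oc, axis=0)[None, :] + 1e-30)
        assert np.abs(corr).max() < 1e-3

    def test_eval_mode_reuses_training_statistics(self, rng):
        aligner = RegBNAligner(ridge=1e-6)
        f = rng.standard_normal((8, 4))
        g = rng.standard_normal((8, 4))
        fitted = aligner(Tensor(f), Tensor(g)).data
        aligner.eval()
        replay = aligner(Tensor(f), Tensor(g)).data
        np.testing.assert_allclose(replay, fitted, atol=1e-6)

    def test_batch_of_one_passes_through_with_warning(self, rng):
        aligner = RegBNAligner()
        g = rng.standard_normal((1, 4))
        with pytest.warns(UserWarning):
            out = aligner(Tensor(rng.standard_normal((1, 4))), Tensor(g))
        np.testing.assert_array_equal(out.data, g)


class TestWindowAttention:
    def test_full_window_equals_global_attention(self, rng):
        wa = WindowAttention3d(C, (2, 2, 2), 2, np.random.default_rng(3), dtype=np.float64)
        x = Tensor(rng.standard_normal((1, C, 2, 2, 2)))
        got = wa(x).data
        # same weights applied as one global attention over all 8 tokens
        from admvnet.gpm import _attention, _merge_heads, _split_heads, _to_map
        t = _to_tokens(x)
        q = _split_heads(wa.wq(t), 2)
        k = _split_heads(wa.wk(t), 2)
        v = _split_heads(wa.wv(t), 2)
        want = _to_map(wa.wo(_merge_heads(_attention(q, k, v))), (2, 2, 2)).data
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_locality_between_disjoint_windows(self, rng):
        wa = WindowAttention3d(C, (2, 2, 2), 2, np.random.default_rng(4), dtype=np.float64)
        x = rng.standard_normal((1, C, 4, 4, 4))
        base = wa(Tensor(x)).data
        masked = x.copy()
        masked[:, :, :2, :2, :2] = 0.0  # zero one window's input
        out = wa(Tensor(masked)).data
        # every other window's output is bit-unchanged
        np.testing.assert_array_equal(out[:, :, 2:, :, :], base[:, :, 2:, :, :])
        np.testing.assert_array_equal(out[:, :, :2, 2:, :], base[:, :, :2, 2:, :])
        assert not np.allclose(out[:, :, :2, :2, :2], base[:, :, :2, :2, :2])


class TestGPMForward:
    def make(self, dtype=np.float64):
        return GlobalPerceptionModule(C, GPMConfig(n_heads=2, window=(2, 2, 2)),
                                      np.random.default_rng(5), dtype=dtype)

    def test_zero_inputs_zero_output(self):
        gpm = self.make()
        zeros = Tensor(np.zeros((4, C, 2, 2, 2)))
        out = gpm(zeros, zeros, zeros)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_output_length_is_c4(self, rng):
        gpm = self.make()
        x = [Tensor(rng.standard_normal((4, C, 2, 2, 2))) for _ in range(3)]
        assert gpm(*x).shape == (4, C)

    def test_modality_chain_is_order_sensitive(self, rng):
        """The sequential normalizer chain makes F_g depend on the order of
        the WM and PET streams."""
        gpm = self.make()
        hg, hw, hp = [Tensor(rng.standard_normal((4, C, 2, 2, 2))) for _ in range(3)]
        a = gpm(hg, hw, hp).data
        b = gpm(hg, hp, hw).data
        assert not np.allclose(a, b)
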