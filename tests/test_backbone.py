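"""Backbone contracts: convolution-path shape/positivity, the diffusion
closed forms (decay with the diffusivity off, constant fields), a per-voxel
brute-force neighborhood-sum oracle, the stability bound, and hierarchy
shapes."""

import numpy as np
import pytest

from admvnet.backbone import (HCNetBackbone, HCNetStage, HCNetStageConfig,
                              sdp_diffuse)
from admvnet.nn.core import Tensor


def make_stage(in_ch=2, out_ch=4, downsample=True, steps=2, seed=0, dtype=np.float64):
    cfg = HCNetStageConfig(in_ch, out_ch, downsample=downsample, diffusion_steps=steps)
    return HCNetStage(cfg, np.random.default_rng(seed), dtype=dtype)


class TestSCP:
    def test_shape_contract_and_nonnegativity(self, rng):
        stage = make_stage(1, 32)
        out = stage.scp_forward(Tensor(rng.standard_normal((1, 1, 16, 16, 16))))
        assert out.shape == (1, 32, 8, 8, 8)
        assert np.all(out.data >= 0)

    def test_channel_mismatch_raises(self, rng):
        stage = make_stage(2, 4)
        with pytest.raises(ValueError, match="channels"):
            stage.scp_forward(Tensor(rng.standard_normal((1, 3, 8, 8, 8))))

    def test_zero_input_zero_output(self):
        stage = make_stage(2, 4)
        out = stage.scp_forward(Tensor(np.zeros((2, 2, 8, 8, 8))))
        np.testing.assert_array_equal(out.data, 0.0)


class TestSemanticGuide:
    def test_constant_input_gives_constant_guide(self):
        stage = make_stage(1, 4)
        pre = Tensor(np.full((1, 4, 8, 8, 8), 2.5))
        g = stage.semantic_guide(pre).data
        assert g.shape == pre.shape
        for c in range(4):
            np.testing.assert_allclose(g[0, c], g[0, c].flat[0], atol=1e-10)

    def test_nonidentity_on_random_input(self, rng):
        stage = make_stage(1, 4)
        pre = Tensor(rng.standard_normal((1, 4, 8, 8, 8)))
        g = stage.semantic_guide(pre)
        assert g.shape == pre.shape
        assert not np.allclose(g.data, pre.data)


class TestDiffusion:
    def test_zero_diffusivity_gives_pure_lambda_decay(self, rng):
        """With h == 0 the update is F <- lambda * F, so T steps give
        lambda^T * F0 exactly."""
        stage = make_stage()
        stage.h.gain.data = np.zeros(())
        stage.lam.data = np.asarray(0.7)
        f0 = rng.standard_normal((1, 4, 5, 5, 5))
        g = rng.standard_normal((1, 4, 5, 5, 5))
        out = sdp_diffuse(Tensor(f0), Tensor(g), stage.h, stage.lam, stage.nu, 3)
        np.testing.assert_allclose(out.data, 0.7 ** 3 * f0, rtol=1e-12)

    def test_constant_field_gives_pure_lambda_decay(self, rng):
        stage = make_stage()
        stage.lam.data = np.asarray(0.9)
        f0 = np.full((1, 4, 5, 5, 5), 3.0)
        g = rng.standard_normal((1, 4, 5, 5, 5))
        out = sdp_diffuse(Tensor(f0), Tensor(g), stage.h, stage.lam, stage.nu, 2)
        np.testing.assert_allclose(out.data, 0.9 ** 2 * f0, rtol=1e-10)

    def test_single_step_matches_bruteforce_neighborhood_sum(self, rng):
        """One diffusion step against a direct per-voxel loop over the
        6-connected neighborhood."""
        stage = make_stage(1, 1, steps=1)
        f0 = rng.standard_normal((1, 1, 5, 5, 5))
        g = rng.standard_normal((1, 1, 5, 5, 5))
        lam = float(stage.lam.data)
        nu = float(stage.nu.data)

        def h_scalar(u):
            return float(stage.h(Tensor(np.array(u))).data)

        fhat = np.zeros_like(f0)
        for z in range(5):
            for y in range(5):
                for x in range(5):
                    for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if not (0 <= zz < 5 and 0 <= yy < 5 and 0 <= xx < 5):
                            continue
                        u = (g[0, 0, zz, yy, xx] - g[0, 0, z, y, x]) ** 2
                        fhat[0, 0, z, y, x] += h_scalar(u) * (
                            f0[0, 0, zz, yy, xx] - f0[0, 0, z, y, x])
        want = lam * f0 + nu * fhat
        got = sdp_diffuse(Tensor(f0), Tensor(g), stage.h, stage.lam, stage.nu, 1)
        np.testing.assert_allclose(got.data, want, atol=1e-6)

    def test_shape_mismatch_raises(self, rng):
        stage = make_stage()
        with pytest.raises(ValueError):
            sdp_diffuse(Tensor(np.zeros((1, 2, 4, 4, 4))),
                        Tensor(np.zeros((1, 2, 4, 4, 5))),
                        stage.h, stage.lam, stage.nu, 1)

    def test_sup_norm_stability_bound(self, rng):
        """sup|F^T| <= (lambda + nu * h_max * 6)^T * sup|F0| for
        nonnegative h."""
        stage = make_stage()
        f0 = rng.standard_normal((1, 3, 6, 6, 6))
        g = rng.standard_normal((1, 3, 6, 6, 6))
        steps = 3
        # largest edge weight actually realised on this guide
        h_max = 0.0
        for axis in (2, 3, 4):
            d = np.diff(g, axis=axis)
            u = (d ** 2).sum(axis=1, keepdims=True)
            h_max = max(h_max, float(stage.h(Tensor(u)).data.max()))
        lam = float(stage.lam.data)
        nu = float(stage.nu.data)
        out = sdp_diffuse(Tensor(f0), Tensor(g), stage.h, stage.lam, stage.nu, steps)
        bound = (lam + nu * h_max * 6) ** steps * np.abs(f0).max()
        assert np.abs(out.data).max() <= bound + 1e-9


class TestBlock:
    def test_gate_forced_to_one_gives_scp_plus_projection_bias(self, rng):
        stage = make_stage(2, 4)
        stage.proj.w.data[:] = 0.0
        x = Tensor(rng.standard_normal((1, 2, 8, 8, 8)))
        out = stage(x, gate_override=1.0)
        np.testing.assert_allclose(out.data, stage.scp_forward(x).data, atol=1e-10)

    def test_block_parameters_all_receive_gradient(self, rng):
        stage = make_stage(2, 4, steps=1)
        x = Tensor(rng.standard_normal((2, 2, 8, 8, 8)))
        loss = (stage(x) ** 2.0).sum()
        loss.backward()
        for name, p in stage.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), name

    def test_gradient_matches_finite_difference_spot_check(self, rng):
        stage = make_stage(1, 2, steps=1)
        x = Tensor(rng.standard_normal((1, 1, 6, 6, 6)))
        params = dict(stage.named_parameters())
        picks = [("lam", ()), ("conv1.w", (0, 0, 1, 1, 1)), ("gate_fc.w", (0, 0))]
        loss = (stage(x) ** 2.0).sum()
        loss.backward()
        grads = {n: params[n].grad[i] if params[n].grad.ndim else float(params[n].grad)
                 for n, i in picks}
        eps = 1e-5
        for name, idx in picks:
            p = params[name]
            orig = p.data.copy()
            for sign in (+1, -1):
                p.data = orig.copy()
                if p.data.ndim:
                    p.data[idx] += sign * eps
                else:
                    p.data = p.data + sign * eps
                val = float((stage(x) ** 2.0).sum().data)
                if sign > 0:
                    hi = val
                else:
                    lo = val
            p.data = orig
            fd = (hi - lo) / (2 * eps)
            assert grads[name] == pytest.approx(fd, rel=1e-3, abs=1e-6), name


class TestBackboneHierarchy:
    def test_stage_shapes_halve(self, rng):
        bb = HCNetBackbone(widths=(4, 8, 8, 8), rng=np.random.default_rng(0))
        maps = bb(Tensor(rng.standard_normal((2, 1, 32, 32, 32)).astype(np.float32)))
        shapes = [m.shape for m in maps]
        assert shapes == [(2, 4, 16, 16, 16), (2, 8, 8, 8, 8),
                          (2, 8, 4, 4, 4), (2, 8, 2, 2, 2)]
        vols = [np.prod(s[2:]) for s in shapes]
        assert all(a > b for a, b in zip(vols, vols[1:]))

    def test_non_divisible_input_is_padded(self, rng, caplog):
        bb = HCNetBackbone(widths=(4, 4, 4, 4), rng=np.random.default_rng(0))
        maps = bb(Tensor(rng.standard_normal((1, 1, 24, 24, 24)).astype(np.float32)))
        assert maps[0].shape[2:] == (16, 16, 16)  # padded to 32 then halved

    def test_eval_mode_batch_permutation_equivariance(self, rng):
        bb = HCNetBackbone(widths=(4, 4, 4, 4), rng=np.random.default_rng(1))
        bb.eval()
        x = rng.standard_normal((3, 1, 16, 16, 16)).astype(np.float32)
        out = bb(Tensor(x))[3].data
        perm = [2, 0, 1]
        out_p = bb(Tensor(x[perm]))[3].data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-6)

    def test_zero_input_zero_hierarchy(self):
        bb = HCNetBackbone(widths=(4, 4, 4, 4), rng=np.random.default_rng(2))
        maps = bb(Tensor(np.zeros((1, 1, 16, 16, 16), dtype=np.float32)))
        for m in maps:
            np.testing.assert_array_equal(m.data, 0.0)
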