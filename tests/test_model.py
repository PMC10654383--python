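"""U-Net family: presets, gradients, receptive field, size contracts."""

import numpy as np
import pytest

from jitomo.model import NetworkSpec, PRESETS, build_network, parameter_count, preset_spec


class TestPresets:
    def test_standard_level_widths(self):
        net = build_network(preset_spec("standard"), seed=0)
        assert net.level_widths == (8, 16, 32)

    def test_c32_level_widths(self):
        net = build_network(preset_spec("c32"), seed=0)
        assert net.level_widths == (32, 64, 128)

    def test_all_fourteen_presets_buildable(self):
        assert len(PRESETS) == 14
        for name in PRESETS:
            spec = preset_spec(name)
            net = build_network(spec, seed=1)
            assert net.parameter_count() > 0

    def test_v_presets_share_weight_shapes_with_standard(self):
        """Patch-size variants change training data only, not the network."""
        std = build_network(preset_spec("standard"), seed=0)
        for name in ("v30", "v60", "v150"):
            v = build_network(preset_spec(name), seed=0)
            assert [p.shape for p in v.params()] == [p.shape for p in std.params()]

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            preset_spec("c64")

    def test_invalid_spec_fields_named(self):
        with pytest.raises(ValueError, match="levels"):
            NetworkSpec(levels=0)
        with pytest.raises(ValueError, match="frames"):
            NetworkSpec(frames=2, mode="2D+time")
        with pytest.raises(ValueError, match="mode"):
            NetworkSpec(mode="4D")


class TestDeterminismAndShapes:
    def test_same_seed_bitwise_identical_weights(self):
        a = build_network(preset_spec("standard"), seed=42)
        b = build_network(preset_spec("standard"), seed=42)
        assert all(np.array_equal(x, y) for x, y in zip(a.params(), b.params()))
        c = build_network(preset_spec("standard"), seed=43)
        assert any(not np.array_equal(x, y) for x, y in zip(a.params(), c.params()))

    def test_standard_20x20_in_out(self):
        net = build_network(preset_spec("standard"), seed=0)
        out = net.apply(np.random.default_rng(0).standard_normal((20, 20)))
        assert out.shape == (20, 20)

    def test_t3_sequence_collapses_to_single_frame(self):
        net = build_network(preset_spec("t3"), seed=0)
        out = net.apply(np.random.default_rng(0).standard_normal((3, 20, 20)))
        assert out.shape == (20, 20)

    def test_z5_slab_collapses_to_middle_slice(self):
        net = build_network(preset_spec("z5"), seed=0)
        out = net.apply(np.random.default_rng(0).standard_normal((5, 20, 20)))
        assert out.shape == (20, 20)

    def test_train_small_infer_large(self):
        """Fully convolutional: a 20x20-trained net runs on 1000x1000."""
        net = build_network(preset_spec("standard"), seed=0)
        out = net.apply(np.random.default_rng(1).standard_normal((1000, 1000)).astype(np.float32))
        assert out.shape == (1000, 1000)
        assert np.all(np.isfinite(out))

    def test_undersized_input_rejected(self):
        net = build_network(preset_spec("standard"), seed=0)
        with pytest.raises(ValueError, match="minimum"):
            net.apply(np.zeros((4, 4)))

    def test_wrong_depth_rejected(self):
        net = build_network(preset_spec("t3"), seed=0)
        with pytest.raises(ValueError, match="depth"):
            net.apply(np.zeros((5, 20, 20)))


class TestParameterCount:
    def test_wider_nets_have_more_parameters(self):
        assert parameter_count(preset_spec("c16")) > parameter_count(preset_spec("standard"))
        assert parameter_count(preset_spec("c32")) > parameter_count(preset_spec("c16"))

    def test_count_invariant_to_input_shape(self):
        assert parameter_count(preset_spec("v150")) == parameter_count(preset_spec("standard"))

    def test_standard_count_matches_hand_tally(self):
        """Layer-by-layer enumeration of the Standard architecture."""
        def conv(cin, cout, k=3):
            return cout * cin * k * k + cout

        def down(cin, cout):
            return cout * cin * 4 + cout

        def up(cin, cout):
            return cout * cin * 4 + cout

        total = (
            conv(1, 8) + 2 * conv(8, 8)          # encoder level 0
            + down(8, 16)
            + 3 * conv(16, 16)                   # encoder level 1
            + down(16, 32)
            + 3 * conv(32, 32)                   # encoder level 2
            + down(32, 64)
            + 2 * conv(64, 64)                   # bridge
            + up(64, 32) + conv(64, 32) + 2 * conv(32, 32)   # decoder level 2
            + up(32, 16) + conv(32, 16) + 2 * conv(16, 16)   # decoder level 1
            + up(16, 8) + conv(16, 8) + 2 * conv(8, 8)       # decoder level 0
            + (8 * 1 + 1)                        # final 1x1 projection
        )
        assert parameter_count(preset_spec("standard")) == total


class TestGradients:
    @pytest.mark.parametrize("mode,frames,xshape", [
        ("2D", 1, (2, 1, 8, 8)),
        ("2D+time", 3, (2, 1, 3, 8, 8)),
    ])
    def test_backward_matches_finite_differences(self, mode, frames, xshape):
        spec = NetworkSpec(base_features=2, levels=2, convs_per_block=1,
                           input_shape=(8, 8, 1), frames=frames, mode=mode)
        net = build_network(spec, seed=3)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(xshape).astype(np.float32)
        vshape = xshape if mode == "2D" else (2, 1, 1, 8, 8)
        v = rng.standard_normal(vshape).astype(np.float32)

        def loss():
            return float(np.sum((net.forward(x) - v) ** 2))

        y = net.forward(x)
        net.backward(2.0 * (y - v))
        analytic = [g.copy() for g in net.grads()]
        for p, g in zip(net.params(), analytic):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-2
            old = p[idx]
            p[idx] = old + eps
            l1 = loss()
            p[idx] = old - eps
            l2 = loss()
            p[idx] = old
            num = (l1 - l2) / (2 * eps)
            assert num == pytest.approx(g[idx], rel=5e-2, abs=5e-4)


class TestReceptiveField:
    @staticmethod
    def _support_width(levels):
        spec = NetworkSpec(base_features=2, levels=levels, convs_per_block=1,
                           input_shape=(64, 64, 1))
        net = build_network(spec, seed=0)
        net.final.w[...] = 1.0  # zero-init final would hide the field
        n = 64
        x = np.zeros((1, 1, n, n), dtype=np.float32)
        base = net.forward(x.copy())
        x[0, 0, n // 2, n // 2] = 1.0
        diff = np.abs(net.forward(x) - base)[0, 0]
        rows = np.where(diff.max(axis=1) > 1e-7)[0]
        return rows.max() - rows.min() + 1

    def test_receptive_field_grows_with_levels(self):
        widths = [self._support_width(lv) for lv in (1, 2, 3)]
        assert widths[0] < widths[1] < widths[2]


class TestShiftConsistency:
    def test_tiled_interior_agrees_with_whole_image(self):
        """Interior pixels of overlapping tiles match whole-image output."""
        spec = preset_spec("standard")
        net = build_network(spec, seed=5)
        rng = np.random.default_rng(2)
        net.final.w[...] = rng.standard_normal(net.final.w.shape).astype(np.float32) * 0.1
        img = rng.standard_normal((256, 256)).astype(np.float32)
        whole = net.apply(img)
        off, size = 48, 160
        tile = net.apply(img[off:off + size, off:off + size])
        margin = 64  # beyond the receptive-field radius
        inner = slice(margin, size - margin)
        np.testing.assert_allclose(
            tile[inner, inner],
            whole[off + margin:off + size - margin, off + margin:off + size - margin],
            rtol=1e-4, atol=1e-6,
        )
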