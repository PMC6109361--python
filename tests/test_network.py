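import numpy as np
import pytest

from mfsr.errors import DataError, SpecError
from mfsr.network import (
    ConvLayerSpec,
    LayerParams,
    MFCNSpec,
    MFUSpec,
    baseline_spec,
    build_network,
    conv_layer,
    count_parameters,
    forward,
    forward_batch,
    forward_mfu,
    load_params,
    mfu,
    plain_cnn_spec,
    save_params,
)


def brute_force_conv(x, W, b):
    """Nested-loop same-padded convolution oracle.  x: (C, H, W)."""
    C, H, Wd = x.shape
    F, _, k, _ = W.shape
    r = k // 2
    out = np.zeros((F, H, Wd))
    for f in range(F):
        for y in range(H):
            for xx in range(Wd):
                acc = 0.0
                for c in range(C):
                    for i in range(k):
                        for j in range(k):
                            yy, xj = y + i - r, xx + j - r
                            if 0 <= yy < H and 0 <= xj < Wd:
                                acc += x[c, yy, xj] * W[f, c, i, j]
                out[f, y, xx] = acc + b[f]
    return out


class TestSpecs:
    def test_layer_spec_parse(self):
        layer = ConvLayerSpec.parse("9/32")
        assert (layer.kernel_size, layer.n_kernels) == (9, 32)

    def test_layer_spec_rejects_even_kernel(self):
        with pytest.raises(SpecError):
            ConvLayerSpec(4, 8)

    def test_subpath_channel_mismatch_rejected(self):
        with pytest.raises(SpecError, match="fusion"):
            MFUSpec(main=ConvLayerSpec(9, 32),
                    subpaths=((ConvLayerSpec(1, 16, relu=False),),))

    def test_recon_must_be_single_kernel(self):
        with pytest.raises(SpecError):
            MFCNSpec(units=(mfu("9/8", ["1/8"]),), recon=ConvLayerSpec(5, 2, relu=False))

    def test_yaml_roundtrip(self, tiny_net_spec, tmp_path):
        path = tmp_path / "net.yaml"
        tiny_net_spec.save(path)
        assert MFCNSpec.load(path) == tiny_net_spec

    def test_dict_roundtrip_preserves_relu_flag(self):
        spec = MFCNSpec((mfu("9/8", ["1/8"], relu_before_fusion=True),),
                        recon=ConvLayerSpec(5, 1, relu=False))
        assert MFCNSpec.from_dict(spec.to_dict()) == spec


class TestBaselineSpec:
    def test_structure(self):
        spec = baseline_spec()
        assert spec.n_units == 2
        assert (spec.recon.kernel_size, spec.recon.n_kernels) == (5, 1)
        u1, u2 = spec.units
        assert u1.main.notation() == "9/32"
        assert [l.notation() for l in u1.subpaths[0]] == ["1/32"]
        assert u2.main.notation() == "3/64"
        assert [l.notation() for l in u2.subpaths[0]] == ["1/64"]

    def test_parameter_count(self):
        assert count_parameters(baseline_spec()) == 24_897

    def test_single_trivial_layer_count(self):
        spec = MFCNSpec(units=(MFUSpec(main=ConvLayerSpec(1, 1)),),
                        recon=ConvLayerSpec(1, 1, relu=False))
        # unit layer: 1*1*1+1 = 2; recon: 1*1*1+1 = 2
        assert count_parameters(spec) == 4
        assert count_parameters(spec) - 2 == 2  # the 1/1 layer alone contributes 2

    def test_doubling_kernel_counts(self):
        doubled = MFCNSpec(
            units=(mfu("9/64", ["1/64"]), mfu("3/128", ["1/128"])),
            recon=ConvLayerSpec(5, 1, relu=False),
        )
        base = count_parameters(baseline_spec())
        assert 2 * base < count_parameters(doubled) < 4 * base


class TestPlainCnnSpec:
    def test_baseline_becomes_three_layers(self):
        plain = plain_cnn_spec(baseline_spec())
        assert all(len(u.subpaths) == 0 for u in plain.units)
        layers = [u.main.notation() for u in plain.units] + [plain.recon.notation()]
        assert layers == ["9/32", "3/64", "5/1"]
        assert plain.units[0].main.relu and plain.units[1].main.relu
        assert not plain.recon.relu

    def test_parameter_count(self):
        assert count_parameters(plain_cnn_spec(baseline_spec())) == 22_721
        assert 24_897 - 22_721 == 64 + 2_112

    def test_forward_equivalence_with_zero_subpaths(self, rng):
        spec = baseline_spec()
        params = build_network(spec, seed=0, init_std=0.05)
        for u in params.units:
            for sp in u.subpaths:
                for layer in sp:
                    layer.W[...] = 0.0
                    layer.b[...] = 0.0
        plain = build_network(plain_cnn_spec(spec), seed=1)
        for pu, mu_ in zip(plain.units, params.units):
            pu.main.W = mu_.main.W.copy()
            pu.main.b = mu_.main.b.copy()
        plain.recon.W = params.recon.W.copy()
        plain.recon.b = params.recon.b.copy()
        x = rng.uniform(0, 1, (16, 16))
        assert np.allclose(forward(params, x), forward(plain, x), atol=1e-12)


class TestBuildNetwork:
    def test_seeded_determinism(self, tiny_net_spec):
        a = build_network(tiny_net_spec, seed=7)
        b = build_network(tiny_net_spec, seed=7)
        for pa, pb in zip(a.layers(), b.layers()):
            assert np.array_equal(pa.W, pb.W)

    def test_biases_zero(self, tiny_net_spec):
        params = build_network(tiny_net_spec, seed=0)
        for p in params.layers():
            assert np.all(p.b == 0.0)

    def test_sample_std_matches_configured(self):
        params = build_network(baseline_spec(), seed=3)
        main2 = params.units[1].main.W  # 3*3*32*64 = 18,432 weights
        assert main2.size == 18_432
        assert 0.0008 <= main2.std() <= 0.0012

    def test_parameter_total_matches_count(self, tiny_net_spec):
        params = build_network(tiny_net_spec, seed=0)
        assert params.n_parameters() == count_parameters(tiny_net_spec)

    def test_init_record(self, tiny_net_spec):
        params = build_network(tiny_net_spec, seed=42)
        assert params.init == {"distribution": "gaussian", "std": 0.001, "seed": 42}

    def test_checkpoint_roundtrip(self, tiny_net_spec, tmp_path):
        params = build_network(tiny_net_spec, seed=5)
        path = tmp_path / "ckpt.npz"
        save_params(params, path)
        back = load_params(path)
        assert back.spec == tiny_net_spec
        for pa, pb in zip(params.layers(), back.layers()):
            assert np.array_equal(pa.W, pb.W)
            assert np.array_equal(pa.b, pb.b)


class TestConvolutionOracle:
    @pytest.mark.parametrize("k,c_in,c_out", [(1, 1, 3), (3, 2, 4), (5, 3, 2), (9, 1, 2)])
    def test_single_layer_matches_nested_loops(self, rng, k, c_in, c_out):
        x = rng.normal(size=(c_in, 12, 12))
        p = LayerParams(W=rng.normal(size=(c_out, c_in, k, k)),
                        b=rng.normal(size=c_out))
        assert np.allclose(conv_layer(x, p), brute_force_conv(x, p.W, p.b), atol=1e-6)

    def test_large_column_offset_route_matches_oracle(self, rng):
        # C*k^2 and F*k^2 both exceed the im2col threshold
        x = rng.normal(size=(4, 10, 10))
        p = LayerParams(W=rng.normal(size=(6, 4, 7, 7)), b=rng.normal(size=6))
        assert np.allclose(conv_layer(x, p), brute_force_conv(x, p.W, p.b), atol=1e-6)


class TestForwardMfu:
    def test_zero_subpaths_equal_main_relu(self, rng):
        unit = mfu("3/4", ["1/4"])
        params = build_network(MFCNSpec((unit,), recon=ConvLayerSpec(1, 1, relu=False)),
                               seed=0, init_std=0.1)
        uparams = params.units[0]
        for layer in uparams.subpaths[0]:
            layer.W[...] = 0.0
            layer.b[...] = 0.0
        x = rng.normal(size=(1, 9, 9))
        out = forward_mfu(x, unit, uparams)
        main = np.maximum(conv_layer(x, uparams.main), 0.0)
        assert np.allclose(out, main, atol=1e-12)

    def test_delta_plus_identity_doubles_input(self, rng):
        # main = centred delta kernel, sub-path 1x1 identity, nonnegative x
        unit = mfu("3/1", ["1/1"])
        params = build_network(MFCNSpec((unit,), recon=ConvLayerSpec(1, 1, relu=False)), seed=0)
        up = params.units[0]
        up.main.W[...] = 0.0
        up.main.W[0, 0, 1, 1] = 1.0
        up.main.b[...] = 0.0
        up.subpaths[0][0].W[...] = 1.0
        up.subpaths[0][0].b[...] = 0.0
        x = rng.uniform(0, 1, (1, 7, 7))
        assert np.allclose(forward_mfu(x, unit, up), 2 * x, atol=1e-12)

    def test_shape_contract_baseline_first_unit(self, rng):
        spec = baseline_spec()
        params = build_network(spec, seed=0)
        x = rng.normal(size=(1, 20, 24))
        out = forward_mfu(x, spec.units[0], params.units[0])
        assert out.shape == (32, 20, 24)

    def test_channel_mismatch_raises(self, rng):
        spec = baseline_spec()
        params = build_network(spec, seed=0)
        with pytest.raises(SpecError, match="channel"):
            forward_mfu(rng.normal(size=(3, 10, 10)), spec.units[0], params.units[0])

    def test_fusion_linearity(self, rng):
        # output == main + sum of instrumented sub-path outputs
        from mfsr.experiments import feature_maps

        spec = MFCNSpec((mfu("5/3", ["1/3", "3/3"]),), recon=ConvLayerSpec(3, 1, relu=False))
        params = build_network(spec, seed=2, init_std=0.3)
        img = rng.uniform(0, 1, (11, 11))
        maps = feature_maps(params, img)[0]
        fused = forward_mfu(img[None], spec.units[0], params.units[0])
        assert np.allclose(maps["main"] + sum(maps["subpaths"]), fused, atol=1e-10)
        assert np.allclose(maps["fused"], fused, atol=1e-10)


class TestForward:
    def test_zero_parameters_zero_output(self, tiny_net_spec, rng):
        params = build_network(tiny_net_spec, seed=0)
        for p in params.layers():
            p.W[...] = 0.0
            p.b[...] = 0.0
        x = rng.uniform(0, 1, (16, 16))
        assert np.all(forward(params, x) == 0.0)

    def test_composition_oracle(self, tiny_net_spec, rng):
        # forward == recon(mfu2(mfu1(x))) composed explicitly
        params = build_network(tiny_net_spec, seed=4, init_std=0.2)
        x = rng.uniform(0, 1, (8, 8))
        h = forward_mfu(x[None], tiny_net_spec.units[0], params.units[0])
        h = forward_mfu(h, tiny_net_spec.units[1], params.units[1])
        expected = conv_layer(h, params.recon)[0]
        assert np.allclose(forward(params, x), expected, atol=1e-10)

    def test_fresh_network_on_phantom_slice(self, mid_pair):
        params = build_network(baseline_spec(), seed=0)
        out = forward(params, mid_pair.lr)
        assert out.shape == mid_pair.lr.shape
        assert np.isfinite(out).all()

    def test_non_finite_input_rejected(self, tiny_net_spec):
        params = build_network(tiny_net_spec, seed=0)
        x = np.full((8, 8), np.nan)
        with pytest.raises(DataError):
            forward(params, x)

    def test_image_smaller_than_kernel_rejected(self, tiny_net_spec):
        params = build_network(tiny_net_spec, seed=0)
        with pytest.raises(DataError):
            forward(params, np.zeros((3, 3)))

    def test_float32_path_close_to_float64(self, tiny_net_spec, rng):
        params = build_network(tiny_net_spec, seed=1, init_std=0.1)
        x = rng.uniform(0, 1, (1, 1, 12, 12))
        y64, _ = forward_batch(params, x)
        y32, _ = forward_batch(params, x.astype(np.float32))
        assert np.allclose(y64, y32, atol=1e-5)


class TestShapePreservation:
    @pytest.mark.parametrize("name", [
        "MFCN_BL", "MFCN_s713", "MFCN_s957", "MFCN_s1159", "MFCN_n16321",
        "MFCN_S3", "MFCN_L2", "MFCN_U1", "MFCN_U3", "MFCN_BL_relu_fusion",
    ])
    def test_output_spatial_dims_preserved(self, name, rng):
        from mfsr.experiments import builtin_variants

        spec = builtin_variants()[name]
        params = build_network(spec, seed=0)
        x = rng.uniform(0, 1, (13, 15))
        assert forward(params, x).shape == (13, 15)
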