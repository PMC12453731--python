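"""Architecture contracts: shapes, attention closed forms, variants."""

import numpy as np
import pytest

import cardiofuse.nn as nn
from cardiofuse.errors import ConfigurationError
from cardiofuse.network import (
    VARIANTS,
    FusionNetwork,
    ModelConfig,
    SACMF,
    build_model,
    load_checkpoint,
    save_checkpoint,
)
from conftest import small_config


def _zero_module(module):
    for _, p in module.named_parameters():
        p.data[...] = 0.0


@pytest.fixture(scope="module")
def full_net():
    return FusionNetwork("full", ModelConfig(), seed=0).eval()


class TestEncoder:
    def test_level_shapes_for_2000_sample_input(self, full_net):
        x = nn.Tensor(np.random.default_rng(0).standard_normal((1, 2, 2000)))
        with nn.no_grad():
            feats = full_net.encode(x)
        shapes = [(f.shape[2], f.shape[1]) for f in feats["ecg"]]
        assert shapes == [(2000, 64), (400, 128), (80, 192), (16, 256)]
        assert [(f.shape[2], f.shape[1]) for f in feats["pcg"]] == shapes

    def test_encoders_weight_independent(self, full_net):
        e = dict(full_net.ecg_encoder.named_parameters())
        p = dict(full_net.pcg_encoder.named_parameters())
        assert e.keys() == p.keys()
        assert any(not np.array_equal(e[k].data, p[k].data) for k in e)

    def test_raw_injection_pool_windows_match_level_inputs(self):
        cfg = ModelConfig()
        assert cfg.raw_pool_window(3) == 5
        assert cfg.raw_pool_window(4) == 25
        assert 2000 // 5 == cfg.level_lengths()[2] == 400
        assert 2000 // 25 == cfg.level_lengths()[3] == 80

    def test_zero_raw_signal_equals_no_injection(self):
        """Raw injection is additive: a zero raw signal must leave the
        level outputs unchanged relative to removing the injection."""
        cfg = small_config()
        net = FusionNetwork("full", cfg, seed=3).eval()
        enc = net.ecg_encoder
        rng = np.random.default_rng(1)
        zero_raw = nn.Tensor(np.zeros((2, 1, cfg.input_len)))
        with nn.no_grad():
            injected = enc(zero_raw)
            # manual chain without injection on the same zero input
            x = zero_raw
            plain = []
            for level in range(1, 5):
                x = getattr(enc, f"cbr{level}")(x)
                x = getattr(enc, f"res{level}a")(x)
                x = getattr(enc, f"res{level}b")(x)
                plain.append(x)
        for a, b in zip(injected, plain):
            assert np.allclose(a.data, b.data)

    def test_misaligned_input_length_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(input_len=300).validate()


class TestClosedFormAttention:
    def test_se_gate_is_half_with_zeroed_excitation(self):
        rng = np.random.default_rng(0)
        se = nn.SqueezeExcite(8, 2, rng=rng)
        _zero_module(se)
        x = nn.Tensor(rng.standard_normal((3, 8, 16)))
        out = se(x)
        assert np.allclose(out.data, 0.5 * x.data, atol=1e-7)

    def test_se_gates_in_unit_interval_and_zero_maps_to_zero(self):
        rng = np.random.default_rng(2)
        se = nn.SqueezeExcite(8, 2, rng=rng)
        zero = nn.Tensor(np.zeros((2, 8, 16)))
        assert np.allclose(se(zero).data, 0.0)
        x = nn.Tensor(rng.standard_normal((2, 8, 16)))
        ratio = se(x).data / x.data
        assert (ratio > 0).all() and (ratio < 1).all()

    def test_spatial_maps_are_half_with_zeroed_weights(self):
        cfg = small_config()
        sac = SACMF(1, 8, None, cfg, rng=np.random.default_rng(0))
        _zero_module(sac.sam)
        f = nn.Tensor(np.random.default_rng(1).standard_normal((2, 8, 40)))
        m_ecg, m_pcg = sac.spatial_maps(f, f)
        assert np.allclose(m_ecg.data, 0.5)
        assert np.allclose(m_pcg.data, 0.5)
        assert m_ecg.shape == (2, 1, 40)

    def test_spatial_maps_bounded_in_unit_interval(self):
        cfg = small_config()
        sac = SACMF(1, 8, None, cfg, rng=np.random.default_rng(4))
        rng = np.random.default_rng(5)
        f = nn.Tensor(rng.standard_normal((2, 8, 40)))
        m_ecg, m_pcg = sac.spatial_maps(f, nn.Tensor(rng.standard_normal((2, 8, 40))))
        for m in (m_ecg, m_pcg):
            assert (m.data > 0).all() and (m.data < 1).all()

    def test_channel_attention_halves_with_zeroed_fc(self):
        cfg = small_config()
        sac = SACMF(1, 8, None, cfg, rng=np.random.default_rng(0))
        _zero_module(sac.cam)
        v = nn.Tensor(np.random.default_rng(1).standard_normal((2, 16, 40)))
        out = sac.cam(v)
        assert np.allclose(out.data, 0.5 * v.data, atol=1e-7)

    def test_res_block_with_zero_convs_is_relu_of_half_input(self):
        """Zero conv weights make the residual branch zero; the SE gate
        on a zero branch is 0.5 * 0 = 0, so output = ReLU(identity)."""
        rng = np.random.default_rng(0)
        from cardiofuse.network import SEResBlock
        block = SEResBlock(4, 7, 2, rng=rng)
        _zero_module(block)
        block.eval()
        x = nn.Tensor(rng.standard_normal((2, 4, 20)))
        with nn.no_grad():
            out = block(x)
        assert np.allclose(out.data, np.maximum(x.data, 0.0), atol=1e-6)


class TestFusion:
    def test_progressive_chain_output_shape(self, full_net):
        x = nn.Tensor(np.random.default_rng(0).standard_normal((1, 2, 2000)))
        with nn.no_grad():
            fused = full_net.fuse(full_net.encode(x))
        assert (fused.shape[2], fused.shape[1]) == (16, 256)

    def test_level1_and_level4_sacmf_shapes(self):
        cfg = ModelConfig()
        rng = np.random.default_rng(0)
        s1 = SACMF(1, 64, None, cfg, rng=rng).eval()
        s4 = SACMF(4, 256, 192, cfg, rng=rng).eval()
        r = np.random.default_rng(1)
        with nn.no_grad():
            o1 = s1(nn.Tensor(r.standard_normal((2, 64, 2000))),
                    nn.Tensor(r.standard_normal((2, 64, 2000))))
            o4 = s4(nn.Tensor(r.standard_normal((2, 256, 16))),
                    nn.Tensor(r.standard_normal((2, 256, 16))),
                    nn.Tensor(r.standard_normal((2, 192, 80))))
        assert (o1.shape[2], o1.shape[1]) == (2000, 64)
        assert (o4.shape[2], o4.shape[1]) == (16, 256)

    def test_spatial_identity_map_is_plain_concatenation(self):
        cfg = small_config()
        sac = SACMF(1, 8, None, cfg, rng=np.random.default_rng(0)).eval()
        rng = np.random.default_rng(1)
        fe = nn.Tensor(rng.standard_normal((2, 8, 40)))
        fp = nn.Tensor(rng.standard_normal((2, 8, 40)))
        sac.identity_spatial = True
        sac.identity_channel = True
        with nn.no_grad():
            v = nn.concat([fe, fp], axis=1)
            out_ident = sac(fe, fp)
            out_manual = nn.relu(sac.fuse_conv(sac.fuse_bn(v)))
        assert np.allclose(out_ident.data, out_manual.data)

    def test_conv_first_fusion_order_also_builds(self):
        cfg = small_config(fuse_bn_first=False)
        net = build_model("full", cfg, seed=1).eval()
        p = net.predict_proba_array(
            np.random.default_rng(0).standard_normal((2, 2, 500)))
        assert np.isfinite(p).all()

    def test_zeroed_pcg_leaves_ecg_branch_untouched(self, full_net):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((1, 2, 2000))
        X0 = X.copy()
        X0[:, 1, :] = 0.0
        with nn.no_grad():
            a = full_net.encode(nn.Tensor(X))
            b = full_net.encode(nn.Tensor(X0))
        for fa, fb in zip(a["ecg"], b["ecg"]):
            assert np.array_equal(fa.data, fb.data)
        assert not np.allclose(a["pcg"][0].data, b["pcg"][0].data)


class TestHead:
    def test_probabilities_sum_to_one(self, full_net):
        x = np.random.default_rng(0).standard_normal((3, 2, 2000))
        p = full_net.predict_proba_array(x)
        assert p.shape == (3, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p > 0).all() and (p < 1).all()

    def test_head_conv_halves_positions(self, full_net):
        x = nn.Tensor(np.random.default_rng(0).standard_normal((1, 256, 16)))
        with nn.no_grad():
            out = full_net.head.conv(x)
        assert out.shape[2] == 8

    def test_inference_is_deterministic(self, full_net):
        x = np.random.default_rng(0).standard_normal((2, 2, 2000))
        assert np.array_equal(full_net.predict_proba_array(x),
                              full_net.predict_proba_array(x))


class TestVariants:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_all_variants_build_and_run(self, variant):
        net = build_model(variant, small_config(), seed=1).eval()
        x = np.random.default_rng(0).standard_normal((2, 2, 500))
        p = net.predict_proba_array(x)
        assert p.shape == (2, 2)
        assert np.isfinite(p).all()

    def test_parameter_count_ordering(self):
        cfg = small_config()
        n = {v: build_model(v, cfg, seed=0).n_parameters()
             for v in ("full", "single_ecg", "sa_only", "ca_only")}
        assert n["full"] > n["single_ecg"]
        assert n["sa_only"] < n["full"]
        assert n["ca_only"] < n["full"]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            build_model("bogus", small_config())

    def test_concat_only_equals_full_with_identity_attention(self):
        """Forcing both attention branches to identity in the full model
        reproduces concat_only exactly under shared weights."""
        cfg = small_config(dropout=0.0)
        full = build_model("full", cfg, seed=2).eval()
        cat = build_model("concat_only", cfg, seed=99).eval()
        shared = {k: v for k, v in full.state_dict().items()
                  if ".sam." not in k and ".cam." not in k}
        cat.load_state_dict(shared, strict=True)
        full.set_attention_identity(spatial=True, channel=True)
        x = np.random.default_rng(5).standard_normal((3, 2, 500))
        pa = full.predict_proba_array(x)
        pb = cat.predict_proba_array(x)
        assert np.allclose(pa, pb, atol=1e-6)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        cfg = small_config()
        a = build_model("full", cfg, seed=1).eval()
        b = build_model("full", cfg, seed=2).eval()
        x = np.random.default_rng(0).standard_normal((2, 2, 500))
        assert not np.allclose(a.predict_proba_array(x),
                               b.predict_proba_array(x))
        save_checkpoint(a, tmp_path / "w.npz")
        load_checkpoint(b, tmp_path / "w.npz")
        assert np.allclose(a.predict_proba_array(x),
                           b.predict_proba_array(x))

    def test_variant_mismatch_rejected(self, tmp_path):
        cfg = small_config()
        a = build_model("full", cfg, seed=1)
        save_checkpoint(a, tmp_path / "w.npz")
        b = build_model("late_fusion", cfg, seed=1)
        with pytest.raises(ConfigurationError):
            load_checkpoint(b, tmp_path / "w.npz")
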