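"""Architecture arithmetic, attention/fusion contracts, spectral normalisation."""

import numpy as np
import pytest

import ssvep_tffnet as st
from ssvep_tffnet.nn import Tensor
from ssvep_tffnet.model import spectral_normalize


@pytest.fixture(scope="module")
def model12():
    cfg = st.ModelConfig(n_channels=8, n_samples=256, n_classes=12)
    return st.build_model(cfg, seed=0)


def _batch(rng, n, C, T):
    return (rng.standard_normal((n, C, T)).astype(np.float32),
            rng.standard_normal((n, C, 570)).astype(np.float32))


class TestShapes:
    @pytest.mark.parametrize("C,T,U", [(8, 256, 12), (9, 250, 40)])
    def test_forward_logit_count(self, rng, C, T, U):
        model = st.build_model(st.ModelConfig(n_channels=C, n_samples=T, n_classes=U),
                               seed=1)
        model.eval()
        ep, sp = _batch(rng, 3, C, T)
        assert model(ep, sp).data.shape == (3, U)

    def test_window_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            st.ModelConfig(n_channels=8, n_samples=5, n_classes=12)

    @pytest.mark.parametrize("T,width", [(256, 124), (250, 121), (102, 47)])
    def test_tempnet_prepool_width_formula(self, rng, T, width):
        assert (T - 10) // 2 + 1 == width
        model = st.build_model(st.ModelConfig(n_channels=8, n_samples=T, n_classes=12),
                               seed=1)
        model.eval()
        x = Tensor(rng.standard_normal((2, 1, 8, T)).astype(np.float32))
        out = model.tempnet(x)
        assert out.data.shape == (2, 32, 124)

    def test_specnet_stage_widths(self, rng, model12):
        model12.eval()
        s = Tensor(rng.standard_normal((2, 1, 8, 570)).astype(np.float32))
        sn = model12.specnet
        h1 = sn.b1(s)             # 1x10 stride 2: 570 -> 281
        assert h1.data.shape[-1] == 281
        h2 = sn.b3(sn.b2(h1))     # 1x35 stride 2: 281 -> 124
        assert h2.data.shape[-1] == 124
        assert sn(s).data.shape == (2, 32, 124)

    def test_flattened_fusion_length(self, model12):
        assert model12.cfg.flattened_size == 3968
        assert model12.classifier.fc1.weight.data.shape == (198, 3968)

    def test_wrong_spectrum_width_rejected(self, rng, model12):
        ep, _ = _batch(rng, 2, 8, 256)
        with pytest.raises(ValueError):
            model12(ep, rng.standard_normal((2, 8, 512)).astype(np.float32))

    @pytest.mark.parametrize("T", [102, 256, 307])
    def test_parameter_count_invariant_to_window_length(self, T):
        model = st.build_model(st.ModelConfig(n_channels=8, n_samples=T, n_classes=12),
                               seed=0)
        ref = st.build_model(st.ModelConfig(n_channels=8, n_samples=256, n_classes=12),
                             seed=0)
        assert model.n_parameters() == ref.n_parameters()

    def test_eval_forward_deterministic(self, rng, model12):
        model12.eval()
        ep, sp = _batch(rng, 4, 8, 256)
        a = model12(ep, sp).data
        b = model12(ep, sp).data
        assert np.array_equal(a, b)

    def test_all_zero_input_finite(self, model12):
        model12.eval()
        out = model12(np.zeros((2, 8, 256), np.float32),
                      np.zeros((2, 8, 570), np.float32))
        assert np.all(np.isfinite(out.data))


class TestChannelAttention:
    def test_zeroed_bottleneck_halves_features(self, rng, model12):
        model12.eval()
        att = model12.specnet.attention
        saved = [(p, p.data.copy()) for p in att.parameters()]
        try:
            for p in att.parameters():
                p.data[...] = 0.0
            f = Tensor(rng.standard_normal((3, 32, 124)).astype(np.float32))
            # all-zero weights are exempted from spectral normalisation
            with pytest.warns(UserWarning):
                out = att(f)
            assert np.allclose(out.data, f.data / 2.0, atol=1e-7)
        finally:
            for p, v in saved:
                p.data[...] = v

    def test_per_map_constant_gating_ratio(self, rng, model12):
        model12.eval()
        att = model12.specnet.attention
        f = rng.standard_normal((2, 32, 124)).astype(np.float32)
        f[np.abs(f) < 1e-3] = 1.0  # avoid division noise
        out = att(Tensor(f)).data
        ratio = out / f
        spread = ratio.max(axis=2) - ratio.min(axis=2)
        assert spread.max() < 1e-5
        assert np.all(ratio > 0) and np.all(ratio < 1)

    def test_weights_match_straight_line_reimplementation(self, rng, model12):
        model12.eval()
        att = model12.specnet.attention
        f = rng.standard_normal((3, 32, 124)).astype(np.float32)
        got = att.weights(Tensor(f)).data

        def fc(w_layer, v):
            w2d = w_layer.weight.data.reshape(w_layer.weight.data.shape[0], -1)
            u, vv = w_layer._sn_u, w_layer._sn_v
            sigma = float(u @ w2d @ vv)
            return v @ (w2d / sigma).T + w_layer.bias.data

        def act(a, v):
            alpha = a.alpha.data
            return np.where(v > 0, v, alpha * v)

        expected = []
        for sample in f:
            d_avg = sample.mean(axis=1)
            d_max = sample.max(axis=1)
            z = (fc(att.fc2, act(att.act, fc(att.fc1, d_avg)))
                 + fc(att.fc2, act(att.act, fc(att.fc1, d_max))))
            expected.append(1.0 / (1.0 + np.exp(-z)))
        assert np.abs(got - np.stack(expected)).max() < 1e-6


class TestFusion:
    def test_zero_gate_output_layer_gives_exact_mean(self, rng):
        cfg = st.ModelConfig(n_channels=8, n_samples=256, n_classes=12)
        model = st.build_model(cfg, seed=2)
        model.eval()
        fus = model.fusion
        fus.fc2.weight.data[...] = 0.0
        fus.fc2.bias.data[...] = 0.0
        ft = Tensor(rng.standard_normal((2, 32, 124)).astype(np.float32))
        ff = Tensor(rng.standard_normal((2, 32, 124)).astype(np.float32))
        with pytest.warns(UserWarning):
            fused = fus(ft, ff)
        assert np.allclose(fused.data, (ft.data + ff.data) / 2.0, atol=1e-7)

    def test_equal_branches_pass_through(self, rng, model12):
        model12.eval()
        ft = Tensor(rng.standard_normal((2, 32, 124)).astype(np.float32))
        fused = model12.fusion(ft, Tensor(ft.data.copy()))
        assert np.allclose(fused.data, ft.data, atol=1e-6)

    def test_convexity_and_weight_normalisation(self, rng, model12):
        model12.eval()
        ft = rng.standard_normal((3, 32, 124)).astype(np.float32)
        ff = rng.standard_normal((3, 32, 124)).astype(np.float32)
        fused = model12.fusion(Tensor(ft), Tensor(ff)).data
        lo = np.minimum(ft, ff)
        hi = np.maximum(ft, ff)
        assert np.all(fused >= lo - 1e-6)
        assert np.all(fused <= hi + 1e-6)
        w = model12.fusion.attention_weights(ft, ff)
        assert w.shape == (3, 32, 124, 2)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(w >= 0) and np.all(w <= 1)

    def test_shape_mismatch_rejected(self, rng, model12):
        with pytest.raises(ValueError, match="differ"):
            model12.fusion(Tensor(np.zeros((1, 32, 124), np.float32)),
                           Tensor(np.zeros((1, 32, 100), np.float32)))


class TestSpectralNormalization:
    def test_diagonal_worked_example(self):
        w = np.diag([2.0, 1.0])
        out = spectral_normalize(w, iterations=100)
        assert np.allclose(out, np.diag([1.0, 0.5]), atol=1e-9)

    def test_identity_unchanged(self):
        w = np.eye(4)
        assert np.allclose(spectral_normalize(w, 50), w, atol=1e-12)

    def test_power_iteration_matches_svd(self, rng):
        w = rng.standard_normal((10, 10))
        sigma_svd = np.linalg.svd(w, compute_uv=False)[0]
        out = spectral_normalize(w, iterations=50)
        assert np.linalg.svd(out, compute_uv=False)[0] == pytest.approx(1.0, rel=1e-4)
        assert np.allclose(out * sigma_svd, w, rtol=1e-4)

    def test_zero_weight_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="zero"):
            out = spectral_normalize(np.zeros((3, 3)))
        assert np.all(out == 0)

    def test_all_wrapped_layers_unit_sigma_after_convergence(self, model12):
        model12.converge_spectral_norm(n_steps=200)
        checked = 0
        for m in model12.modules():
            if getattr(m, "spectral_norm", False):
                w_eff = m.effective_weight().data
                w2d = w_eff.reshape(w_eff.shape[0], -1)
                sigma = np.linalg.svd(w2d, compute_uv=False)[0]
                assert sigma == pytest.approx(1.0, abs=1e-3)
                checked += 1
        assert checked >= 19  # every conv and linear layer is wrapped


class TestAblation:
    def test_time_only_ignores_spectrum(self, rng):
        cfg = st.ModelConfig(n_channels=8, n_samples=256, n_classes=12)
        model = st.build_ablation_model(cfg, "time_only", seed=5)
        model.eval()
        ep, sp = _batch(rng, 2, 8, 256)
        a = model(ep, sp).data
        b = model(ep, None).data
        assert np.array_equal(a, b)

    def test_frequency_only_ignores_epochs(self, rng):
        cfg = st.ModelConfig(n_channels=8, n_samples=256, n_classes=12)
        model = st.build_ablation_model(cfg, "frequency_only", seed=5)
        model.eval()
        ep, sp = _batch(rng, 2, 8, 256)
        assert np.array_equal(model(ep, sp).data, model(None, sp).data)

    def test_full_variant_equals_build_model(self, rng):
        cfg = st.ModelConfig(n_channels=8, n_samples=256, n_classes=12)
        a = st.build_model(cfg, seed=9)
        b = st.build_ablation_model(cfg, "full", seed=9)
        a.eval(); b.eval()
        ep, sp = _batch(rng, 2, 8, 256)
        assert np.array_equal(a(ep, sp).data, b(ep, sp).data)

    def test_unknown_branch_rejected(self):
        cfg = st.ModelConfig(n_channels=8, n_samples=256, n_classes=12)
        with pytest.raises(ValueError, match="branch"):
            st.build_ablation_model(cfg, "both_somehow")


class TestCheckpointRoundTrip:
    def test_state_arrays_restore_forward(self, rng, tmp_path):
        cfg = st.ModelConfig(n_channels=8, n_samples=256, n_classes=12)
        a = st.build_model(cfg, seed=3)
        state = a.state_arrays()
        np.savez(tmp_path / "ckpt.npz", **state)
        b = st.build_model(cfg, seed=99)
        with np.load(tmp_path / "ckpt.npz") as zf:
            b.load_state_arrays(dict(zf))
        a.eval(); b.eval()
        ep, sp = _batch(rng, 2, 8, 256)
        assert np.array_equal(a(ep, sp).data, b(ep, sp).data)

    def test_checkpoint_file_roundtrip(self, rng, tmp_path):
        import json

        cfg = st.ModelConfig(n_channels=8, n_samples=256, n_classes=12)
        a = st.build_ablation_model(cfg, "frequency_only", seed=3)
        path = st.save_checkpoint(a, tmp_path / "ckpt.npz")
        meta = json.loads(path.with_suffix(".json").read_text())
        assert meta["branch"] == "frequency_only"
        assert meta["n_parameters"] == a.n_parameters()
        b = st.load_checkpoint(path)
        a.eval(); b.eval()
        _, sp = _batch(rng, 2, 8, 256)
        assert np.array_equal(a(None, sp).data, b(None, sp).data)
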