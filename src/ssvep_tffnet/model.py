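"""SSVEP-TFFNet: a dual-branch time-frequency fusion network.

The network classifies steady-state visual evoked potential (SSVEP)
epochs into stimulus-frequency classes. A time-domain branch (TempNet)
ingests the raw multichannel epoch; a frequency-domain branch (SpecNet)
ingests the complex spectrum (concatenated real/imaginary DFT parts).
Branch outputs — both 32 feature maps of width 124 — are fused by a
position-wise attention gate (softmax over a time/frequency weight
pair) and classified by a two-layer fully connected head. Every
convolutional and fully connected weight is spectrally normalised to
unit largest singular value for 1-Lipschitz stability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import (
    AdaptiveAvgPool1d,
    BatchNorm2d,
    Conv2d,
    Dropout,
    LayerNorm,
    Linear,
    Module,
    PReLU,
    Tensor,
    power_iteration_sigma,
)

__all__ = [
    "ModelConfig",
    "SSVEPTFFNet",
    "TempNet",
    "SpecNet",
    "ChannelAttention",
    "FeatureFusion",
    "Classifier",
    "build_model",
    "build_ablation_model",
    "spectral_normalize",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture constants of the dual-branch network.

    The defaults reproduce the published layer tables; only the input
    geometry (``n_channels``, ``n_samples``) and the class count vary
    between paradigms.
    """

    n_channels: int
    n_samples: int
    n_classes: int
    feature_maps: int = 32
    feature_width: int = 124
    temporal_kernel: int = 10
    temporal_stride: int = 2
    spectral_kernels: tuple[int, int] = (10, 35)
    spectral_strides: tuple[int, int] = (2, 2)
    bicnn_kernel: int = 3
    spectrum_width: int = 570
    classifier_hidden: int = 198
    dropout_rate: float = 0.5
    attention_reduction: int = 4
    fusion_hidden: int = 16
    spectral_norm_enabled: bool = True

    def __post_init__(self):
        if self.n_samples < self.temporal_kernel:
            raise ValueError(
                f"window of {self.n_samples} samples is shorter than the "
                f"temporal kernel ({self.temporal_kernel})"
            )
        if self.n_classes < 2:
            raise ValueError("need at least two stimulus classes")

    @property
    def flattened_size(self) -> int:
        return self.feature_maps * self.feature_width


def _conv_out(width: int, kernel: int, stride: int) -> int:
    return (width - kernel) // stride + 1


class _ConvBNAct(Module):
    """Conv2d -> BatchNorm2d -> PReLU block."""

    def __init__(self, in_ch, out_ch, kernel, stride, padding, rng, sn):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, padding, rng=rng, spectral_norm=sn)
        self.bn = BatchNorm2d(out_ch)
        self.act = PReLU(out_ch)

    def __call__(self, x):
        return self.act(self.bn(self.conv(x)))


class TempNet(Module):
    """Time-domain branch.

    Two parallel paths apply a spatial (C x 1) and a strided temporal
    (1 x 10) convolution in opposite orders; their sum passes through a
    bidirectional kernel-3 convolution (forward and time-reversed, then
    summed), a 1 x 1 convolution, and adaptive average pooling to the
    common feature width.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        C, k, s = cfg.n_channels, cfg.temporal_kernel, cfg.temporal_stride
        sn = cfg.spectral_norm_enabled
        F = cfg.feature_maps
        self.st_spatial = _ConvBNAct(1, 16, (C, 1), (1, 1), (0, 0), rng, sn)
        self.st_temporal = _ConvBNAct(16, F, (1, k), (1, s), (0, 0), rng, sn)
        self.ts_temporal = _ConvBNAct(1, 16, (1, k), (1, s), (0, 0), rng, sn)
        self.ts_spatial = _ConvBNAct(16, F, (C, 1), (1, 1), (0, 0), rng, sn)
        self.drop_st = Dropout(cfg.dropout_rate, rng)
        self.drop_ts = Dropout(cfg.dropout_rate, rng)
        kb = cfg.bicnn_kernel
        self.bi_fwd = Conv2d(F, F, (1, kb), (1, 1), (0, kb // 2), rng=rng, spectral_norm=sn)
        self.bi_bwd = Conv2d(F, F, (1, kb), (1, 1), (0, kb // 2), rng=rng, spectral_norm=sn)
        self.bi_mix = _ConvBNAct(F, F, (1, 1), (1, 1), (0, 0), rng, sn)
        self.drop_bi = Dropout(cfg.dropout_rate, rng)
        self.pool = AdaptiveAvgPool1d(cfg.feature_width)
        self.feature_maps = F

    def __call__(self, x: Tensor) -> Tensor:
        # x: (N, 1, C, T)
        a = self.drop_st(self.st_temporal(self.st_spatial(x)))
        b = self.drop_ts(self.ts_spatial(self.ts_temporal(x)))
        h = a + b                                  # (N, 32, 1, L)
        fwd = self.bi_fwd(h)
        bwd = self.bi_bwd(h.flip(3)).flip(3)
        h = self.drop_bi(self.bi_mix(fwd + bwd))
        N, F, _, L = h.data.shape
        return self.pool(h.reshape(N, F, L))       # (N, 32, 124)


class ChannelAttention(Module):
    """Per-feature-map gating from pooled descriptors.

    Global average and global max descriptors share a two-layer
    bottleneck; their outputs are summed and squashed by a sigmoid to a
    scalar weight per feature map.
    """

    def __init__(self, n_maps: int, reduction: int, rng: np.random.Generator, sn: bool):
        super().__init__()
        hidden = max(n_maps // reduction, 1)
        self.fc1 = Linear(n_maps, hidden, rng=rng, spectral_norm=sn)
        self.act = PReLU(hidden)
        self.fc2 = Linear(hidden, n_maps, rng=rng, spectral_norm=sn)

    def weights(self, f: Tensor) -> Tensor:
        d_avg = f.mean(axis=2)                     # (N, 32)
        d_max = f.max(axis=2)
        z = self.fc2(self.act(self.fc1(d_avg))) + self.fc2(self.act(self.fc1(d_max)))
        return z.sigmoid()

    def __call__(self, f: Tensor) -> Tensor:
        w = self.weights(f)
        N, F = w.data.shape
        return f * w.reshape(N, F, 1)


class SpecNet(Module):
    """Frequency-domain branch over the C x 570 complex spectrum.

    Two parallel paths order the spatial (C x 1) and local spectral
    (1 x 10, stride 2) convolutions oppositely, each closing with a
    1 x 35 stride-2 context convolution (570 -> 281 -> 124); the summed
    output passes through channel attention.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        C = cfg.n_channels
        k1, k2 = cfg.spectral_kernels
        s1, s2 = cfg.spectral_strides
        sn = cfg.spectral_norm_enabled
        F = cfg.feature_maps
        # spatio-spectral path: C x 1 first
        self.a1 = _ConvBNAct(1, 16, (C, 1), (1, 1), (0, 0), rng, sn)
        self.a2 = _ConvBNAct(16, F, (1, k1), (1, s1), (0, 0), rng, sn)
        self.a3 = _ConvBNAct(F, F, (1, k2), (1, s2), (0, 0), rng, sn)
        # spectral-spatio path: 1 x 10 first
        self.b1 = _ConvBNAct(1, 16, (1, k1), (1, s1), (0, 0), rng, sn)
        self.b2 = _ConvBNAct(16, F, (C, 1), (1, 1), (0, 0), rng, sn)
        self.b3 = _ConvBNAct(F, F, (1, k2), (1, s2), (0, 0), rng, sn)
        self.drop_a = Dropout(cfg.dropout_rate, rng)
        self.drop_b = Dropout(cfg.dropout_rate, rng)
        self.attention = ChannelAttention(F, cfg.attention_reduction, rng, sn)
        self.expected_width = cfg.spectrum_width

    def __call__(self, s: Tensor) -> Tensor:
        # s: (N, 1, C, 570)
        if s.data.shape[-1] != self.expected_width:
            raise ValueError(
                f"spectrum width {s.data.shape[-1]} != expected {self.expected_width}"
            )
        a = self.drop_a(self.a3(self.a2(self.a1(s))))
        b = self.drop_b(self.b3(self.b2(self.b1(s))))
        h = a + b                                   # (N, 32, 1, 124)
        N, F, _, L = h.data.shape
        return self.attention(h.reshape(N, F, L))   # (N, 32, 124)


def _softmax_pair_mix(z: Tensor, x: Tensor, y: Tensor) -> Tensor:
    """Convex mix ``a0*x + a1*y`` with ``(a0, a1) = softmax(z)`` per row.

    z: (n, 2); x, y: (n,). Gradients flow into all three inputs.
    """
    zs = z.data - z.data.max(axis=1, keepdims=True)
    e = np.exp(zs)
    a = e / e.sum(axis=1, keepdims=True)           # (n, 2)
    out = Tensor(a[:, 0] * x.data + a[:, 1] * y.data, parents=(z, x, y))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * a[:, 0])
        if y.requires_grad:
            y._accum(g * a[:, 1])
        if z.requires_grad:
            dl_da = np.stack([g * x.data, g * y.data], axis=1)
            dz = a * (dl_da - (dl_da * a).sum(axis=1, keepdims=True))
            z._accum(dz.astype(z.data.dtype))

    out._backward = bwd
    return out


class FeatureFusion(Module):
    """Dynamic position-wise weighting of the two branch feature maps.

    At every position the (time, frequency) value pair passes through a
    shared two-layer gate; a softmax over the two output logits yields
    convex weights used for the weighted summation.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        sn = cfg.spectral_norm_enabled
        self.fc1 = Linear(2, cfg.fusion_hidden, rng=rng, spectral_norm=sn)
        self.act = PReLU(cfg.fusion_hidden)
        self.fc2 = Linear(cfg.fusion_hidden, 2, rng=rng, spectral_norm=sn)

    def _logits(self, ft: Tensor, ff: Tensor) -> Tensor:
        n = ft.data.size
        pair_data = np.stack([ft.data.reshape(n), ff.data.reshape(n)], axis=1)
        pair = Tensor(pair_data, parents=(ft, ff))

        def bwd(g):
            if ft.requires_grad:
                ft._accum(g[:, 0].reshape(ft.data.shape))
            if ff.requires_grad:
                ff._accum(g[:, 1].reshape(ff.data.shape))

        pair._backward = bwd
        return self.fc2(self.act(self.fc1(pair)))

    def attention_weights(self, ft: np.ndarray, ff: np.ndarray) -> np.ndarray:
        """Evaluation helper: (alpha_t, alpha_f) per position, shape (..., 2)."""
        z = self._logits(Tensor(ft.astype(np.float32)), Tensor(ff.astype(np.float32))).data
        zs = z - z.max(axis=1, keepdims=True)
        e = np.exp(zs)
        a = e / e.sum(axis=1, keepdims=True)
        return a.reshape(ft.shape + (2,))

    def __call__(self, ft: Tensor, ff: Tensor) -> Tensor:
        if ft.data.shape != ff.data.shape:
            raise ValueError(f"branch shapes differ: {ft.data.shape} vs {ff.data.shape}")
        shape = ft.data.shape
        n = ft.data.size
        z = self._logits(ft, ff)
        fused = _softmax_pair_mix(z, ft.reshape(n), ff.reshape(n))
        return fused.reshape(*shape)


class Classifier(Module):
    """Two-layer head: 3968 -> 198 (LayerNorm, PReLU, Dropout) -> U logits."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        sn = cfg.spectral_norm_enabled
        self.fc1 = Linear(cfg.flattened_size, cfg.classifier_hidden, rng=rng, spectral_norm=sn)
        self.norm = LayerNorm(cfg.classifier_hidden)
        self.act = PReLU(cfg.classifier_hidden)
        self.drop = Dropout(cfg.dropout_rate, rng)
        self.fc2 = Linear(cfg.classifier_hidden, cfg.n_classes, rng=rng, spectral_norm=sn)

    def __call__(self, fused: Tensor) -> Tensor:
        N = fused.data.shape[0]
        h = fused.reshape(N, -1)
        h = self.drop(self.act(self.norm(self.fc1(h))))
        return self.fc2(h)


class SSVEPTFFNet(Module):
    """Full dual-branch model; ``branch`` selects ablation variants."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, branch: str = "full"):
        super().__init__()
        if branch not in ("full", "time_only", "frequency_only"):
            raise ValueError(f"unknown branch variant: {branch!r}")
        self.cfg = cfg
        self.seed = seed
        self.branch = branch
        rng = np.random.default_rng(seed)
        self.rng = rng
        if branch != "frequency_only":
            self.tempnet = TempNet(cfg, rng)
        if branch != "time_only":
            self.specnet = SpecNet(cfg, rng)
        if branch == "full":
            self.fusion = FeatureFusion(cfg, rng)
        self.classifier = Classifier(cfg, rng)

    def __call__(self, epochs: np.ndarray | None, spectra: np.ndarray | None) -> Tensor:
        """Forward pass on float32 batches (N,C,T) and (N,C,570) -> (N,U) logits."""
        if self.branch != "frequency_only":
            if epochs is None:
                raise ValueError("time branch requires the epoch input")
            x = np.asarray(epochs, dtype=np.float32)
            if x.ndim != 3 or x.shape[1] != self.cfg.n_channels:
                raise ValueError(f"expected epochs (N, {self.cfg.n_channels}, T), got {x.shape}")
            xt = Tensor(x[:, None, :, :])
            ft = self.tempnet(xt)
        if self.branch != "time_only":
            if spectra is None:
                raise ValueError("frequency branch requires the spectrum input")
            s = np.asarray(spectra, dtype=np.float32)
            if s.ndim != 3 or s.shape[1] != self.cfg.n_channels:
                raise ValueError(f"expected spectra (N, {self.cfg.n_channels}, W), got {s.shape}")
            st = Tensor(s[:, None, :, :])
            ff = self.specnet(st)
        if self.branch == "full":
            fused = self.fusion(ft, ff)
        elif self.branch == "time_only":
            fused = ft
        else:
            fused = ff
        return self.classifier(fused)

    # ------------------------------------------------------------------
    def converge_spectral_norm(self, n_steps: int = 100) -> dict[str, float]:
        """Refine every layer's power-iteration estimate; returns sigmas."""
        out = {}
        for i, m in enumerate(self.modules()):
            if hasattr(m, "converge_sigma") and getattr(m, "spectral_norm", False):
                out[f"layer{i}"] = m.converge_sigma(n_steps)
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat, ordered mapping of all learnable and running state."""
        state: dict[str, np.ndarray] = {}
        for i, m in enumerate(self.modules()):
            for name, val in vars(m).items():
                if hasattr(val, "requires_grad") and getattr(val, "requires_grad", False):
                    state[f"m{i}.{name}"] = val.data
                elif isinstance(val, np.ndarray):
                    state[f"m{i}.{name}"] = val
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        if set(own) != set(state):
            raise ValueError("checkpoint does not match model structure")
        for i, m in enumerate(self.modules()):
            for name, val in list(vars(m).items()):
                key = f"m{i}.{name}"
                if key in state:
                    if hasattr(val, "requires_grad") and getattr(val, "requires_grad", False):
                        val.data = state[key].copy()
                    else:
                        setattr(m, name, state[key].copy())


def build_model(cfg: ModelConfig, seed: int = 0) -> SSVEPTFFNet:
    """Instantiate the full dual-branch network with seeded initialisation."""
    return SSVEPTFFNet(cfg, seed=seed, branch="full")


def build_ablation_model(cfg: ModelConfig, branch: str, seed: int = 0) -> SSVEPTFFNet:
    """Instantiate a single-branch variant (``time_only``/``frequency_only``) or ``full``."""
    return SSVEPTFFNet(cfg, seed=seed, branch=branch)


def save_checkpoint(model: SSVEPTFFNet, path: str | Path) -> Path:
    """Write weights + running state (.npz) and a JSON summary sidecar.

    The sidecar records the full model configuration, the training
    seed, branch variant, parameter count and per-array shapes, so any
    forward pass is reproducible from the file pair alone.
    """
    path = Path(path)
    state = model.state_arrays()
    np.savez(path, **state)
    meta = {
        "model_config": asdict(model.cfg),
        "seed": model.seed,
        "branch": model.branch,
        "n_parameters": model.n_parameters(),
        "array_shapes": {k: list(v.shape) for k, v in state.items()},
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def load_checkpoint(path: str | Path) -> SSVEPTFFNet:
    """Rebuild a model from :func:`save_checkpoint` output."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = dict(meta["model_config"])
    for key in ("spectral_kernels", "spectral_strides"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = SSVEPTFFNet(ModelConfig(**cfg_dict), seed=meta["seed"],
                        branch=meta["branch"])
    with np.load(path) as zf:
        model.load_state_arrays(dict(zf))
    return model


def spectral_normalize(w: np.ndarray, iterations: int = 50) -> np.ndarray:
    """Divide a weight array by its largest singular value.

    Convolution kernels are viewed as (out maps, everything else); the
    singular value is estimated by deterministic power iteration. An
    all-zero weight is returned unchanged with a warning.
    """
    w = np.asarray(w, dtype=np.float64)
    w2d = w.reshape(w.shape[0], -1)
    if float(np.abs(w2d).max()) == 0.0:
        warnings.warn("spectral_normalize: all-zero weight left unchanged")
        return w
    u0 = np.ones(w2d.shape[0]) / np.sqrt(w2d.shape[0])
    sigma, _, _ = power_iteration_sigma(w2d, u0, n_steps=iterations)
    return w / sigma
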