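"""The fusion network: modality encoders, cross-modal fusion, classifier.

Three-branch design: two weight-independent, architecturally identical
modality encoders (ECG, PCG) and a progressive fusion branch.  Each
encoder runs four levels of CBR (conv - batch norm - ReLU) followed by
two SE-ResNet blocks; the level's downsampling (stride 5) happens once,
in the CBR convolution.  At levels 3 and 4 the raw input signal,
average-pooled to the level-input length (windows 5 and 25 for a
2000-sample input), is added to the level input, broadcast across all
feature channels.

Fusion at each level concatenates the two modality features, applies a
spatial attention block producing one weight map per modality, rescales
and re-concatenates (``V_s``), applies SE-style channel attention
(``V_c``), then fuses with the previous level's output (average-pooled
by 5 to the current length) through BN -> conv(k=7) -> ReLU.  The final
fused map feeds a small convolution + GAP + dense classifier head.

For a 2000-sample input the level shapes are (2000, 64), (400, 128),
(80, 192), (16, 256), and the fused output is (16, 256).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError
from .nn import Tensor

VARIANTS = (
    "full", "single_ecg", "single_pcg", "early_fusion", "late_fusion",
    "only_last_sacmf", "concat_only", "sa_only", "ca_only",
)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults are the full-scale model."""

    input_len: int = 2000
    channels: tuple[int, ...] = (64, 128, 192, 256)
    kernel_size: int = 7
    strides: tuple[int, ...] = (1, 5, 5, 5)
    se_ratio: int = 16
    spatial_reduce: int = 4
    spatial_kernel: int = 16
    channel_ratio: int = 16
    prev_pool: int = 5
    head_hidden: tuple[int, ...] = (128, 64, 32)
    head_conv_kernel: int = 3
    head_conv_stride: int = 2
    dropout: float = 0.5
    n_classes: int = 2
    # fusion op order: BN before the learnable conv (default) or after
    fuse_bn_first: bool = True

    def level_lengths(self) -> list[int]:
        """Input length of each level (before that level's stride)."""
        lens = [self.input_len]
        for s in self.strides[:-1]:
            lens.append(-(-lens[-1] // s))
        return lens

    def raw_pool_window(self, level: int) -> int:
        """Pool window taking the raw signal to the level-input length."""
        return int(np.prod(self.strides[:level - 1]))

    def validate(self) -> None:
        total = int(np.prod(self.strides))
        if self.input_len % total:
            raise ConfigurationError(
                f"input_len {self.input_len} must be a multiple of "
                f"{total} for the stride/pooling chain to align"
            )
        lens = self.level_lengths()
        for level in (3, 4):
            w = self.raw_pool_window(level)
            if self.input_len % w or self.input_len // w != lens[level - 1]:
                raise ConfigurationError(
                    f"raw-injection pooling window {w} does not reach the "
                    f"level-{level} input length {lens[level - 1]}"
                )


class CBRBlock(nn.Module):
    """conv -> batch norm -> ReLU; the only strided op in a level."""

    def __init__(self, cin, cout, kernel, stride, *, rng):
        super().__init__()
        self.conv = nn.Conv1d(cin, cout, kernel, stride, bias=False, rng=rng)
        self.bn = nn.BatchNorm1d(cout)

    def forward(self, x):
        return nn.relu(self.bn(self.conv(x)))


class SEResBlock(nn.Module):
    """Residual block with a squeeze-and-excitation gate, shape preserving."""

    def __init__(self, channels, kernel, se_ratio, *, rng):
        super().__init__()
        self.channels = channels
        self.conv1 = nn.Conv1d(channels, channels, kernel, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm1d(channels)
        self.conv2 = nn.Conv1d(channels, channels, kernel, 1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm1d(channels)
        self.se = nn.SqueezeExcite(channels, se_ratio, rng=rng)

    def forward(self, x):
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"res block expects {self.channels} channels, got {x.shape[1]}"
            )
        h = nn.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        h = self.se(h)
        return nn.relu(nn.add(h, x))


class ModalityEncoder(nn.Module):
    """Four-level feature pyramid with raw-signal injection at levels 3-4."""

    def __init__(self, cfg: ModelConfig, in_channels: int = 1, *, rng):
        super().__init__()
        self.cfg = cfg
        cin = in_channels
        for i, (cout, stride) in enumerate(zip(cfg.channels, cfg.strides), 1):
            setattr(self, f"cbr{i}",
                    CBRBlock(cin, cout, cfg.kernel_size, stride, rng=rng))
            setattr(self, f"res{i}a",
                    SEResBlock(cout, cfg.kernel_size, cfg.se_ratio, rng=rng))
            setattr(self, f"res{i}b",
                    SEResBlock(cout, cfg.kernel_size, cfg.se_ratio, rng=rng))
            cin = cout

    def forward(self, raw: Tensor) -> list[Tensor]:
        """``raw`` is (N, in_channels, L); returns the four level outputs."""
        pooled_raw = nn.mean_channels(raw) if raw.shape[1] > 1 else raw
        feats = []
        x = raw
        for level in range(1, 5):
            if level in (3, 4):
                w = self.cfg.raw_pool_window(level)
                inj = nn.avg_pool1d(pooled_raw, w)
                if inj.shape[2] != x.shape[2]:
                    raise ConfigurationError(
                        f"level {level}: pooled raw length {inj.shape[2]} "
                        f"!= level input length {x.shape[2]}"
                    )
                x = nn.add(x, inj)  # broadcast across feature channels
            x = getattr(self, f"cbr{level}")(x)
            x = getattr(self, f"res{level}a")(x)
            x = getattr(self, f"res{level}b")(x)
            feats.append(x)
        return feats


class SpatialAttention(nn.Module):
    """Two modality-specific per-position weight maps from concat features."""

    def __init__(self, channels2c: int, cfg: ModelConfig, *, rng):
        super().__init__()
        hidden = max(channels2c // cfg.spatial_reduce, 8)
        self.reduce = nn.Conv1d(channels2c, hidden, 1, 1, rng=rng)
        self.spatial = nn.Conv1d(hidden, hidden, cfg.spatial_kernel, 1, rng=rng)
        self.project = nn.Conv1d(hidden, 2, 1, 1, rng=rng)

    def forward(self, concat: Tensor) -> tuple[Tensor, Tensor]:
        h = nn.relu(self.reduce(concat))
        h = nn.relu(self.spatial(h))
        maps = nn.sigmoid(self.project(h))          # (N, 2, L)
        return nn.narrow(maps, 1, 0, 1), nn.narrow(maps, 1, 1, 1)


class ChannelAttention(nn.Module):
    """SE-style gating of the spatially refined concat features."""

    def __init__(self, channels2c: int, cfg: ModelConfig, *, rng):
        super().__init__()
        hidden = max(channels2c // cfg.channel_ratio, 1)
        self.fc1 = nn.Linear(channels2c, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels2c, rng=rng)

    def forward(self, v_s: Tensor) -> Tensor:
        s = nn.global_avg_pool(v_s)
        s = nn.relu(self.fc1(s))
        g = nn.sigmoid(self.fc2(s))
        gate = nn.reshape(g, (g.shape[0], g.shape[1], 1))
        return nn.mul(v_s, gate)


class SACMF(nn.Module):
    """Selective attention-based cross-modal fusion at one level.

    ``identity_spatial`` / ``identity_channel`` replace the respective
    attention branch by the identity (used by the ablation variants and
    the equivalence checks); they can also be toggled after building.
    """

    def __init__(self, level: int, c_level: int, c_prev: int | None,
                 cfg: ModelConfig, *, rng,
                 identity_spatial: bool = False,
                 identity_channel: bool = False):
        super().__init__()
        self.level = level
        self.c_level = c_level
        self.c_prev = c_prev
        self.prev_pool = cfg.prev_pool
        self.identity_spatial = identity_spatial
        self.identity_channel = identity_channel
        c2 = 2 * c_level
        if not identity_spatial:
            self.sam = SpatialAttention(c2, cfg, rng=rng)
        if not identity_channel:
            self.cam = ChannelAttention(c2, cfg, rng=rng)
        fuse_in = c2 + (c_prev or 0)
        self.bn_first = cfg.fuse_bn_first
        self.fuse_bn = nn.BatchNorm1d(fuse_in if cfg.fuse_bn_first else c_level)
        self.fuse_conv = nn.Conv1d(fuse_in, c_level, cfg.kernel_size, 1,
                                   bias=False, rng=rng)

    def spatial_maps(self, f_ecg: Tensor, f_pcg: Tensor):
        cat = nn.concat([f_ecg, f_pcg], axis=1)
        return self.sam(cat)

    def forward(self, f_ecg: Tensor, f_pcg: Tensor,
                f_prev: Tensor | None = None) -> Tensor:
        if f_ecg.shape != f_pcg.shape:
            raise ConfigurationError("modality feature shapes differ")
        if (f_prev is None) != (self.c_prev is None):
            raise ConfigurationError(
                f"level {self.level}: previous-level feature "
                f"{'missing' if self.c_prev else 'unexpected'}"
            )
        if self.identity_spatial or getattr(self, "sam", None) is None:
            v_s = nn.concat([f_ecg, f_pcg], axis=1)
        else:
            m_ecg, m_pcg = self.spatial_maps(f_ecg, f_pcg)
            v_s = nn.concat([nn.mul(f_ecg, m_ecg), nn.mul(f_pcg, m_pcg)],
                            axis=1)
        if self.identity_channel or getattr(self, "cam", None) is None:
            v_c = v_s
        else:
            v_c = self.cam(v_s)
        if f_prev is not None:
            prev = nn.avg_pool1d(f_prev, self.prev_pool)
            if prev.shape[2] != v_c.shape[2]:
                raise ConfigurationError(
                    f"level {self.level}: pooled previous length "
                    f"{prev.shape[2]} != {v_c.shape[2]}"
                )
            z = nn.concat([prev, v_c], axis=1)
        else:
            z = v_c
        if self.bn_first:
            return nn.relu(self.fuse_conv(self.fuse_bn(z)))
        return nn.relu(self.fuse_bn(self.fuse_conv(z)))


class ClassifierHead(nn.Module):
    """conv(k=3, s=2) -> GAP -> dense stack with dropout -> logits."""

    def __init__(self, channels: int, cfg: ModelConfig, *, rng,
                 dropout_rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv1d(channels, channels, cfg.head_conv_kernel,
                              cfg.head_conv_stride, rng=rng)
        fin = channels
        for i, h in enumerate(cfg.head_hidden, 1):
            setattr(self, f"fc{i}", nn.Linear(fin, h, rng=rng))
            setattr(self, f"drop{i}", nn.Dropout(cfg.dropout, dropout_rng))
            fin = h
        self.n_hidden = len(cfg.head_hidden)
        self.out = nn.Linear(fin, cfg.n_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = nn.global_avg_pool(self.conv(x))
        for i in range(1, self.n_hidden + 1):
            h = getattr(self, f"drop{i}")(nn.relu(getattr(self, f"fc{i}")(h)))
        return self.out(h)


class FusionNetwork(nn.Module):
    """A buildable variant of the full architecture.

    Input is always (N, 2, L) with ECG on channel 0 and PCG on channel 1;
    single-modality variants select their channel internally, so the
    data pipeline is variant-agnostic.
    """

    def __init__(self, variant: str = "full",
                 config: ModelConfig | None = None,
                 seed: int = 0):
        super().__init__()
        if variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {variant!r}; expected one of {VARIANTS}"
            )
        cfg = config or ModelConfig()
        cfg.validate()
        self.variant = variant
        self.config = cfg
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(seed).spawn(1)[0]
        )
        ch = cfg.channels
        if variant == "early_fusion":
            self.encoder = ModalityEncoder(cfg, in_channels=2, rng=rng)
        elif variant in ("single_ecg", "single_pcg"):
            self.encoder = ModalityEncoder(cfg, rng=rng)
        else:
            self.ecg_encoder = ModalityEncoder(cfg, rng=rng)
            self.pcg_encoder = ModalityEncoder(cfg, rng=rng)
        if variant in ("full", "concat_only", "sa_only", "ca_only"):
            ident_sa = variant in ("concat_only", "ca_only")
            ident_ca = variant in ("concat_only", "sa_only")
            for lvl in range(1, 5):
                c_prev = ch[lvl - 2] if lvl > 1 else None
                setattr(self, f"sacmf{lvl}",
                        SACMF(lvl, ch[lvl - 1], c_prev, cfg, rng=rng,
                              identity_spatial=ident_sa,
                              identity_channel=ident_ca))
        elif variant == "only_last_sacmf":
            self.sacmf4 = SACMF(4, ch[-1], None, cfg, rng=rng)
        elif variant == "late_fusion":
            self.late_bn = nn.BatchNorm1d(2 * ch[-1])
            self.late_conv = nn.Conv1d(2 * ch[-1], ch[-1], cfg.kernel_size, 1,
                                       bias=False, rng=rng)
        self.head = ClassifierHead(ch[-1], cfg, rng=rng,
                                   dropout_rng=self.dropout_rng)

    # -- forward pieces ------------------------------------------------
    def _check_input(self, x: Tensor) -> None:
        if x.ndim != 3 or x.shape[1] != 2 or x.shape[2] != self.config.input_len:
            raise ConfigurationError(
                f"expected input (N, 2, {self.config.input_len}), "
                f"got {tuple(x.shape)}"
            )

    def encode(self, x: Tensor) -> dict[str, list[Tensor]]:
        """Per-branch encoder feature pyramids (exposed for analysis)."""
        self._check_input(x)
        ecg = nn.narrow(x, 1, 0, 1)
        pcg = nn.narrow(x, 1, 1, 1)
        if self.variant == "early_fusion":
            return {"fused_input": self.encoder(x)}
        if self.variant == "single_ecg":
            return {"ecg": self.encoder(ecg)}
        if self.variant == "single_pcg":
            return {"pcg": self.encoder(pcg)}
        return {"ecg": self.ecg_encoder(ecg), "pcg": self.pcg_encoder(pcg)}

    def fuse(self, feats: dict[str, list[Tensor]]) -> Tensor:
        v = self.variant
        if v == "early_fusion":
            return feats["fused_input"][-1]
        if v == "single_ecg":
            return feats["ecg"][-1]
        if v == "single_pcg":
            return feats["pcg"][-1]
        ef, pf = feats["ecg"], feats["pcg"]
        if v == "late_fusion":
            cat = nn.concat([ef[-1], pf[-1]], axis=1)
            return nn.relu(self.late_conv(self.late_bn(cat)))
        if v == "only_last_sacmf":
            return self.sacmf4(ef[-1], pf[-1])
        prev = None
        for lvl in range(1, 5):
            prev = getattr(self, f"sacmf{lvl}")(ef[lvl - 1], pf[lvl - 1], prev)
        return prev

    def forward(self, x: Tensor) -> Tensor:
        """Returns class logits (N, n_classes)."""
        return self.head(self.fuse(self.encode(x)))

    def predict_proba_array(self, X: np.ndarray,
                            batch_size: int = 128) -> np.ndarray:
        """Inference helper: softmax probabilities for a raw array."""
        self.eval()
        out = []
        with nn.no_grad():
            for i in range(0, X.shape[0], batch_size):
                logits = self.forward(nn.astensor(X[i:i + batch_size]))
                out.append(nn.softmax(logits.data))
        return np.concatenate(out, axis=0)

    def set_attention_identity(self, spatial: bool | None = None,
                               channel: bool | None = None) -> None:
        """Force attention branches to identity in every SACMF module."""
        for lvl in range(1, 5):
            mod = getattr(self, f"sacmf{lvl}", None)
            if mod is None:
                continue
            if spatial is not None:
                mod.identity_spatial = spatial
            if channel is not None:
                mod.identity_channel = channel


CHECKPOINT_VERSION = 1


def save_checkpoint(model: FusionNetwork, path) -> None:
    state = model.state_dict()
    np.savez_compressed(
        path,
        __version__=np.int64(CHECKPOINT_VERSION),
        __variant__=np.array(model.variant),
        **state,
    )


def load_checkpoint(model: FusionNetwork, path) -> None:
    from .errors import SchemaVersionError

    with np.load(path, allow_pickle=False) as z:
        if int(z["__version__"]) > CHECKPOINT_VERSION:
            raise SchemaVersionError(f"{path}: checkpoint schema too new")
        if str(z["__variant__"]) != model.variant:
            raise ConfigurationError(
                f"{path}: checkpoint is for variant {z['__variant__']}"
            )
        state = {k: z[k] for k in z.files if not k.startswith("__")}
    model.load_state_dict(state)


def build_model(variant: str, config: ModelConfig | None = None,
                seed: int = 0) -> FusionNetwork:
    """Factory for the nine architecture variants."""
    return FusionNetwork(variant, config, seed)
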