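"""Heart-rate estimation models: ViT backbone + BiLSTM decoders.

Two architectures are provided.  Variant A runs each frame of a window
through the transformer, feeds the final-block class tokens to a BiLSTM,
and regresses a single BPM through a three-layer linear stack.  Variant B
taps the class token at five transformer depths (blocks 0, 3, 6, 9, 11 in
the full-size preset); each tap has its own decoder head (BiLSTM ->
batch norm -> 1D conv -> linear) emitting an interval triple
(min, max, avg) BPM.  Training averages the five triples; inference fuses
the averaged triple into a scalar with weights 0.25 on the interval
midpoint and 0.75 on the average:

    HR = 0.25 * (min + max) / 2 + 0.75 * avg
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .windows import HRTriple

__all__ = [
    "BackboneConfig",
    "HRPrediction",
    "get_preset",
    "scale_taps",
    "ViTBackbone",
    "DecoderHead",
    "VariantA",
    "VariantB",
    "build_model",
    "fuse_hr",
    "FUSION_WEIGHTS",
    "extract_features",
    "save_checkpoint",
    "load_checkpoint",
]

#: Eq-style fusion weights on (min, max, avg); affine, summing to 1
FUSION_WEIGHTS = (0.125, 0.125, 0.75)

#: the five tap depths of the full 12-block backbone
FULL_TAPS = (0, 3, 6, 9, 11)


def scale_taps(depth: int) -> tuple:
    """Rescale the canonical 12-block tap depths {0,3,6,9,11} to ``depth`` blocks."""
    taps = tuple(int(round(i * (depth - 1) / 11)) for i in FULL_TAPS)
    if len(set(taps)) != len(taps) or list(taps) != sorted(taps):
        raise ValueError(f"scaled taps {taps} are not strictly increasing at depth {depth}")
    return taps


@dataclass
class BackboneConfig:
    """Geometry of the backbone and decoder; see ``get_preset``."""

    depth: int = 12
    embed_dim: int = 384
    patch_size: int = 16
    image_size: int = 224
    n_heads: int = 6
    mlp_ratio: float = 4.0
    tap_blocks: tuple = FULL_TAPS
    preset: str = "full"
    lstm_hidden: int = 128       # per direction
    conv_channels: int = 64
    conv_kernel: int = 3
    head_widths: tuple = (256, 64)   # variant A hidden widths before the scalar
    clamp_output: bool = False       # optional inference clamp to [30, 240] BPM

    def __post_init__(self):
        self.tap_blocks = tuple(self.tap_blocks)
        if list(self.tap_blocks) != sorted(set(self.tap_blocks)):
            raise ValueError("tap_blocks must be strictly increasing")
        if any(t >= self.depth for t in self.tap_blocks):
            raise ValueError("every tap block index must be < depth")
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be a multiple of patch_size")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2


PRESETS = {
    # vit_small_patch16_224 geometry with the canonical tap depths
    "full": dict(depth=12, embed_dim=384, patch_size=16, image_size=224,
                  n_heads=6, tap_blocks=FULL_TAPS, lstm_hidden=128,
                  conv_channels=64),
    # CPU-test scale: 64x64 frames, proportionally scaled taps
    "tiny": dict(depth=6, embed_dim=32, patch_size=16, image_size=64,
                 n_heads=2, tap_blocks=scale_taps(6), lstm_hidden=32,
                 conv_channels=16, head_widths=(32, 16)),
}


def get_preset(name: str, **overrides) -> BackboneConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return BackboneConfig(preset=name, **kw)


@dataclass
class HRPrediction:
    """Per-head triples, their mean, and the fused scalar for one window."""

    per_head: list                    # of HRTriple
    mean_triple: HRTriple
    fused_bpm: float


def fuse_hr(triple) -> float:
    """Weighted fusion of an interval triple into one BPM value.

    ``0.25 * (min + max) / 2 + 0.75 * avg`` — affine with coefficients
    (0.125, 0.125, 0.75), hence any equal triple is a fixed point.
    """
    if isinstance(triple, HRTriple):
        mn, mx, av = triple.min_bpm, triple.max_bpm, triple.avg_bpm
    else:
        arr = np.asarray(triple, dtype=float)
        mn, mx, av = arr[..., 0], arr[..., 1], arr[..., 2]
    out = 0.25 * (mn + mx) / 2.0 + 0.75 * av
    return float(out) if np.ndim(out) == 0 else out


def _images_to_patches(images: np.ndarray, patch: int) -> np.ndarray:
    """(B, S, S, 3) -> (B, N, patch*patch*3), row-major patch order."""
    B, H, W, C = images.shape
    gh, gw = H // patch, W // patch
    x = images.reshape(B, gh, patch, gw, patch, C)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return np.ascontiguousarray(x).reshape(B, gh * gw, patch * patch * C)


class ViTBackbone(nn.Module):
    """Frame-wise vision transformer exposing class-token taps."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        D = cfg.embed_dim
        in_dim = cfg.patch_size * cfg.patch_size * 3
        self.patch_embed = nn.Linear(in_dim, D, rng, dtype)
        self.cls_token = nn.Tensor(rng.normal(0, 0.02, (1, 1, D)).astype(dtype), requires_grad=True)
        self.pos_embed = nn.Tensor(rng.normal(0, 0.02, (1, cfg.n_patches + 1, D)).astype(dtype),
                                   requires_grad=True)
        self.blocks = [nn.TransformerBlock(D, cfg.n_heads, cfg.mlp_ratio, rng, dtype)
                       for _ in range(cfg.depth)]
        self.norm = nn.LayerNorm(D, dtype=dtype)

    def forward(self, images: np.ndarray):
        """Run frames through the transformer.

        Returns (taps, final): ``taps`` is a list of class-token Tensors
        (B, D), one per configured tap block; ``final`` is the post-norm
        class token used by variant A.
        """
        cfg = self.cfg
        if images.shape[1] != cfg.image_size or images.shape[2] != cfg.image_size:
            raise ValueError(
                f"frame size {images.shape[1:3]} does not match preset image size {cfg.image_size}")
        patches = _images_to_patches(np.asarray(images, dtype=np.float32), cfg.patch_size)
        x = self.patch_embed(nn.Tensor(patches))
        B = patches.shape[0]
        cls = self.cls_token.broadcast_to((B, 1, cfg.embed_dim))
        x = nn.concatenate([cls, x], axis=1) + self.pos_embed
        taps = []
        for i, block in enumerate(self.blocks):
            x = block(x)
            if i in cfg.tap_blocks:
                taps.append(x[:, 0, :])
        final = self.norm(x)[:, 0, :]
        return taps, final


class DecoderHead(nn.Module):
    """BiLSTM -> batch norm -> 1D conv -> temporal mean-pool -> linear(3).

    Emits an unclamped (min, max, avg) BPM triple for each window in the
    batch.
    """

    def __init__(self, embed_dim: int, cfg: BackboneConfig, rng, dtype=np.float32):
        super().__init__()
        self.bilstm = nn.BiLSTM(embed_dim, cfg.lstm_hidden, rng, dtype)
        self.bn = nn.BatchNorm1d(2 * cfg.lstm_hidden, dtype=dtype)
        self.conv = nn.Conv1dSame(2 * cfg.lstm_hidden, cfg.conv_channels, cfg.conv_kernel, rng, dtype)
        self.out = nn.Linear(cfg.conv_channels, 3, rng, dtype)

    def forward(self, seq: nn.Tensor) -> nn.Tensor:
        x = self.bilstm(seq)           # (B, W, 2H)
        x = self.bn(x)
        x = self.conv(x)               # (B, W, C)
        x = x.mean(axis=1)             # (B, C)
        return self.out(x)             # (B, 3) as (min, max, avg)

    def set_bias_only(self, bias3) -> None:
        """Zero every parameter and set the output bias (degenerate network)."""
        for p in self.parameters():
            p.data = np.zeros_like(p.data)
        self.out.bias.data = np.asarray(bias3, dtype=self.out.bias.data.dtype)
        self.bn.running_mean[:] = 0.0
        self.bn.running_var[:] = 1.0
        self.bn.gamma.data = np.ones_like(self.bn.gamma.data)


class VariantA(nn.Module):
    """Backbone -> BiLSTM -> three linear layers -> scalar BPM."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0, dtype=np.float32):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.backbone = ViTBackbone(cfg, rng, dtype)
        self.bilstm = nn.BiLSTM(cfg.embed_dim, cfg.lstm_hidden, rng, dtype)
        w1, w2 = cfg.head_widths
        self.fc1 = nn.Linear(2 * cfg.lstm_hidden, w1, rng, dtype)
        self.fc2 = nn.Linear(w1, w2, rng, dtype)
        self.fc3 = nn.Linear(w2, 1, rng, dtype)

    def forward(self, windows: np.ndarray) -> nn.Tensor:
        """(B, W, S, S, 3) -> (B,) scalar BPM Tensor."""
        B, W = windows.shape[:2]
        flat = windows.reshape(B * W, *windows.shape[2:])
        _, final = self.backbone(flat)
        seq = final.reshape(B, W, self.cfg.embed_dim)
        x = self.bilstm(seq).mean(axis=1)
        x = self.fc1(x).relu()
        x = self.fc2(x).relu()
        return self.fc3(x).reshape(B)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        self.eval()
        out = self.forward(windows).data.astype(float)
        if self.cfg.clamp_output:
            out = np.clip(out, 30.0, 240.0)
        return out


class VariantB(nn.Module):
    """Backbone with five class-token taps and five interval decoder heads."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0, dtype=np.float32):
        super().__init__()
        if len(cfg.tap_blocks) != 5:
            raise ValueError("variant B requires exactly 5 tap blocks")
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.backbone = ViTBackbone(cfg, rng, dtype)
        self.heads = [DecoderHead(cfg.embed_dim, cfg, rng, dtype) for _ in cfg.tap_blocks]

    def forward(self, windows: np.ndarray):
        """(B, W, S, S, 3) -> (mean_triple (B, 3) Tensor, list of per-head Tensors)."""
        B, W = windows.shape[:2]
        flat = windows.reshape(B * W, *windows.shape[2:])
        taps, _ = self.backbone(flat)
        per_head = []
        for tap, head in zip(taps, self.heads):
            seq = tap.reshape(B, W, self.cfg.embed_dim)
            per_head.append(head(seq))
        mean = per_head[0]
        for h in per_head[1:]:
            mean = mean + h
        mean = mean * (1.0 / len(per_head))
        return mean, per_head

    def predict(self, windows: np.ndarray) -> list:
        """Inference: one HRPrediction per window."""
        self.eval()
        mean, per_head = self.forward(windows)
        mean = mean.data.astype(float)
        heads = [h.data.astype(float) for h in per_head]
        out = []
        for i in range(mean.shape[0]):
            triples = [HRTriple(*h[i]) for h in heads]
            mt = HRTriple(*mean[i])
            fused = fuse_hr(mt)
            if self.cfg.clamp_output:
                fused = float(np.clip(fused, 30.0, 240.0))
            out.append(HRPrediction(per_head=triples, mean_triple=mt, fused_bpm=fused))
        return out

    def predict_fused(self, windows: np.ndarray) -> np.ndarray:
        return np.array([p.fused_bpm for p in self.predict(windows)])


def build_model(cfg: BackboneConfig, variant: str = "B", seed: int = 0):
    if variant.upper() == "A":
        return VariantA(cfg, seed)
    if variant.upper() == "B":
        return VariantB(cfg, seed)
    raise ValueError("variant must be 'A' or 'B'")


def extract_features(window_images: np.ndarray, backbone: ViTBackbone) -> list:
    """Per-tap feature sequences for one window.

    ``window_images`` is (W, S, S, 3); returns a list of (W, embed_dim)
    arrays, one per tap block, each row the class-token embedding of one
    frame (frames pass through the backbone independently).
    """
    taps, _ = backbone(np.asarray(window_images))
    return [t.data.copy() for t in taps]


def save_checkpoint(path, model, variant: str, train_meta: dict | None = None) -> None:
    """Single-file archive: weights + JSON config snapshot."""
    meta = {"variant": variant, "config": asdict(model.cfg), "train": train_meta or {}}
    state = model.state_dict()
    np.savez(path, __meta__=np.array(json.dumps(meta)), **state)


def load_checkpoint(path):
    """Rebuild a model (weights + config) from a checkpoint archive."""
    with np.load(path, allow_pickle=False) as f:
        meta = json.loads(str(f["__meta__"]))
        state = {k: f[k] for k in f.files if k != "__meta__"}
    cfg_kw = meta["config"]
    cfg_kw["tap_blocks"] = tuple(cfg_kw["tap_blocks"])
    cfg_kw["head_widths"] = tuple(cfg_kw["head_widths"])
    cfg = BackboneConfig(**cfg_kw)
    model = build_model(cfg, meta["variant"], seed=0)
    model.load_state_dict(state)
    return model, meta
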