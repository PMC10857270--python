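"""Training and evaluation: MAE loss, RMSE metric, window pipeline, sweeps.

The loss for the single-output model is the MAE between predicted and true
BPM; the interval model averages its five head triples and takes the MAE of
the three components against the window label.  Evaluation reports MAE and
RMSE of the fused scalar against the window-average heart rate.  Splits are
by video, never by window, to avoid leakage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import nn
from .model import BackboneConfig, build_model, get_preset, save_checkpoint
from .roi import add_forehead_points, crop_resize_normalize, mask_face, IMAGENET_MEAN, IMAGENET_STD
from .windows import HRTriple, label_window, make_windows, resample_fps

__all__ = [
    "EvalBatch",
    "TrainConfig",
    "mae",
    "rmse",
    "loss_variant_b",
    "dataset_split_shares",
    "load_video",
    "preprocess_video",
    "build_window_arrays",
    "train",
    "sweep",
]


@dataclass
class EvalBatch:
    """Paired true and predicted BPM values."""

    truths: np.ndarray
    preds: np.ndarray

    def __post_init__(self):
        self.truths = np.asarray(self.truths, dtype=float)
        self.preds = np.asarray(self.preds, dtype=float)
        if self.truths.shape != self.preds.shape or self.truths.size < 1:
            raise ValueError("truths and preds must be non-empty and equal-length")


def mae(truths, preds=None) -> float:
    """Mean absolute error in BPM."""
    b = truths if isinstance(truths, EvalBatch) else EvalBatch(truths, preds)
    return float(np.mean(np.abs(b.truths - b.preds)))


def rmse(truths, preds=None) -> float:
    """Root mean square error in BPM."""
    b = truths if isinstance(truths, EvalBatch) else EvalBatch(truths, preds)
    return float(np.sqrt(np.mean((b.truths - b.preds) ** 2)))


def loss_variant_b(pred_triple, label_triple) -> float:
    """MAE of the three interval components (head-averaged prediction vs label)."""
    p = pred_triple.as_array() if isinstance(pred_triple, HRTriple) else np.asarray(pred_triple, float)
    t = label_triple.as_array() if isinstance(label_triple, HRTriple) else np.asarray(label_triple, float)
    return float(np.mean(np.abs(p - t)))


def dataset_split_shares(counts) -> np.ndarray:
    """Percentage share of each split given per-split video counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 1 or np.any(counts < 0) or counts.sum() == 0:
        raise ValueError("counts must be non-negative with a positive total")
    return 100.0 * counts / counts.sum()


@dataclass
class TrainConfig:
    """Hyper-parameters for one training run.

    Variant B trains in two phases: the five decoder heads are first fitted
    on cached backbone features (``head_steps`` minibatch steps at
    ``head_batch``), then the whole model is fine-tuned end to end for
    ``epochs`` epochs at ``learning_rate / 10``.  ``head_steps=0`` disables
    the staged phase; variant A always trains end to end.
    """

    learning_rate: float = 3e-3
    batch_size: int = 32
    epochs: int = 10
    seed: int = 0
    variant: str = "B"
    window_length: int = 15
    stride: int = None                 # defaults to window_length
    preset: str = "tiny"
    target_fps: float = None           # down-sample sources to this rate
    val_fraction: float = 0.2
    normalize: str = "imagenet"        # or "identity"
    head_steps: int = 6000             # phase-1 decoder-head steps (variant B)
    head_batch: int = 32
    head_log_every: int = 500          # steps between phase-1 metric rows
    lr_grid: tuple = field(default=(1e-5, 1e-4, 1e-3))
    batch_grid: tuple = field(default=(2, 4, 8))

    def __post_init__(self):
        if self.learning_rate != 0.0 and not (1e-6 <= self.learning_rate <= 1e-1):
            # 0 is allowed as the degenerate no-update case
            raise ValueError("learning_rate must be 0 or lie in [1e-6, 1e-1]")
        if self.stride is None:
            self.stride = self.window_length
        if self.epochs < 1 or self.batch_size < 1 or self.window_length < 1:
            raise ValueError("epochs, batch_size and window_length must be >= 1")


def _norm_constants(name: str):
    if name == "imagenet":
        return IMAGENET_MEAN, IMAGENET_STD
    if name == "identity":
        return (0.0, 0.0, 0.0), (1.0, 1.0, 1.0)
    raise ValueError("normalize must be 'imagenet' or 'identity'")


def load_video(entry: dict):
    """Load one manifest entry -> (frames uint8 (N,H,W,3), landmarks (N,68,2), hr_rows)."""
    vdir = Path(entry["video_dir"])
    paths = sorted(vdir.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frames in {vdir}")
    frames = np.stack([iio.imread(p) for p in paths])
    lm = pd.read_csv(entry["landmarks_csv"])
    n_pts = lm["point_id"].nunique()
    landmarks = (lm.sort_values(["frame", "point_id"])[["x", "y"]]
                 .to_numpy().reshape(len(paths), n_pts, 2))
    hr_rows = pd.read_csv(entry["hr_csv"])[["time_s", "bpm"]].to_numpy()
    return frames, landmarks, hr_rows


def preprocess_video(frames, landmarks, fps: float, image_size: int,
                     mean, std, target_fps: float = None) -> list:
    """Mask, crop, resize and normalize every frame; returns ProcessedFrames."""
    if target_fps is not None and target_fps < fps:
        keep = resample_fps(np.arange(len(frames)) / fps, fps, target_fps)
        frames, landmarks = frames[keep], landmarks[keep]
        timestamps = keep / fps
    else:
        timestamps = np.arange(len(frames)) / fps
    out = []
    for frame, lm68, t in zip(frames, landmarks, timestamps):
        lms = add_forehead_points(lm68)
        masked = mask_face(frame, lms)
        out.append(crop_resize_normalize(masked, size=image_size, mean=mean, std=std, timestamp=t))
    return out


def build_window_arrays(manifest_path, cfg: TrainConfig, bb_cfg: BackboneConfig):
    """Manifest -> (X (n, W, S, S, 3) float32, y (n, 3), video_ids (n,))."""
    entries = json.loads(Path(manifest_path).read_text())
    mean, std = _norm_constants(cfg.normalize)
    X, y, vids = [], [], []
    for vid, entry in enumerate(entries):
        frames, landmarks, hr_rows = load_video(entry)
        processed = preprocess_video(frames, landmarks, entry["fps"], bb_cfg.image_size,
                                     mean, std, cfg.target_fps)
        for win in make_windows(processed, W=cfg.window_length, stride=cfg.stride):
            X.append(win.images)
            y.append(label_window(win, hr_rows).as_array())
            vids.append(vid)
    if not X:
        raise ValueError("manifest produced no windows")
    return (np.stack(X).astype(np.float32), np.stack(y), np.asarray(vids))


def _split_by_video(video_ids: np.ndarray, val_fraction: float, rng: np.random.Generator):
    vids = np.unique(video_ids)
    perm = rng.permutation(vids)
    n_val = max(1, int(round(len(vids) * val_fraction)))
    val_vids = set(perm[:n_val].tolist())
    val_mask = np.isin(video_ids, list(val_vids))
    if val_mask.all() or not val_mask.any():
        raise ValueError("need at least one training and one validation video")
    return ~val_mask, val_mask


def _batch_loss(model, xb: np.ndarray, yb: np.ndarray, variant: str) -> nn.Tensor:
    if variant.upper() == "B":
        mean_triple, _ = model.forward(xb)
        diff = mean_triple - nn.Tensor(yb.astype(mean_triple.data.dtype))
        return diff.abs().mean()
    pred = model.forward(xb)
    truth = nn.Tensor(yb[:, 2].astype(pred.data.dtype))   # window-average HR
    return (pred - truth).abs().mean()


def _validate(model, X: np.ndarray, y: np.ndarray, variant: str, batch: int = 16):
    model.eval()
    preds = []
    for i in range(0, len(X), batch):
        xb = X[i:i + batch]
        if variant.upper() == "B":
            preds.append(model.predict_fused(xb))
        else:
            preds.append(model.predict(xb))
    preds = np.concatenate(preds)
    truths = y[:, 2]
    return mae(truths, preds), rmse(truths, preds), preds


def _cache_tap_features(model, X: np.ndarray, batch: int = 16) -> list:
    """Frozen-backbone class-token sequences per tap: 5 x (n, W, D) arrays."""
    n, W = X.shape[:2]
    taps_all = None
    for i in range(0, n, batch):
        taps, _ = model.backbone(X[i:i + batch].reshape(-1, *X.shape[2:]))
        if taps_all is None:
            taps_all = [[] for _ in taps]
        for k, t in enumerate(taps):
            taps_all[k].append(t.data.reshape(-1, W, t.data.shape[-1]).astype(np.float32))
    return [np.concatenate(chunks) for chunks in taps_all]


def _heads_fused(model, feats: list) -> np.ndarray:
    """Fused BPM from cached features (heads in their current mode)."""
    outs = [h(nn.Tensor(f)).data for h, f in zip(model.heads, feats)]
    mean = np.mean(outs, axis=0)
    return 0.25 * (mean[:, 0] + mean[:, 1]) / 2.0 + 0.75 * mean[:, 2]


def _train_heads_on_cached_features(model, Xtr, ytr, Xval, yval, cfg, rng, log_rows, best):
    """Phase 1: fit the five decoder heads on frozen-backbone features."""
    Ftr = _cache_tap_features(model, Xtr)
    Fval = _cache_tap_features(model, Xval)
    params = [p for h in model.heads for p in h.parameters()]
    opt = nn.Adam(params, lr=cfg.learning_rate)
    ytr32 = ytr.astype(np.float32)
    losses = []
    for step in range(1, cfg.head_steps + 1):
        for h in model.heads:
            h.train()
        idx = rng.integers(0, len(ytr32), cfg.head_batch)
        outs = [h(nn.Tensor(f[idx])) for h, f in zip(model.heads, Ftr)]
        mean = outs[0]
        for o in outs[1:]:
            mean = mean + o
        mean = mean * (1.0 / len(outs))
        loss = (mean - nn.Tensor(ytr32[idx])).abs().mean()
        if not np.isfinite(loss.data):
            raise RuntimeError(f"NaN/inf loss at head step {step}; try a lower learning rate")
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
        if step % cfg.head_log_every == 0 or step == cfg.head_steps:
            for h in model.heads:
                h.eval()
            preds = _heads_fused(model, Fval)
            val_mae = mae(yval[:, 2], preds)
            val_rmse = rmse(yval[:, 2], preds)
            log_rows.append({"epoch": len(log_rows), "train_loss": float(np.mean(losses)),
                             "val_mae": val_mae, "val_rmse": val_rmse})
            losses = []
            if val_mae < best["val_mae"]:
                best.update(val_mae=val_mae, state=model.state_dict(), epoch=len(log_rows) - 1)


def train(manifest_path, cfg: TrainConfig, out_dir, data=None):
    """Train one model from a manifest; returns (checkpoint_path, metrics log).

    Seeded and deterministic: the same config and seed reproduce the metric
    log bit-for-bit.  Variant B first fits its decoder heads on cached
    backbone features (rows of the metric log every ``head_log_every``
    steps), then fine-tunes end to end at ``learning_rate / 10``; the log's
    ``epoch`` column simply numbers the rows.  The best-validation-MAE
    checkpoint is kept.  ``data`` may carry precomputed ``(X, y, video_ids)``
    to skip re-reading the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bb_cfg = get_preset(cfg.preset)
    X, y, vids = data if data is not None else build_window_arrays(manifest_path, cfg, bb_cfg)
    rng = np.random.default_rng(cfg.seed)
    tr_mask, val_mask = _split_by_video(vids, cfg.val_fraction, rng)
    Xtr, ytr = X[tr_mask], y[tr_mask]
    Xval, yval = X[val_mask], y[val_mask]

    model = build_model(bb_cfg, cfg.variant, seed=cfg.seed)
    log_rows = []
    best = {"val_mae": np.inf, "state": None, "epoch": -1}
    # learning rate 0 is a dry run: nothing may change, including norm stats
    frozen = cfg.learning_rate == 0.0

    staged = cfg.variant.upper() == "B" and cfg.head_steps > 0 and not frozen
    if staged:
        _train_heads_on_cached_features(model, Xtr, ytr, Xval, yval, cfg, rng, log_rows, best)

    ft_lr = cfg.learning_rate / 10.0 if staged else cfg.learning_rate
    opt = nn.Adam(model.parameters(), lr=ft_lr)
    n = len(Xtr)
    for epoch in range(cfg.epochs):
        model.eval() if frozen else model.train()
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            loss = _batch_loss(model, Xtr[idx], ytr[idx], cfg.variant)
            if not np.isfinite(loss.data):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}; try a lower learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_mae, val_rmse, _ = _validate(model, Xval, yval, cfg.variant)
        log_rows.append({"epoch": len(log_rows), "train_loss": float(np.mean(losses)),
                         "val_mae": val_mae, "val_rmse": val_rmse})
        if val_mae < best["val_mae"]:
            best.update(val_mae=val_mae, state=model.state_dict(), epoch=len(log_rows) - 1)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    ckpt = out_dir / "checkpoint.npz"
    save_checkpoint(ckpt, model, cfg.variant,
                    {"best_epoch": best["epoch"], "best_val_mae": best["val_mae"],
                     "seed": cfg.seed, "preset": cfg.preset})
    log = pd.DataFrame(log_rows)
    log.to_csv(out_dir / "metrics.csv", index=False)
    return ckpt, log


def sweep(manifest_path, grid, cfg: TrainConfig, out_dir, param: str = "window_length"):
    """Train one model per grid setting under a shared seed; CSV (setting, mae, rmse)."""
    if not grid:
        raise ValueError("grid must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for setting in grid:
        run_cfg = TrainConfig(**{**vars(cfg), param: setting,
                                 "stride": setting if param == "window_length" else cfg.stride})
        _, log = train(manifest_path, run_cfg, out_dir / f"{param}_{setting}")
        best = log.loc[log["val_mae"].idxmin()]
        rows.append({"setting": setting, "mae": best["val_mae"], "rmse": best["val_rmse"]})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "sweep.csv", index=False)
    return table
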