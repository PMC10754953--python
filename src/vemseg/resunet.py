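"""Residual U-Net for semantic segmentation of vEM slices.

The network maps a single-channel tile to per-pixel foreground
probabilities.  Pre-activation residual blocks (batch norm -> ReLU -> 3x3
conv, twice, plus a shortcut) form a four-level encoder whose first
convolution in each block is strided, halving the spatial size while
doubling the feature count; a bridge block sits at 1/16 resolution; the
decoder mirrors the encoder with nearest-neighbor upsampling followed by a
2x2 convolution that halves the feature count and concatenation with the
matching encoder feature map.  A 1x1 convolution with sigmoid produces the
output heads — one for organelle masks, or two (interior mask + boundary)
for the cell task.

Training minimizes the soft-Dice loss with Adam (lr 1e-4, beta1 0.9,
beta2 0.999, eps 1e-7) on batches of five 512x512 tiles; a nucleolus-aware
sampler guarantees that at least four of the five tiles contain at least
100 nucleolus pixels, compensating for how sparse nucleoli are (<1% of a
full image).  Horizontal/vertical flips are applied independently per tile.
Tiles may optionally be cropped at a larger context size (2048 px) and
downsampled to the network input size, trading resolution for context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from vemseg import nn
from vemseg.nn.tensor import Tensor, concat_channels, relu, sigmoid, upsample2x
from vemseg.stack_io import SparseLabelSet, boundary_map_from_labels, interior_map_from_labels

__all__ = [
    "ModelSpec", "TrainConfig", "ResUNet", "build_model", "dice_loss",
    "sample_batch", "train", "save_checkpoint", "load_checkpoint",
]


@dataclass
class ModelSpec:
    """Architecture hyperparameters.

    ``base_filters`` sets the width of the first encoder level; each level
    doubles it.  ``in_size`` must be divisible by 16 (four 2x downsamplings
    to the bridge).  ``heads`` is 1 for organelles, 2 for cell mask+boundary.
    """

    base_filters: int = 32
    in_size: tuple = (512, 512)
    heads: int = 1

    def validate(self):
        if any(s % 16 != 0 for s in self.in_size):
            raise ValueError(f"in_size {self.in_size} must be divisible by 16")
        if self.base_filters < 1 or self.heads < 1:
            raise ValueError("base_filters and heads must be positive")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    updates: int = 5000
    batch_size: int = 5
    tile_px: int = 512
    context_px: int = 512       # 2048 crops downsampled to tile_px add context
    nucleolus_min_px: int = 100
    nucleolus_min_tiles: int = 4
    augment: bool = True        # horizontal + vertical flips
    boundary_thickness_px: int = 3
    seed: int = 0

    def validate(self):
        for k in ("learning_rate", "batch_size", "tile_px", "context_px"):
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be positive")
        if self.updates < 0:
            raise ValueError("updates must be >= 0")
        if self.nucleolus_min_tiles > self.batch_size:
            raise ValueError("nucleolus_min_tiles must be <= batch_size")
        if self.context_px % self.tile_px != 0:
            raise ValueError("context_px must be a multiple of tile_px")


class _ResBlock(nn.Module):
    """Pre-activation residual block; strided first conv downsamples."""

    def __init__(self, cin, cout, stride=1, rng=None):
        self.bn1 = nn.BatchNorm2d(cin)
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng=rng)
        if stride != 1 or cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
        else:
            self.proj = None

    def __call__(self, x):
        h = self.conv1(relu(self.bn1(x)))
        h = self.conv2(relu(self.bn2(h)))
        shortcut = self.proj(x) if self.proj is not None else x
        return h + shortcut


class _UpStep(nn.Module):
    """Nearest-neighbor 2x upsampling then a 2x2 conv halving the features."""

    def __init__(self, cin, rng=None):
        self.conv = nn.Conv2d(cin, cin // 2, 2, rng=rng)

    def __call__(self, x):
        return self.conv(upsample2x(x))


class ResUNet(nn.Module):
    def __init__(self, spec: ModelSpec, rng=None):
        spec.validate()
        rng = rng or np.random.default_rng(0)
        b = spec.base_filters
        self.spec = spec
        self.enc = [
            _ResBlock(1, b, stride=2, rng=rng),
            _ResBlock(b, 2 * b, stride=2, rng=rng),
            _ResBlock(2 * b, 4 * b, stride=2, rng=rng),
            _ResBlock(4 * b, 8 * b, stride=2, rng=rng),
        ]
        self.bridge = _ResBlock(8 * b, 16 * b, stride=1, rng=rng)
        self.up = [
            _UpStep(16 * b, rng=rng),
            _UpStep(8 * b, rng=rng),
            _UpStep(4 * b, rng=rng),
            _UpStep(2 * b, rng=rng),
        ]
        self.dec = [
            _ResBlock(8 * b + 4 * b, 8 * b, rng=rng),
            _ResBlock(4 * b + 2 * b, 4 * b, rng=rng),
            _ResBlock(2 * b + b, 2 * b, rng=rng),
            _ResBlock(b + 1, b, rng=rng),
        ]
        self.head = nn.Conv2d(b, spec.heads, 1, rng=rng)
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        e1 = self.enc[0](x)
        e2 = self.enc[1](e1)
        e3 = self.enc[2](e2)
        e4 = self.enc[3](e3)
        br = self.bridge(e4)
        d = self.dec[0](concat_channels(self.up[0](br), e3))
        d = self.dec[1](concat_channels(self.up[1](d), e2))
        d = self.dec[2](concat_channels(self.up[2](d), e1))
        d = self.dec[3](concat_channels(self.up[3](d), x))
        return sigmoid(self.head(d))

    def bridge_features(self, x: Tensor) -> Tensor:
        e = x
        for blk in self.enc:
            e = blk(e)
        return self.bridge(e)

    def predict(self, tiles: np.ndarray) -> np.ndarray:
        """Eval-mode forward on a (N, H, W) or (H, W) array of tiles."""
        arr = np.asarray(tiles, dtype=np.float32)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        self.set_training(False)
        out = self.forward(Tensor(arr[:, None] / 255.0)).data
        self.set_training(True)
        return out[0] if single else out

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_model(spec: ModelSpec, seed: int = 0) -> ResUNet:
    """Construct a ResUNet with He-initialized weights fixed by ``seed``."""
    return ResUNet(spec, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# loss

DICE_SMOOTH = 1.0  # numerator/denominator smoothing of the soft Dice


def dice_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """1 - soft Dice with the squared-denominator form.

    soft Dice = (2 Σ p·g + ε) / (Σ p² + Σ g² + ε); with binary p = g the
    loss vanishes (up to ε), with p = 1-g it approaches 1.
    """
    t = np.asarray(target, dtype=np.float32)
    inter = (pred * t).sum()
    denom = pred.square().sum() + float((t ** 2).sum())
    soft = (2.0 * inter + DICE_SMOOTH) / (denom + DICE_SMOOTH)
    return 1.0 - soft


# ---------------------------------------------------------------------------
# batch sampling

def _downsample_tile(tile: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return tile
    h, w = tile.shape
    return tile.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def _downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return mask
    return mask[::factor, ::factor]


def sample_batch(images: np.ndarray, labels: SparseLabelSet, cfg: TrainConfig, rng,
                 dual_head: bool = False):
    """Draw one training batch of (tile, target) pairs from labeled slices.

    Returns (tiles, targets): tiles (B, 1, t, t) in [0,1], targets
    (B, heads, t, t) binary.  For the nucleolus class at least
    ``nucleolus_min_tiles`` of the batch tiles contain at least
    ``nucleolus_min_px`` foreground pixels; sampling retries are bounded and
    exhaustion raises with a hint to lower nucleolus_min_px.
    """
    cfg.validate()
    if not labels.slice_indices:
        raise ValueError("empty label set")
    ctx = cfg.context_px
    factor = ctx // cfg.tile_px
    H, W = images.shape[1:]
    pad_h, pad_w = max(0, ctx - H), max(0, ctx - W)

    def grab(constrained: bool):
        for _ in range(500):
            z = labels.slice_indices[rng.integers(len(labels.slice_indices))]
            img = images[z]
            lab = labels.labels[z]
            if pad_h or pad_w:
                img = np.pad(img, ((0, pad_h), (0, pad_w)), mode="reflect")
                lab = np.pad(lab, ((0, pad_h), (0, pad_w)), mode="reflect")
            r = rng.integers(img.shape[0] - ctx + 1)
            c = rng.integers(img.shape[1] - ctx + 1)
            tile = img[r:r + ctx, c:c + ctx].astype(np.float32)
            crop = lab[r:r + ctx, c:c + ctx]
            if constrained and int((crop > 0).sum()) < cfg.nucleolus_min_px:
                continue
            return tile, crop
        raise RuntimeError(
            "could not sample a tile meeting the nucleolus pixel constraint; "
            "try a smaller nucleolus_min_px")

    tiles, targets = [], []
    for i in range(cfg.batch_size):
        constrained = labels.class_name == "nucleolus" and i < cfg.nucleolus_min_tiles
        tile, crop = grab(constrained)
        tile = _downsample_tile(tile, factor) / 255.0
        if dual_head:
            tgt = np.stack([
                interior_map_from_labels(crop, cfg.boundary_thickness_px),
                boundary_map_from_labels(crop, cfg.boundary_thickness_px),
            ]).astype(np.float32)
            tgt = tgt[:, ::factor, ::factor]
        else:
            tgt = (_downsample_mask(crop, factor) > 0).astype(np.float32)[None]
        if cfg.augment:
            if rng.random() < 0.5:
                tile, tgt = tile[::-1], tgt[:, ::-1]
            if rng.random() < 0.5:
                tile, tgt = tile[:, ::-1], tgt[:, :, ::-1]
        tiles.append(tile.copy())
        targets.append(tgt.copy())
    return np.stack(tiles)[:, None], np.stack(targets)


# ---------------------------------------------------------------------------
# training

def train(model: ResUNet, images: np.ndarray, labels: SparseLabelSet, cfg: TrainConfig,
          progress=None):
    """Run exactly ``cfg.updates`` Adam weight updates of the Dice loss.

    Returns (model, trace) where trace = {"raw": [...], "smoothed": [...]}
    (exponential moving average).  A NaN loss aborts with a diagnostic of
    the offending batch.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1,
                  beta2=cfg.beta2, eps=cfg.epsilon)
    dual = model.spec.heads == 2
    raw, smoothed = [], []
    ema = None
    model.set_training(True)
    for step in range(cfg.updates):
        tiles, targets = sample_batch(images, labels, cfg, rng, dual_head=dual)
        pred = model.forward(Tensor(tiles))
        if dual:
            # mask and boundary heads contribute equally
            loss = dice_loss(_slice_head(pred, 0), targets[:, 0:1]) + \
                dice_loss(_slice_head(pred, 1), targets[:, 1:2])
        else:
            loss = dice_loss(pred, targets)
        val = float(loss.data)
        if not np.isfinite(val):
            raise RuntimeError(
                f"NaN/inf loss at update {step}; batch slice indices unknown, "
                f"tile stats: min={tiles.min():.3f} max={tiles.max():.3f}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        raw.append(val)
        ema = val if ema is None else 0.98 * ema + 0.02 * val
        smoothed.append(ema)
        if progress is not None:
            progress(step, val)
    return model, {"raw": raw, "smoothed": smoothed}


def _slice_head(pred: Tensor, h: int) -> Tensor:
    out = Tensor(pred.data[:, h:h + 1], parents=(pred,))

    def back(g):
        full = np.zeros_like(pred.data)
        full[:, h:h + 1] = g
        pred._accum(full)

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: ResUNet, path, train_config: TrainConfig | None = None):
    """Serialize weights + ModelSpec (+TrainConfig) to an .npz; bit-exact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"spec": {**asdict(model.spec), "in_size": list(model.spec.in_size)}}
    if train_config is not None:
        meta["train_config"] = asdict(train_config)
    state = model.named_state()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> ResUNet:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec_d = meta["spec"]
        spec = ModelSpec(base_filters=spec_d["base_filters"],
                         in_size=tuple(spec_d["in_size"]), heads=spec_d["heads"])
        model = build_model(spec)
        model.load_state({k: data[k] for k in data.files if k != "__meta__"})
    return model
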