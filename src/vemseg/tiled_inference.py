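"""Full-image prediction by overlapping tiles with tapered-cosine blending.

EM images are far larger than the network input, so each slice is parsed
into overlapping tiles; each tile's probability map is multiplied by a 2D
tapered cosine (Tukey) window and accumulated, which suppresses the step
artifact at tile borders.  The accumulated sum is divided by the
accumulated window weight so that a constant field is reproduced exactly
(partition of unity after normalization).  The final map is thresholded at
0.5, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import tukey

__all__ = [
    "TileGrid", "ProbabilityMap", "plan_tiles", "tapered_cosine_window",
    "predict_full_image", "predict_stack", "threshold_map",
]

_WEIGHT_FLOOR = 1e-3  # keeps edge/corner pixels covered when alpha -> 1


@dataclass
class TileGrid:
    tile_px: int
    stride_px: int
    origins: list            # (row, col) corners, in padded-image coordinates
    pad: tuple               # (top/left, bottom/right reflect padding applied)
    image_shape: tuple

    def __post_init__(self):
        if self.stride_px >= self.tile_px:
            raise ValueError("stride must be smaller than tile (tiles must overlap)")


@dataclass
class ProbabilityMap:
    values: np.ndarray       # [0,1] per pixel
    weight: np.ndarray       # accumulated window weight (pre-normalization)


def plan_tiles(image_shape, tile_px: int, overlap_px: int) -> TileGrid:
    """Grid of tile origins covering the image.

    Tiles step by ``tile_px - overlap_px`` and the last tile along each axis
    is aligned to the far edge so every pixel is covered; images smaller
    than a tile are reflect-padded up to tile size (single tile).
    """
    if not 0 < overlap_px < tile_px:
        raise ValueError("overlap must satisfy 0 < overlap < tile")
    h, w = image_shape
    pad_h = max(0, tile_px - h)
    pad_w = max(0, tile_px - w)
    ph, pw = h + pad_h, w + pad_w
    stride = tile_px - overlap_px

    def axis_origins(size):
        if size == tile_px:
            return [0]
        pos = list(range(0, size - tile_px + 1, stride))
        if pos[-1] != size - tile_px:
            pos.append(size - tile_px)
        return pos

    origins = [(r, c) for r in axis_origins(ph) for c in axis_origins(pw)]
    return TileGrid(tile_px=tile_px, stride_px=stride, origins=origins,
                    pad=(pad_h, pad_w), image_shape=(h, w))


def tapered_cosine_window(tile_px: int, alpha: float) -> np.ndarray:
    """Separable 2D Tukey window; alpha=0 is rectangular, alpha=1 is Hann."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    w1 = tukey(tile_px, alpha).astype(np.float64)
    return np.outer(w1, w1)


def predict_full_image(predict_tile, image: np.ndarray, grid: TileGrid,
                       window: np.ndarray) -> ProbabilityMap:
    """Blend per-tile predictions into one probability map.

    ``predict_tile`` maps a (tile, tile) float image to a same-shape
    probability array (or a (heads, tile, tile) stack).  Per-pixel output is
    Σ(window·tile_prob)/Σ(window) over all covering tiles; a model emitting
    a constant c therefore yields exactly c everywhere.
    """
    h, w = grid.image_shape
    pad_h, pad_w = grid.pad
    img = np.pad(image, ((0, pad_h), (0, pad_w)), mode="reflect") if (pad_h or pad_w) else image
    wfl = np.maximum(window, _WEIGHT_FLOOR)
    t = grid.tile_px
    acc = None
    wacc = np.zeros(img.shape, dtype=np.float64)
    for (r, c) in grid.origins:
        pred = np.asarray(predict_tile(img[r:r + t, c:c + t]), dtype=np.float64)
        if pred.ndim == 2:
            pred = pred[None]
        if acc is None:
            acc = np.zeros((pred.shape[0],) + img.shape, dtype=np.float64)
        acc[:, r:r + t, c:c + t] += pred * wfl
        wacc[r:r + t, c:c + t] += wfl
    if acc is None or not (wacc > 0).all():
        raise RuntimeError("tile grid left pixels uncovered (grid bug)")
    values = (acc / wacc)[:, :h, :w]
    if values.shape[0] == 1:
        values = values[0]
    return ProbabilityMap(values=values, weight=wacc[:h, :w])


def threshold_map(prob, t: float = 0.5) -> np.ndarray:
    """Foreground mask (prob >= t); the 0.5 threshold is inclusive."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    values = prob.values if isinstance(prob, ProbabilityMap) else np.asarray(prob)
    return (values >= t).astype(np.uint8)


def predict_stack(model, voxels: np.ndarray, tile_px: int = 512, overlap_px: int = 256,
                  alpha: float = 0.5, context_px: int | None = None) -> np.ndarray:
    """Per-slice tiled inference of a trained network over a whole stack.

    With ``context_px`` set (e.g. 2048 for a 512 network input), tiles are
    taken at the context size, mean-pool downsampled to the network input,
    and the predicted probabilities are bilinearly upsampled back before
    blending.  Returns float32 probabilities shaped like ``voxels`` (with a
    leading head axis when the model has several heads).
    """
    from scipy.ndimage import zoom

    ctx = context_px or tile_px
    factor = ctx // tile_px
    grid = plan_tiles(voxels.shape[1:], ctx, overlap_px * factor)
    window = tapered_cosine_window(ctx, alpha)
    heads = model.spec.heads

    def predict_tile(tile):
        t8 = tile.astype(np.float32)
        if factor > 1:
            h, w = t8.shape
            t8 = t8.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))
        p = model.predict(t8)  # (heads, tile, tile)
        if factor > 1:
            p = np.stack([zoom(p[c], factor, order=1) for c in range(heads)])
        return p

    out = np.empty((heads, *voxels.shape), dtype=np.float32)
    for z in range(voxels.shape[0]):
        pm = predict_full_image(predict_tile, voxels[z], grid, window)
        vals = pm.values if pm.values.ndim == 3 else pm.values[None]
        out[:, z] = vals
    return out[0] if heads == 1 else out
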