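"""Stack input/output, per-slice histogram equalization, and label targets.

Volumes follow the (slice, row, col) axis convention, 0-based, throughout the
package.  Images are 8-bit grayscale; label volumes are uint16 with 0
reserved for background.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "ImageStack",
    "SparseLabelSet",
    "read_stack",
    "write_stack",
    "equalize_stack",
    "boundary_map_from_labels",
    "interior_map_from_labels",
]

ORGANELLE_CLASSES = ("cell", "nucleus", "nucleolus", "mitochondrion", "endosome", "lysosome")


@dataclass
class ImageStack:
    """3D grayscale volume with voxel-size metadata.

    ``voxels`` is indexed (slice, row, col); FIB-SEM acquisition yields
    isotropic voxels, so a single ``voxel_size_nm`` suffices.
    """

    voxels: np.ndarray
    voxel_size_nm: float = 1.0
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("voxels must be a non-empty 3D array (slice, row, col)")
        self.voxels = v

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class SparseLabelSet:
    """Per-slice integer label images on a sparse subset of slice indices."""

    slice_indices: list
    labels: dict  # slice index -> 2D uint16 label image
    class_name: str = "cell"

    def __post_init__(self):
        self.slice_indices = sorted(set(int(i) for i in self.slice_indices))
        if self.class_name not in ORGANELLE_CLASSES:
            raise ValueError(f"unknown class {self.class_name!r}")
        shapes = {self.labels[i].shape for i in self.slice_indices}
        if len(shapes) > 1:
            raise ValueError("label images differ in shape")


def read_stack(path, voxel_size_nm: float = 1.0) -> ImageStack:
    """Read a multi-page TIFF or a directory of equally sized 2D slices.

    Directory entries are taken in lexical order; mixed sizes raise a format
    error naming the offending file.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff", ".png"})
        if not files:
            raise ValueError(f"no TIFF/PNG slices in {path}")
        slices = []
        shape = None
        for f in files:
            img = np.asarray(iio.imread(f))
            if img.ndim == 3:  # RGB(A) PNG: keep first channel
                img = img[..., 0]
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(f"slice size mismatch: {f.name} has {img.shape}, expected {shape}")
            slices.append(img)
        voxels = np.stack(slices)
    else:
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:
            voxels = voxels[None]
    return ImageStack(voxels=voxels, voxel_size_nm=voxel_size_nm, provenance=[str(path)])


def write_stack(stack, path) -> None:
    """Write a stack (ImageStack or bare array) as a multi-page TIFF."""
    voxels = stack.voxels if isinstance(stack, ImageStack) else np.asarray(stack)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, voxels, photometric='minisblack')
    if isinstance(stack, ImageStack):
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({
            "voxel_size_nm": stack.voxel_size_nm,
            "provenance": [str(p) for p in stack.provenance],
        }))


def _equalize_slice(img: np.ndarray) -> np.ndarray:
    """Classic 256-bin global histogram equalization of one 8-bit slice."""
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist).astype(np.float64)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    total = cdf[-1]
    if total == cdf_min:  # constant slice
        return img
    lut = np.round(255.0 * (cdf - cdf_min) / (total - cdf_min)).astype(np.uint8)
    return lut[img]


def equalize_stack(stack: ImageStack) -> ImageStack:
    """Equalize each slice's histogram to suppress inter-slice brightness drift.

    FIB-SEM stacks intermittently change brightness between milling cycles;
    per-slice global equalization maps shifted copies of the same scene to
    the same output, restoring consistency along z.  Constant slices are
    passed through unchanged with a warning.
    """
    voxels = np.asarray(stack.voxels)
    if voxels.dtype != np.uint8:
        raise ValueError("equalize_stack expects an 8-bit stack")
    out = np.empty_like(voxels)
    for z in range(voxels.shape[0]):
        sl = voxels[z]
        if sl.min() == sl.max():
            warnings.warn(f"slice {z} is constant; passed through unchanged")
            out[z] = sl
        else:
            out[z] = _equalize_slice(sl)
    return ImageStack(out, stack.voxel_size_nm, stack.provenance + ["equalized"])


def boundary_map_from_labels(labels: np.ndarray, thickness_px: int = 3) -> np.ndarray:
    """Binary boundary target: labeled pixels near an inter-label or
    label/background transition.

    A labeled pixel is boundary if any pixel within Chebyshev distance
    ``thickness_px`` carries a different value.  Background pixels are never
    boundary, so the interior mask (labels>0 minus boundary) and the boundary
    are disjoint by construction.
    """
    if thickness_px < 1:
        raise ValueError("thickness_px must be >= 1")
    lab = np.asarray(labels)
    size = 2 * thickness_px + 1
    mx = ndi.maximum_filter(lab, size=size, mode="nearest")
    mn = ndi.minimum_filter(lab, size=size, mode="nearest")
    return ((lab > 0) & ((mx != lab) | (mn != lab))).astype(np.uint8)


def interior_map_from_labels(labels: np.ndarray, thickness_px: int = 3) -> np.ndarray:
    """Interior mask target: labels>0 minus the boundary band."""
    lab = np.asarray(labels)
    b = boundary_map_from_labels(lab, thickness_px)
    return ((lab > 0) & (b == 0)).astype(np.uint8)
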