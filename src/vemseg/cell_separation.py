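"""Separation of touching cells by fusing network and optical-flow boundaries.

Tumor cells in FIB-SEM tissue often share membranes the network cannot see,
so the semantic segmentation merges neighbors into one blob.  Cell labels
are therefore propagated from the nearest manually annotated slice with
dense optical flow, and the propagated inter-cell boundaries are combined
with the network's own boundary prediction in one of three ways before a
seeded watershed splits the interior mask:

* OVERLAY — burn all propagated boundaries onto the network mask;
* SELECTIVE — keep the network boundary and add propagated boundaries only
  inside mask components that contain two or more distinct propagated
  labels (i.e. regions where cells actually overlap);
* FRAME_CHAINED — as SELECTIVE, but each slice's propagated labels come
  from the previous slice's final fused segmentation, so the boundary
  estimate is continually re-anchored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from vemseg._farneback import farneback_flow_pair
from vemseg.stack_io import SparseLabelSet, boundary_map_from_labels

__all__ = [
    "FlowParams", "FlowField", "FusionMethod", "farneback_flow", "warp_labels",
    "fuse_boundaries", "watershed_cells", "separate_stack",
]

MIN_OVERLAP_LABEL_PX = 50   # a propagated label counts toward "overlapping cells" above this size
SEED_SNAP_RADIUS_PX = 50.0


@dataclass
class FlowParams:
    """Farneback parameter set; the defaults are the ones that work well on
    FIB-SEM stacks (pyramid levels 6, neighborhood 5, filter 30, scale 0.2,
    3 iterations)."""

    pyramid_levels: int = 6
    pyramid_scale: float = 0.2
    iterations: int = 3
    poly_neighborhood: int = 5
    averaging_window: int = 30

    def validate(self):
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if not 0.0 < self.pyramid_scale < 1.0:
            raise ValueError("pyramid_scale must lie in (0, 1)")


@dataclass
class FlowField:
    """Per-pixel (dy, dx) displacement between slice z and z+1."""

    dy: np.ndarray
    dx: np.ndarray


class FusionMethod(Enum):
    OVERLAY = "overlay"
    SELECTIVE = "selective"
    FRAME_CHAINED = "frame_chained"


def farneback_flow(slice_a: np.ndarray, slice_b: np.ndarray,
                   params: FlowParams | None = None) -> FlowField:
    """Dense optical flow from slice_a to slice_b."""
    params = params or FlowParams()
    params.validate()
    f = farneback_flow_pair(
        slice_a, slice_b,
        levels=params.pyramid_levels, scale=params.pyramid_scale,
        iterations=params.iterations, poly_n=params.poly_neighborhood,
        win=params.averaging_window,
    )
    return FlowField(dy=f[0], dx=f[1])


def warp_labels(labels_2d: np.ndarray, flow: FlowField) -> np.ndarray:
    """Propagate a label image along a flow field.

    Each output pixel takes the label at its flow-displaced source location
    (nearest-neighbor sampling); sources falling outside the image yield
    background.  The output label set is a subset of the input's.
    """
    lab = np.asarray(labels_2d)
    if lab.shape != flow.dy.shape:
        raise ValueError("label/flow shape mismatch")
    h, w = lab.shape
    yy, xx = np.mgrid[0:h, 0:w]
    sy = np.rint(yy + flow.dy).astype(np.int64)
    sx = np.rint(xx + flow.dx).astype(np.int64)
    inside = (sy >= 0) & (sy < h) & (sx >= 0) & (sx < w)
    out = np.zeros_like(lab)
    out[inside] = lab[sy[inside], sx[inside]]
    return out


def fuse_boundaries(method: FusionMethod, net_mask: np.ndarray, net_boundary: np.ndarray,
                    propagated_labels: np.ndarray | None,
                    boundary_thickness_px: int = 3):
    """Combine network and propagated boundary information.

    Returns (interior_mask, barrier).  FRAME_CHAINED uses the same fusion
    rule as SELECTIVE — the difference is in what ``propagated_labels`` the
    caller feeds it (previous fused slice rather than a warped annotation).
    """
    net_mask = np.asarray(net_mask).astype(bool)
    net_boundary = np.asarray(net_boundary).astype(bool)
    if propagated_labels is None or not (np.asarray(propagated_labels) > 0).any():
        warnings.warn("no propagated labels; falling back to network boundary alone")
        barrier = net_boundary
        return (net_mask & ~barrier), barrier.astype(np.uint8)
    prop = np.asarray(propagated_labels)
    prop_boundary = boundary_map_from_labels(prop, boundary_thickness_px).astype(bool)

    if method is FusionMethod.OVERLAY:
        barrier = prop_boundary
    elif method in (FusionMethod.SELECTIVE, FusionMethod.FRAME_CHAINED):
        barrier = net_boundary.copy()
        comp, n = ndi.label(net_mask)
        for ci in range(1, n + 1):
            cmask = comp == ci
            ids, counts = np.unique(prop[cmask], return_counts=True)
            big = [(i, c) for i, c in zip(ids, counts) if i > 0 and c >= MIN_OVERLAP_LABEL_PX]
            if len(big) >= 2:  # overlapping cells: bring in the propagated split
                barrier |= prop_boundary & cmask
    else:  # pragma: no cover
        raise ValueError(f"unknown fusion method {method}")
    interior = net_mask & ~barrier
    return interior, barrier.astype(np.uint8)


def watershed_cells(interior_mask: np.ndarray, barrier: np.ndarray,
                    seed_points: dict) -> tuple[np.ndarray, np.ndarray]:
    """Split the interior mask among seeds by watershed on the negated
    distance transform.

    ``seed_points`` maps cell id -> (row, col).  Seeds outside the interior
    are snapped to the nearest interior pixel within 50 px, else dropped
    with a warning.  Returns (cell_labels, island_labels): connected
    components containing no seed stay unlabeled in ``cell_labels`` and get
    fresh per-slice component ids in ``island_labels`` (candidate islands).
    """
    interior = np.asarray(interior_mask).astype(bool) & ~np.asarray(barrier).astype(bool)
    markers = np.zeros(interior.shape, dtype=np.int32)
    if seed_points:
        # distances to interior for snapping
        dist_out, (iy, ix) = ndi.distance_transform_edt(~interior, return_indices=True)
        for cid, (r, c) in seed_points.items():
            r, c = int(round(r)), int(round(c))
            r = np.clip(r, 0, interior.shape[0] - 1)
            c = np.clip(c, 0, interior.shape[1] - 1)
            if not interior[r, c]:
                if dist_out[r, c] <= SEED_SNAP_RADIUS_PX:
                    r, c = int(iy[r, c]), int(ix[r, c])
                else:
                    warnings.warn(f"seed {cid} farther than {SEED_SNAP_RADIUS_PX}px from interior; dropped")
                    continue
            markers[r, c] = cid
    dist_in = ndi.distance_transform_edt(interior)
    labels = watershed(-dist_in, markers=markers, mask=interior) if markers.any() else \
        np.zeros(interior.shape, dtype=np.int32)
    # components without any seed are candidate islands
    comp, n = ndi.label(interior)
    seeded = np.unique(comp[labels > 0])
    island_mask = interior & ~np.isin(comp, seeded)
    islands, _ = ndi.label(island_mask)
    return labels.astype(np.uint16), islands.astype(np.uint16)


def _centroids(label_img: np.ndarray) -> dict:
    out = {}
    for i in np.unique(label_img):
        if i == 0:
            continue
        ys, xs = np.nonzero(label_img == i)
        out[int(i)] = (ys.mean(), xs.mean())
    return out


def separate_stack(stack_voxels: np.ndarray, sparse_cell_labels: SparseLabelSet,
                   net_masks: np.ndarray, net_boundaries: np.ndarray,
                   method: FusionMethod = FusionMethod.SELECTIVE,
                   flow_params: FlowParams | None = None,
                   seed_mode: str = "warped",
                   boundary_thickness_px: int = 3):
    """Per-slice cell separation over a whole stack.

    Each unlabeled slice is processed using propagation from its nearest
    labeled slice (ties break to the lower index), with the flow chained
    slice-by-slice because accuracy decays with propagation distance.
    Ground-truth slices pass through verbatim.  ``method=None`` runs the
    mask-alone ablation baseline (seeded watershed with no barrier at all).
    Returns (cell_labels 3D, island_labels 3D).
    """
    flow_params = flow_params or FlowParams()
    Z = stack_voxels.shape[0]
    anchors = sparse_cell_labels.slice_indices
    if not anchors:
        raise ValueError("need at least one labeled slice")
    nearest = {z: min(anchors, key=lambda a: (abs(a - z), a)) for z in range(Z)}

    cells = np.zeros_like(net_masks, dtype=np.uint16)
    islands = np.zeros_like(net_masks, dtype=np.uint16)
    for a in anchors:
        cells[a] = sparse_cell_labels.labels[a]

    # process outward from each anchor so warps chain one step at a time
    order = sorted((z for z in range(Z) if z not in anchors),
                   key=lambda z: (abs(z - nearest[z]), z))
    warped_gt: dict[int, np.ndarray] = {a: sparse_cell_labels.labels[a] for a in anchors}
    for z in order:
        a = nearest[z]
        step = 1 if z > a else -1
        prev = z - step  # one slice closer to the anchor; already processed
        flow = farneback_flow(stack_voxels[z], stack_voxels[prev], flow_params)
        if method is FusionMethod.FRAME_CHAINED:
            source = cells[prev] if prev in anchors or (cells[prev] > 0).any() else warped_gt.get(prev)
            propagated = warp_labels(source, flow)
        else:
            propagated = warp_labels(warped_gt[prev], flow)
        warped_gt[z] = propagated
        if method is None:  # ablation baseline: network mask alone, no barrier
            interior = np.asarray(net_masks[z]).astype(bool)
            barrier = np.zeros_like(interior, dtype=np.uint8)
        else:
            interior, barrier = fuse_boundaries(method, net_masks[z], net_boundaries[z],
                                                propagated, boundary_thickness_px)
        if seed_mode == "warped":
            seeds = _centroids(propagated)
        elif seed_mode == "gt":
            seeds = _centroids(sparse_cell_labels.labels[a])
        else:
            raise ValueError("seed_mode must be 'warped' or 'gt'")
        cells[z], islands[z] = watershed_cells(interior, barrier, seeds)
    # islands also exist on anchor slices: unsegmented foreground components
    for a in anchors:
        leftover = (np.asarray(net_masks[a]) > 0) & (cells[a] == 0)
        islands[a], _ = ndi.label(leftover & ~boundary_map_from_labels(
            cells[a], boundary_thickness_px).astype(bool))
    return cells, islands
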