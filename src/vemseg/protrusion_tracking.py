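"""Two-pass IoU tracking of cells and island-like protrusion blobs.

Filopodium-like protrusions cut transversely appear as island blobs
detached from any cell body and live only across a few slices.  Regions
are therefore tracked along z by maximum intersection-over-union between
consecutive slices: first the main cell bodies (which keep the cell ids
assigned at separation), then the islands.  When a tracked island meets a
main cell body, its whole track — including all earlier slices — is
relabeled to that cell id; a protrusion that later breaks off keeps the
cell's label.  Because inter-slice motion is small, candidate matches are
only searched inside a local window (512×512 by default) centered on the
region's bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = ["TrackTable", "track_main_cells", "track_islands", "apply_tracks"]

MIN_REGION_PX = 20  # speck suppression for islands


@dataclass
class TrackTable:
    """Per-slice region -> track assignment plus track metadata."""

    assignments: dict = field(default_factory=dict)  # (z, region_id) -> track label
    first_slice: dict = field(default_factory=dict)  # track -> first z
    last_slice: dict = field(default_factory=dict)   # track -> last z
    merged_into: dict = field(default_factory=dict)  # island track -> cell id
    next_new_label: int = 1

    def label_of(self, z, region_id):
        t = self.assignments[(z, region_id)]
        return self.merged_into.get(t, t)

    def _touch(self, track, z):
        self.first_slice.setdefault(track, z)
        self.last_slice[track] = z


def _regions(label_img: np.ndarray, min_px: int = 0):
    """Connected components per id: list of (region_id, id, mask_bbox, bbox).

    A region id is unique within the slice; ``id`` is the carried label.
    """
    out = []
    rid = 0
    for i in np.unique(label_img):
        if i == 0:
            continue
        comp, n = ndi.label(label_img == i)
        objs = ndi.find_objects(comp)
        for ci, sl in enumerate(objs, start=1):
            m = comp[sl] == ci
            if m.sum() < min_px:
                continue
            rid += 1
            out.append((rid, int(i), m, sl))
    return out


def _window_iou(mask_a, bbox_a, mask_b, bbox_b, shape, window_px):
    """IoU of two regions given as (bbox-cropped mask, bbox), restricted to
    a window of ``window_px`` centered on region a's bounding box."""
    cy = (bbox_a[0].start + bbox_a[0].stop) / 2
    cx = (bbox_a[1].start + bbox_a[1].stop) / 2
    half = window_px / 2
    wy0, wy1 = max(0, int(cy - half)), min(shape[0], int(cy + half))
    wx0, wx1 = max(0, int(cx - half)), min(shape[1], int(cx + half))

    def clipped(mask, bbox):
        y0, y1 = bbox[0].start, bbox[0].stop
        x0, x1 = bbox[1].start, bbox[1].stop
        gy0, gy1 = max(y0, wy0), min(y1, wy1)
        gx0, gx1 = max(x0, wx0), min(x1, wx1)
        if gy0 >= gy1 or gx0 >= gx1:
            return None, None
        return mask[gy0 - y0:gy1 - y0, gx0 - x0:gx1 - x0], (gy0, gy1, gx0, gx1)

    ca, ba = clipped(mask_a, bbox_a)
    cb, bb = clipped(mask_b, bbox_b)
    if ca is None or cb is None:
        return 0.0, 0
    # overlap of the two clipped bboxes
    oy0, oy1 = max(ba[0], bb[0]), min(ba[1], bb[1])
    ox0, ox1 = max(ba[2], bb[2]), min(ba[3], bb[3])
    inter = 0
    if oy0 < oy1 and ox0 < ox1:
        sa = ca[oy0 - ba[0]:oy1 - ba[0], ox0 - ba[2]:ox1 - ba[2]]
        sb = cb[oy0 - bb[0]:oy1 - bb[0], ox0 - bb[2]:ox1 - bb[2]]
        inter = int(np.logical_and(sa, sb).sum())
    union = int(ca.sum()) + int(cb.sum()) - inter
    return (inter / union if union else 0.0), inter


def track_main_cells(cell_slices: np.ndarray, window_px: int = 512) -> TrackTable:
    """Track main cell bodies; separation ids seed the track labels.

    Each region in slice z+1 takes the track label of its maximum-IoU match
    among slice-z regions inside the local window; with no overlap at all it
    receives a fresh label.
    """
    table = TrackTable()
    shape = cell_slices.shape[1:]
    max_id = int(cell_slices.max())
    table.next_new_label = max_id + 1
    prev = []  # (track, mask, bbox)
    for z in range(cell_slices.shape[0]):
        regs = _regions(cell_slices[z])
        cur = []
        for rid, cid, mask, bbox in regs:
            if z == 0:
                track = cid
            else:
                best, best_key = None, (0.0, 0, 0)
                for track_p, mask_p, bbox_p in prev:
                    i, inter = _window_iou(mask, bbox, mask_p, bbox_p, shape, window_px)
                    key = (i, inter, -track_p)  # ties: larger overlap, smaller label
                    if i > 0 and key > best_key:
                        best, best_key = track_p, key
                if best is None:
                    track = table.next_new_label
                    table.next_new_label += 1
                else:
                    track = best
            table.assignments[(z, rid)] = track
            table._touch(track, z)
            cur.append((track, mask, bbox))
        prev = cur
    return table


def track_islands(island_slices: np.ndarray, cell_slices: np.ndarray,
                  main_tracks: TrackTable, window_px: int = 512,
                  min_region_px: int = MIN_REGION_PX) -> TrackTable:
    """Track islands and retroactively merge them into cells they meet.

    Islands are matched by maximum IoU against the previous slice's islands
    and main-cell regions.  Matching a cell region merges the island's whole
    track (all earlier slices included) into that cell id; the track keeps
    the cell id even if it later detaches.  Ties go to the larger overlap
    area, then the smaller cell id.
    """
    table = TrackTable()
    shape = island_slices.shape[1:]
    table.next_new_label = int(max(cell_slices.max(), island_slices.max())) + 1
    prev_islands = []   # (track, mask, bbox)
    for z in range(island_slices.shape[0]):
        prev_cells = _regions(cell_slices[z - 1]) if z > 0 else []
        cur = []
        continued = set()
        for rid, _i, mask, bbox in _regions(island_slices[z], min_px=min_region_px):
            # joint max-IoU match over previous islands AND cell regions
            best_island, island_key = None, (0.0, 0, 0)
            for track_p, mask_p, bbox_p in prev_islands:
                i, inter = _window_iou(mask, bbox, mask_p, bbox_p, shape, window_px)
                key = (i, inter, -track_p)
                if i > 0 and key > island_key:
                    best_island, island_key = track_p, key
            best_cell, cell_key = None, (0.0, 0, 0)
            for _rid, cid, mask_c, bbox_c in prev_cells:
                i, inter = _window_iou(mask, bbox, mask_c, bbox_c, shape, window_px)
                key = (i, inter, -cid)
                if i > 0 and key > cell_key:
                    best_cell, cell_key = cid, key
            if best_island is not None:
                track = best_island
                continued.add(track)
            else:
                track = table.next_new_label
                table.next_new_label += 1
            if best_cell is not None and cell_key > island_key and \
                    track not in table.merged_into:
                # the island's best predecessor is a main cell: it met the
                # cell, and its whole track is retroactively relabeled
                table.merged_into[track] = best_cell
            table.assignments[(z, rid)] = track
            table._touch(track, z)
            cur.append((track, mask, bbox))
        # the converse meeting: an island track ends because its continuation
        # was absorbed into a cell body; require substantial coverage so a
        # grazing 1-px overlap with a passing cell does not merge the track
        if z > 0:
            for _rid, cid, mask_c, bbox_c in _regions(cell_slices[z]):
                for track_p, mask_p, bbox_p in prev_islands:
                    if track_p in table.merged_into or track_p in continued:
                        continue
                    _, inter = _window_iou(mask_c, bbox_c, mask_p, bbox_p, shape, window_px)
                    if inter >= 0.5 * int(mask_p.sum()):
                        table.merged_into[track_p] = cid
        prev_islands = cur
    return table


def apply_tracks(slices: np.ndarray, table: TrackTable, min_region_px: int = 0) -> np.ndarray:
    """Render final track labels into a 3D volume; idempotent."""
    out = np.zeros(slices.shape, dtype=np.uint16)
    for z in range(slices.shape[0]):
        for rid, _i, mask, bbox in _regions(slices[z], min_px=min_region_px):
            if (z, rid) not in table.assignments:
                raise KeyError(f"region {rid} in slice {z} has no track (bookkeeping bug)")
            out[z][bbox][mask] = table.label_of(z, rid)
    return out
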