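"""IoU tracking of cells and islands, retroactive merge, oracle equivalence."""

import numpy as np
import pytest

from vemseg.protrusion_tracking import (TrackTable, apply_tracks, track_islands,
                                        track_main_cells)


def _disk(img, cy, cx, r, val):
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = val


def test_static_blob_keeps_one_label():
    vol = np.zeros((5, 64, 64), dtype=np.uint16)
    for z in range(5):
        _disk(vol[z], 30, 30, 8, 4)
    table = track_main_cells(vol)
    out = apply_tracks(vol, table)
    assert set(np.unique(out)) == {0, 4}
    assert table.first_slice[4] == 0 and table.last_slice[4] == 4


def test_new_region_gets_fresh_label():
    vol = np.zeros((6, 64, 64), dtype=np.uint16)
    for z in range(6):
        _disk(vol[z], 20, 20, 7, 1)
    for z in range(3, 6):
        _disk(vol[z], 50, 50, 5, 1)  # same id, but disconnected: new track
    table = track_main_cells(vol)
    out = apply_tracks(vol, table)
    labels_at_5 = set(np.unique(out[5])) - {0}
    assert len(labels_at_5) == 2
    assert 1 in labels_at_5
    new = (labels_at_5 - {1}).pop()
    assert new > 1
    assert table.first_slice[new] == 3


def _brute_force_tracks(vol):
    """Oracle: exhaustive IoU over all region pairs, no search window."""
    from scipy import ndimage as ndi

    table = {}
    next_label = int(vol.max()) + 1
    prev = []
    for z in range(vol.shape[0]):
        cur = []
        for i in np.unique(vol[z]):
            if i == 0:
                continue
            comp, n = ndi.label(vol[z] == i)
            for ci in range(1, n + 1):
                m = comp == ci
                if z == 0:
                    t = int(i)
                else:
                    best, key = None, (0.0, 0, 0)
                    for tp, mp in prev:
                        inter = int((m & mp).sum())
                        union = int((m | mp).sum())
                        iou = inter / union if union else 0.0
                        k = (iou, inter, -tp)
                        if iou > 0 and k > key:
                            best, key = tp, k
                    if best is None:
                        t = next_label
                        next_label += 1
                    else:
                        t = best
                table[(z, ci, int(i))] = t
                cur.append((t, m))
        prev = cur
    out = np.zeros_like(vol)
    for z in range(vol.shape[0]):
        from scipy import ndimage as ndi

        for i in np.unique(vol[z]):
            if i == 0:
                continue
            comp, n = ndi.label(vol[z] == i)
            for ci in range(1, n + 1):
                out[z][comp == ci] = table[(z, ci, int(i))]
    return out


def _wandering_blobs(n_slices=20, hw=256, step=12, seed=3):
    """Blobs drifting less than window/4 per slice."""
    rng = np.random.default_rng(seed)
    vol = np.zeros((n_slices, hw, hw), dtype=np.uint16)
    centers = [(60.0, 60.0), (180.0, 80.0), (100.0, 190.0)]
    radii = [14, 10, 8]
    for z in range(n_slices):
        for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
            _disk(vol[z], int(cy), int(cx), r, i)
        centers = [(np.clip(cy + rng.uniform(-step, step), 30, hw - 30),
                    np.clip(cx + rng.uniform(-step, step), 30, hw - 30))
                   for (cy, cx) in centers]
    return vol


def test_windowed_tracking_equals_brute_force_oracle():
    vol = _wandering_blobs()
    windowed = apply_tracks(vol, track_main_cells(vol, window_px=512))
    oracle = _brute_force_tracks(vol)
    assert np.array_equal(windowed, oracle)


def test_swapping_sizes_follow_max_iou():
    vol = _wandering_blobs(n_slices=8, seed=9)
    windowed = apply_tracks(vol, track_main_cells(vol, window_px=512))
    oracle = _brute_force_tracks(vol)
    assert np.array_equal(windowed, oracle)


def test_island_retroactive_merge_covers_earlier_slices():
    cells = np.zeros((12, 128, 128), dtype=np.uint16)
    islands = np.zeros_like(cells)
    for z in range(12):
        _disk(cells[z], 64, 40, 16, 3)
    # island drifts toward the cell; its last section lies mostly inside the
    # cell's footprint, after which it is absorbed by the cell body
    for z, cx in zip(range(3, 10), [96, 88, 80, 72, 64, 56, 50]):
        _disk(islands[z], 64, cx, 6, 1)
    mains = track_main_cells(cells)
    isl = track_islands(islands, cells, mains)
    out = apply_tracks(islands, isl)
    for z in range(3, 10):
        vals = set(np.unique(out[z])) - {0}
        assert vals == {3}, f"slice {z} not relabeled to the cell id"


def test_island_never_meeting_cell_keeps_new_label():
    cells = np.zeros((6, 96, 96), dtype=np.uint16)
    islands = np.zeros_like(cells)
    for z in range(6):
        _disk(cells[z], 20, 20, 10, 2)
        _disk(islands[z], 70, 70, 5, 1)
    isl = track_islands(islands, cells, track_main_cells(cells))
    out = apply_tracks(islands, isl)
    label = set(np.unique(out)) - {0}
    assert len(label) == 1 and label.pop() > 2


def test_apply_tracks_idempotent_and_conserves_area():
    vol = _wandering_blobs(n_slices=6)
    table = track_main_cells(vol)
    once = apply_tracks(vol, table)
    twice = apply_tracks(once, track_main_cells(once))
    assert np.array_equal(once, twice)
    for z in range(vol.shape[0]):
        assert (once[z] > 0).sum() == (vol[z] > 0).sum()


def test_min_region_filter_drops_only_small_regions():
    islands = np.zeros((2, 64, 64), dtype=np.uint16)
    islands[0, 10:12, 10:12] = 1          # 4 px speck
    islands[0, 30:40, 30:40] = 2          # 100 px region
    cells = np.zeros_like(islands)
    isl = track_islands(islands, cells, track_main_cells(cells), min_region_px=20)
    out = apply_tracks(islands, isl, min_region_px=20)
    assert out[0, 10, 10] == 0
    assert out[0, 35, 35] > 0


def test_missing_region_in_table_raises():
    vol = np.zeros((2, 32, 32), dtype=np.uint16)
    vol[0, 5:10, 5:10] = 1
    with pytest.raises(KeyError):
        apply_tracks(vol, TrackTable())


def test_phantom_protrusions_recover_true_parent(phantom_std):
    """Retroactive merge assigns detached protrusion voxels to their parent."""
    from tests.conftest import truth_main_and_islands

    _, _, truth = phantom_std
    mains, islands = truth_main_and_islands(truth)
    main_tracks = track_main_cells(mains, window_px=512)
    isl_tracks = track_islands(islands, mains, main_tracks, window_px=512)
    vol_main = apply_tracks(mains, main_tracks)
    vol_isl = apply_tracks(islands, isl_tracks, min_region_px=20)
    final = np.where(vol_main > 0, vol_main, vol_isl)
    tube_mask = truth.protrusion_labels > 0
    correct = 0
    total = 0
    for tid, cid in truth.protrusion_parent.items():
        m = truth.protrusion_labels == tid
        total += int(m.sum())
        correct += int((final[m] == cid).sum())
    assert correct / total >= 0.95
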