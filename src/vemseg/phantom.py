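"""Synthetic FIB-SEM-like phantom stacks with complete ground truth.

Real tumor-tissue FIB-SEM volumes show tightly packed cells whose shared
membranes are often invisible, thin filopodium-like protrusions that — cut
transversely — appear as island blobs detached from their cell body, nuclei
with envelope invaginations, fenestrated nucleoli, and small ellipsoidal
mitochondria, all under per-slice brightness drift and additive noise.  The
phantom emulates exactly those properties on a seeded random geometry so
that every downstream stage (training, inference, cell separation, island
tracking, feature extraction) can be exercised against known truth.

Geometry: cells are a smoothed 3D Voronoi partition of an ellipsoidal
support; protrusions are straight tubes leaving a cell at 30-60 degrees to
the imaging plane (guaranteeing detached 2D cross-sections); fenestrations
are spherical cavities subtracted from nucleoli until a target cavity
fraction is reached, which makes the fenestrated-volume measure testable
against an analytic value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi

from vemseg.stack_io import ImageStack, SparseLabelSet

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom_stack",
    "make_sparse_labels",
    "save_phantom",
]

# rendered mean gray levels (8-bit); organelles darker than cytoplasm
INTENSITY = {
    "background": 195,
    "cytoplasm": 150,
    "nucleus": 120,
    "nucleolus": 70,
    "mitochondrion": 95,
    "endosome": 55,
    "lysosome": 35,
    "membrane": 40,
}

# in-plane erosion structure: the crop cuts cells mid-tissue, so geometry
# is never eroded along z
_XY_CROSS = np.array([[[0, 0, 0], [0, 0, 0], [0, 0, 0]],
                      [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
                      [[0, 0, 0], [0, 0, 0], [0, 0, 0]]], dtype=bool)


@dataclass
class PhantomConfig:
    """Parameters of the synthetic stack; identical (config, seed) pairs
    produce bit-identical outputs."""

    shape: tuple = (64, 256, 256)  # (slices, height, width)
    n_cells: int = 4
    membrane_visible_fraction: float = 0.6
    n_protrusions_per_cell: int = 1
    protrusion_radius_px: float = 4.0
    protrusion_pitch_deg: tuple = (30.0, 60.0)
    organelle_counts: dict = field(default_factory=lambda: {
        "nucleolus": (1, 6),      # per nucleus (inclusive range)
        "mitochondrion": 5,       # per cell
        "endosome": 2,
        "lysosome": 2,
    })
    fenestration_fraction: float = 0.125
    noise_sigma: float = 5.0
    brightness_jitter: float = 25.0
    seed: int = 0

    def validate(self):
        if len(self.shape) != 3 or any(int(s) < 64 for s in self.shape):
            raise ValueError("shape: all components must be >= 64")
        for name in ("membrane_visible_fraction", "fenestration_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells: must be >= 1")
        if self.n_protrusions_per_cell < 0:
            raise ValueError("n_protrusions_per_cell: must be >= 0")
        if self.protrusion_radius_px <= 0:
            raise ValueError("protrusion_radius_px: must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma: must be >= 0")
        if self.brightness_jitter < 0:
            raise ValueError("brightness_jitter: must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth volumes and the generator's own bookkeeping."""

    cell_labels: np.ndarray            # cell id per voxel, protrusions carry parent id
    organelle_labels: dict             # class -> uint16 label volume
    protrusion_labels: np.ndarray      # tube id per voxel (0 elsewhere)
    protrusion_parent: dict            # tube id -> parent cell id
    detached_sections: list            # (tube id, slice index) for detached 2D islands
    nucleoli_per_nucleus: dict         # cell id -> count
    nucleolus_parent: dict             # nucleolus id -> cell id
    organelle_parent: dict             # class -> {instance id -> cell id}
    cavity_fraction: dict              # nucleolus id -> achieved cavity volume fraction
    visible_interfaces: list = None    # cell id pairs rendered with a dark membrane
    all_interfaces: list = None        # every adjacent cell id pair


def _ball_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    g = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    keep = (g ** 2).sum(axis=0) <= radius ** 2
    return np.stack([g[0][keep], g[1][keep], g[2][keep]], axis=1)


def _stamp(mask: np.ndarray, centers: np.ndarray, offsets: np.ndarray):
    """Set mask True at ball offsets around each center, clipped to bounds."""
    shape = mask.shape
    for c in centers:
        pts = offsets + np.round(c).astype(int)
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - center[0]) / semi_axes[0]) ** 2 + \
           ((yy - center[1]) / semi_axes[1]) ** 2 + \
           ((xx - center[2]) / semi_axes[2]) ** 2 <= 1.0


def _voronoi_cells(shape, seeds, support) -> np.ndarray:
    """Nearest-seed partition of the support, lightly smoothed."""
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    best = np.full(shape, np.inf, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.uint16)
    for i, s in enumerate(seeds, start=1):
        # z distance is down-weighted: cells are tilted columns whose
        # boundaries drift slowly with depth instead of closing off
        d = 0.09 * (zz - s[0]).astype(np.float32) ** 2 + (yy - s[1]) ** 2 + (xx - s[2]) ** 2
        closer = d < best
        best[closer] = d[closer]
        labels[closer] = i
    labels[~support] = 0
    # round the planar Voronoi faces a little
    smooth = np.zeros(shape, dtype=np.float32)
    out = np.zeros(shape, dtype=np.uint16)
    for i in range(1, len(seeds) + 1):
        f = ndi.gaussian_filter((labels == i).astype(np.float32), sigma=1.5)
        take = f > smooth
        smooth[take] = f[take]
        out[take] = i
    out[~support] = 0
    return out


def _grow_protrusion(cfg, rng, cell_id, bodies, tube_mask_all, shape):
    """One oblique tube leaving the cell into background; returns its mask
    and the slices where its 2D section is detached from the cell body."""
    body = bodies == cell_id
    centroid = np.array(ndi.center_of_mass(body))
    # surface voxels adjacent to background
    bg = bodies == 0
    surf = body & ndi.binary_dilation(bg)
    pts = np.argwhere(surf)
    offsets = _ball_offsets(cfg.protrusion_radius_px)
    lo, hi = cfg.protrusion_pitch_deg
    for _ in range(60):
        p0 = pts[rng.integers(len(pts))].astype(float)
        horiz = p0[1:] - centroid[1:]
        n = np.linalg.norm(horiz)
        if n < 1e-6:
            continue
        horiz = horiz / n
        pitch = np.deg2rad(rng.uniform(lo, hi))
        sz = 1.0 if p0[0] >= centroid[0] else -1.0
        d = np.array([sz * np.sin(pitch), np.cos(pitch) * horiz[0], np.cos(pitch) * horiz[1]])
        length = rng.uniform(18.0, 36.0)
        ts = np.arange(0.0, length, 0.5)
        centers = p0[None, :] + ts[:, None] * d[None, :]
        tube = np.zeros(shape, dtype=bool)
        _stamp(tube, centers, offsets)
        # protrusion voxels belong to exactly one parent: keep only voxels
        # outside every cell body and outside previously placed tubes
        tube &= bg & ~tube_mask_all
        if tube.sum() < 30:
            continue
        # the root must emerge laterally through the membrane: at least one
        # slice where the tube section is 2D-adjacent to the cell body (a
        # purely z-diagonal attachment would be untrackable by design)
        detached, attached = [], []
        for z in range(shape[0]):
            tz = tube[z]
            if not tz.any():
                continue
            lab2d, n2d = ndi.label(tz, structure=np.ones((3, 3)))
            touch = ndi.binary_dilation(body[z], structure=np.ones((3, 3)))
            hit = False
            for comp in range(1, n2d + 1):
                if (touch & (lab2d == comp)).any():
                    hit = True
                else:
                    detached.append(z)
            if hit:
                attached.append(z)
        detached = sorted(set(detached))
        if detached and attached:
            return tube, detached
    return None, []


def _place_spheres(rng, region_mask, count, r_range, margin=1):
    """Place up to ``count`` non-overlapping spheres inside region_mask.
    Returns list of (center, radius) in global coordinates."""
    if not region_mask.any():
        return []
    sl = ndi.find_objects(region_mask.astype(np.uint8))[0]
    origin = np.array([s.start for s in sl])
    sub = region_mask[sl]
    dist = ndi.distance_transform_edt(np.pad(sub, 1))[1:-1, 1:-1, 1:-1]
    cand = np.argwhere(dist >= r_range[0] + margin)
    placed = []
    occupied = np.zeros_like(sub)
    for _ in range(count):
        for _try in range(80):
            if len(cand) == 0:
                break
            r = rng.uniform(*r_range)
            c = cand[rng.integers(len(cand))]
            if dist[tuple(c)] < r + margin or occupied[tuple(c)]:
                continue
            pts = _ball_offsets(r + 1) + c
            ins = np.all((pts >= 0) & (pts < np.array(sub.shape)), axis=1)
            pts = pts[ins]
            if occupied[pts[:, 0], pts[:, 1], pts[:, 2]].any():
                continue
            placed.append(((c + origin).astype(float), r))
            occupied[pts[:, 0], pts[:, 1], pts[:, 2]] = True
            break
    return placed


def generate_phantom_stack(config: PhantomConfig):
    """Render a phantom stack and its ground truth.

    Returns (ImageStack, PhantomTruth).  Organelles are darker textured
    regions; membranes are thin dark sheets on the configured fraction of
    cell-cell interfaces (external cell surfaces are always membranous); at
    least one protrusion per cell has a slice where its 2D cross-section is
    disconnected from the parent cell body.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(int(s) for s in config.shape)
    Z, H, W = shape

    # --- cells: Voronoi partition of an elliptic cylinder along z -----------
    # a FIB-SEM stack is a thin crop through tissue, so cells (and nuclei)
    # run through the whole z range; a cylindrical support keeps per-slice
    # content stationary, as in real acquisitions
    center = np.array([Z / 2, H / 2, W / 2])
    semi = np.array([10 * Z, 0.42 * H, 0.42 * W])  # huge z axis = cylinder
    support = _ellipsoid_mask(shape, center, semi)
    seeds = []
    inner = np.array([0.45 * Z, 0.75 * semi[1], 0.75 * semi[2]])
    while len(seeds) < config.n_cells:
        cand = center + (rng.uniform(-1, 1, 3) * inner)
        rel = ((cand[1:] - center[1:]) / inner[1:]) ** 2
        if rel.sum() <= 1.0 and all(np.linalg.norm(cand[1:] - s[1:]) > 0.3 * min(H, W) / np.sqrt(config.n_cells) for s in seeds):
            seeds.append(cand)
    bodies = _voronoi_cells(shape, seeds, support)

    # --- protrusions --------------------------------------------------------
    tube_labels = np.zeros(shape, dtype=np.uint16)
    tube_all = np.zeros(shape, dtype=bool)
    protrusion_parent = {}
    detached_sections = []
    tid = 0
    for cid in range(1, config.n_cells + 1):
        for _k in range(config.n_protrusions_per_cell):
            tube, detached = _grow_protrusion(config, rng, cid, bodies, tube_all, shape)
            if tube is None:
                continue
            tid += 1
            tube_labels[tube] = tid
            tube_all |= tube
            protrusion_parent[tid] = cid
            detached_sections.extend((tid, z) for z in detached)

    cells = bodies.copy()
    for t, cid in protrusion_parent.items():
        cells[tube_labels == t] = cid

    # --- nuclei with envelope invaginations ---------------------------------
    nucleus = np.zeros(shape, dtype=np.uint16)
    organelle_parent = {"nucleus": {}, "mitochondrion": {}, "endosome": {}, "lysosome": {}}
    for cid in range(1, config.n_cells + 1):
        body = bodies == cid
        if not body.any():
            continue
        c = np.array(ndi.center_of_mass(body))
        # nuclei run through (almost) the whole crop in z, like real nuclei
        # whose diameter dwarfs the stack depth, but stay inside the cell in xy
        ext = [max(3.0, f * (np.ptp(np.argwhere(body)[:, a]) + 1))
               for a, f in zip(range(3), (0.75, 0.42, 0.42))]
        nuc = _ellipsoid_mask(shape, c, ext) & ndi.binary_erosion(body, structure=_XY_CROSS, iterations=2)
        # envelope invaginations: subtract 1-2 dents on the surface
        surf = np.argwhere(nuc & ~ndi.binary_erosion(nuc))
        for _d in range(rng.integers(1, 3)):
            if len(surf) == 0:
                break
            p = surf[rng.integers(len(surf))]
            dent = np.zeros(shape, dtype=bool)
            _stamp(dent, p[None, :].astype(float), _ball_offsets(rng.uniform(2.5, 4.5)))
            nuc &= ~dent
        nucleus[nuc] = cid
        organelle_parent["nucleus"][cid] = cid

    # --- nucleoli with fenestrations ----------------------------------------
    nucleolus = np.zeros(shape, dtype=np.uint16)
    nucleoli_per_nucleus = {}
    nucleolus_parent = {}
    cavity_fraction = {}
    cavity_all = np.zeros(shape, dtype=bool)
    nol_id = 0
    lo, hi = config.organelle_counts.get("nucleolus", (1, 6))
    for cid in range(1, config.n_cells + 1):
        nuc = nucleus == cid
        if not nuc.any():
            nucleoli_per_nucleus[cid] = 0
            continue
        want = int(rng.integers(lo, hi + 1))
        spheres = _place_spheres(rng, ndi.binary_erosion(nuc, iterations=2), want, (4.0, 7.0))
        nucleoli_per_nucleus[cid] = len(spheres)
        for c, r in spheres:
            nol_id += 1
            sph = np.zeros(shape, dtype=bool)
            _stamp(sph, c[None, :], _ball_offsets(r))
            sph &= nuc
            filled = int(sph.sum())
            # carve interior cavities until the target volume fraction
            cav = np.zeros(shape, dtype=bool)
            for _try in range(40):
                if filled == 0 or cav.sum() / filled >= config.fenestration_fraction:
                    break
                rc = rng.uniform(1.5, max(1.6, 0.45 * r))
                # cavity strictly interior so hole filling recovers it
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cc = c + u * rng.uniform(0, max(0.0, r - rc - 2.0))
                hole = np.zeros(shape, dtype=bool)
                _stamp(hole, cc[None, :], _ball_offsets(rc))
                cav |= hole & sph
            nucleolus[sph & ~cav] = nol_id
            cavity_all |= cav
            nucleolus_parent[nol_id] = cid
            cavity_fraction[nol_id] = (cav.sum() / filled) if filled else 0.0

    # --- mitochondria / endosomes / lysosomes -------------------------------
    small = {"mitochondrion": np.zeros(shape, dtype=np.uint16),
             "endosome": np.zeros(shape, dtype=np.uint16),
             "lysosome": np.zeros(shape, dtype=np.uint16)}
    radii = {"mitochondrion": (2.5, 4.5), "endosome": (2.0, 3.5), "lysosome": (2.0, 3.0)}
    counters = {k: 0 for k in small}
    for cid in range(1, config.n_cells + 1):
        cyto = (bodies == cid) & (nucleus == 0)
        cyto = ndi.binary_erosion(cyto, structure=_XY_CROSS, iterations=2)
        for cls in small:
            want = int(config.organelle_counts.get(cls, 0))
            for c, r in _place_spheres(rng, cyto, want, radii[cls]):
                counters[cls] += 1
                inst = np.zeros(shape, dtype=bool)
                if cls == "mitochondrion":
                    # ellipsoidal: stretch along a random axis
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    ts = np.linspace(-r, r, 7)
                    centers = c[None, :] + 1.6 * ts[:, None] * u[None, :]
                    _stamp(inst, centers, _ball_offsets(0.7 * r))
                else:
                    _stamp(inst, c[None, :], _ball_offsets(r))
                inst &= (bodies == cid) & (nucleus == 0)
                small[cls][inst] = counters[cls]
                organelle_parent[cls][counters[cls]] = cid

    # --- render -------------------------------------------------------------
    img = np.full(shape, float(INTENSITY["background"]), dtype=np.float32)
    img[cells > 0] = INTENSITY["cytoplasm"]
    img[nucleus > 0] = INTENSITY["nucleus"]
    img[cavity_all] = INTENSITY["nucleus"]  # fenestration interiors look nucleoplasmic
    img[nucleolus > 0] = INTENSITY["nucleolus"]
    for cls in small:
        img[small[cls] > 0] = INTENSITY[cls]
    # chromatin-like low-amplitude texture inside nuclei
    tex = ndi.gaussian_filter(rng.normal(0, 1, shape).astype(np.float32), sigma=2.0)
    tex *= 8.0 / max(tex.std(), 1e-6)
    img[nucleus > 0] += tex[nucleus > 0]

    # membranes: external cell surface always dark
    ext_membrane = (cells > 0) & ndi.binary_dilation(cells == 0)
    img[ext_membrane] = INTENSITY["membrane"]
    # cell-cell interfaces: only the configured fraction is rendered
    pairs = set()
    for ax in range(3):
        a = np.swapaxes(cells, 0, ax)
        l, r = a[:-1], a[1:]
        both = (l > 0) & (r > 0) & (l != r)
        ids = np.stack([np.minimum(l[both], r[both]), np.maximum(l[both], r[both])], axis=1)
        pairs.update(map(tuple, np.unique(ids, axis=0))) if ids.size else None
    pairs = sorted(pairs)
    n_vis = int(round(config.membrane_visible_fraction * len(pairs)))
    visible = [pairs[i] for i in rng.permutation(len(pairs))[:n_vis]]
    for (a, b) in visible:
        ma, mb = cells == a, cells == b
        iface = (ma & ndi.binary_dilation(mb)) | (mb & ndi.binary_dilation(ma))
        img[iface] = INTENSITY["membrane"]

    # per-slice brightness jitter and additive noise
    jitter = rng.uniform(-config.brightness_jitter, config.brightness_jitter, Z).astype(np.float32)
    img += jitter[:, None, None]
    img += rng.normal(0.0, config.noise_sigma, shape).astype(np.float32)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    organelle_labels = {"nucleus": nucleus, "nucleolus": nucleolus, **small}
    truth = PhantomTruth(
        cell_labels=cells,
        organelle_labels=organelle_labels,
        protrusion_labels=tube_labels,
        protrusion_parent=protrusion_parent,
        detached_sections=detached_sections,
        nucleoli_per_nucleus=nucleoli_per_nucleus,
        nucleolus_parent=nucleolus_parent,
        organelle_parent=organelle_parent,
        cavity_fraction=cavity_fraction,
        visible_interfaces=[(int(a), int(b)) for a, b in visible],
        all_interfaces=[(int(a), int(b)) for a, b in pairs],
    )
    stack = ImageStack(img, voxel_size_nm=6.0, provenance=[f"phantom(seed={config.seed})"])
    return stack, truth


def make_sparse_labels(truth, stride: int, class_name: str = "cell") -> SparseLabelSet:
    """Evenly spaced sparse annotation: slices {0, stride, 2*stride, ...}.

    ``truth`` may be a PhantomTruth or a bare 3D label volume.  A stride at
    least the stack depth degenerates to the single slice 0 with a warning.
    """
    import warnings

    if stride < 1:
        raise ValueError("stride must be >= 1")
    if isinstance(truth, PhantomTruth):
        vol = truth.cell_labels if class_name == "cell" else truth.organelle_labels[class_name]
    else:
        vol = np.asarray(truth)
    n = vol.shape[0]
    if stride >= n:
        warnings.warn("stride >= number of slices; using single slice 0")
        indices = [0]
    else:
        indices = list(range(0, n, stride))
    return SparseLabelSet(
        slice_indices=indices,
        labels={i: vol[i].astype(np.uint16) for i in indices},
        class_name=class_name,
    )


def save_phantom(stack: ImageStack, truth: PhantomTruth, config: PhantomConfig, out_dir) -> None:
    """Write image + per-class label TIFFs and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "image.tif", stack.voxels, photometric='minisblack')
    tifffile.imwrite(out / "cells.tif", truth.cell_labels.astype(np.uint16), photometric='minisblack')
    tifffile.imwrite(out / "protrusions.tif", truth.protrusion_labels.astype(np.uint16), photometric='minisblack')
    for cls, vol in truth.organelle_labels.items():
        tifffile.imwrite(out / f"{cls}.tif", vol.astype(np.uint16), photometric='minisblack')
    meta = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items() if k != "organelle_counts"},
        "organelle_counts": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in config.organelle_counts.items()},
        "seed": config.seed,
        "protrusion_parent": {str(k): int(v) for k, v in truth.protrusion_parent.items()},
        "nucleoli_per_nucleus": {str(k): int(v) for k, v in truth.nucleoli_per_nucleus.items()},
    }
    (out / "phantom.json").write_text(json.dumps(meta, indent=2))
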