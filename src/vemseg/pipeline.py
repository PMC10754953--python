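"""End-to-end pipeline orchestration with caching and provenance.

Stages: phantom → train → predict → split-cells → track → features →
evaluate.  Each stage records its parameters and the content hashes of its
inputs/outputs in a JSON manifest inside the run directory; a re-run skips
stages whose recorded hashes still match, and re-executes anything whose
inputs (or parameters) changed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["PipelineConfig", "run_pipeline", "export_mesh", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 0,
    "phantom": {"shape": [64, 256, 256], "n_cells": 4},
    "train": {"classes": ["nucleus"], "label_stride": 10, "updates": 60,
              "base_filters": 4, "tile_px": 64, "context_px": 64},
    "predict": {"tile_px": 64, "overlap_px": 32, "alpha": 0.5},
    "separate": {"method": "selective", "boundary_thickness_px": 3},
    "track": {"window_px": 512, "min_island_px": 20},
    "features": {"compute_texture": False},
}


class PipelineConfig(dict):
    """Nested dict of per-stage parameter blocks plus the global seed."""

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = json.loads(json.dumps(DEFAULT_CONFIG))
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
        return cls(cfg)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_params(params) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {}

    def fresh(self, stage: str, params, inputs: list[Path], outputs: list[Path]) -> bool:
        rec = self.data.get(stage)
        if rec is None:
            return False
        if rec["params"] != _hash_params(params):
            return False
        if not all(Path(o).exists() for o in rec["outputs"]):
            return False
        for p, h in rec["inputs"].items():
            if not Path(p).exists() or _hash_file(Path(p)) != h:
                return False
        for p, h in rec["output_hashes"].items():
            if _hash_file(Path(p)) != h:
                return False
        return True

    def record(self, stage: str, params, inputs: list[Path], outputs: list[Path], seconds: float):
        self.data[stage] = {
            "params": _hash_params(params),
            "inputs": {str(p): _hash_file(Path(p)) for p in inputs},
            "outputs": [str(p) for p in outputs],
            "output_hashes": {str(p): _hash_file(Path(p)) for p in outputs},
            "seconds": round(seconds, 3),
        }
        self.path.write_text(json.dumps(self.data, indent=2))


def run_pipeline(config: PipelineConfig, out_dir, stack_path=None, log=print) -> Path:
    """Execute all stages into ``out_dir``; returns the run directory.

    Without ``stack_path`` a phantom is generated and its ground truth
    drives training and evaluation.  Stages whose recorded input/parameter
    hashes match the manifest are skipped.
    """
    from vemseg import cell_separation as cs
    from vemseg import features as feat
    from vemseg import metrics, protrusion_tracking as pt
    from vemseg.phantom import PhantomConfig, generate_phantom_stack, make_sparse_labels, save_phantom
    from vemseg.resunet import ModelSpec, TrainConfig, build_model, load_checkpoint, save_checkpoint, train
    from vemseg.stack_io import equalize_stack, read_stack
    from vemseg.tiled_inference import predict_stack, threshold_map

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    seed = int(config.get("seed", 0))
    skipped, ran = [], []

    def stage(name, params, inputs, outputs, fn):
        if manifest.fresh(name, params, inputs, outputs):
            skipped.append(name)
            log(f"[{name}] up to date, skipped")
            return
        t0 = time.time()
        fn()
        manifest.record(name, params, inputs, outputs, time.time() - t0)
        ran.append(name)
        log(f"[{name}] done in {time.time() - t0:.1f}s")

    # --- phantom ------------------------------------------------------------
    pdir = out / "phantom"
    image_path = Path(stack_path) if stack_path else pdir / "image.tif"
    if stack_path is None:
        pcfg_d = dict(config.get("phantom", {}))
        pcfg_d["shape"] = tuple(pcfg_d.get("shape", (64, 256, 256)))
        pcfg = PhantomConfig(**pcfg_d, seed=seed)

        def do_phantom():
            stack, truth = generate_phantom_stack(pcfg)
            save_phantom(stack, truth, pcfg, pdir)

        stage("phantom", {"cfg": str(pcfg)}, [],
              [pdir / "image.tif", pdir / "cells.tif", pdir / "phantom.json"], do_phantom)

    tcfg_d = config.get("train", {})
    classes = list(tcfg_d.get("classes", ["nucleus"]))
    stride = int(tcfg_d.get("label_stride", 10))
    tile = int(tcfg_d.get("tile_px", 64))

    stack = equalize_stack(read_stack(image_path))
    voxels = stack.voxels

    def label_volume(cls):
        name = "cells.tif" if cls == "cell" else f"{cls}.tif"
        return tifffile.imread(pdir / name)

    # --- train + predict per class -------------------------------------------
    prob_paths = {}
    for cls in classes + (["cell"] if "cell" not in classes and config.get("separate") else []):
        heads = 2 if cls == "cell" else 1
        ckpt = out / f"model_{cls}.npz"
        tparams = {k: tcfg_d.get(k) for k in sorted(tcfg_d)} | {"class": cls, "seed": seed}

        def do_train(cls=cls, ckpt=ckpt, heads=heads):
            labels = make_sparse_labels(label_volume(cls), stride, class_name=cls)
            cfg = TrainConfig(updates=int(tcfg_d.get("updates", 60)),
                              tile_px=tile, context_px=int(tcfg_d.get("context_px", tile)),
                              seed=seed)
            model = build_model(ModelSpec(base_filters=int(tcfg_d.get("base_filters", 4)),
                                          in_size=(tile, tile), heads=heads), seed=seed)
            model, _ = train(model, voxels, labels, cfg)
            save_checkpoint(model, ckpt, cfg)

        label_file = pdir / ("cells.tif" if cls == "cell" else f"{cls}.tif")
        stage(f"train[{cls}]", tparams, [image_path, label_file], [ckpt], do_train)

        prob = out / f"prob_{cls}.tif"
        pcfg2 = dict(config.get("predict", {}))

        def do_predict(cls=cls, ckpt=ckpt, prob=prob):
            model = load_checkpoint(ckpt)
            p = predict_stack(model, voxels, tile_px=int(pcfg2.get("tile_px", tile)),
                              overlap_px=int(pcfg2.get("overlap_px", tile // 2)),
                              alpha=float(pcfg2.get("alpha", 0.5)))
            tifffile.imwrite(prob, np.asarray(p, dtype=np.float32), photometric='minisblack')

        stage(f"predict[{cls}]", pcfg2 | {"class": cls}, [ckpt, image_path], [prob], do_predict)
        prob_paths[cls] = prob

    # --- split cells ----------------------------------------------------------
    cells_path = out / "cells_separated.tif"
    islands_path = out / "islands.tif"
    scfg = dict(config.get("separate", {}))
    if "cell" in prob_paths:
        def do_separate():
            p = tifffile.imread(prob_paths["cell"])
            mask = threshold_map(p[0])
            boundary = threshold_map(p[1])
            sparse = make_sparse_labels(label_volume("cell"), stride, class_name="cell")
            method = cs.FusionMethod(scfg.get("method", "selective"))
            cells, islands = cs.separate_stack(voxels, sparse, mask, boundary, method,
                                               boundary_thickness_px=int(scfg.get("boundary_thickness_px", 3)))
            tifffile.imwrite(cells_path, cells, photometric='minisblack')
            tifffile.imwrite(islands_path, islands, photometric='minisblack')

        stage("split-cells", scfg, [prob_paths["cell"], image_path],
              [cells_path, islands_path], do_separate)

        # --- track ------------------------------------------------------------
        tracked_path = out / "tracked.tif"
        kcfg = dict(config.get("track", {}))

        def do_track():
            cells = tifffile.imread(cells_path)
            islands = tifffile.imread(islands_path)
            win = int(kcfg.get("window_px", 512))
            mains = pt.track_main_cells(cells, window_px=win)
            isl = pt.track_islands(islands, cells, mains, window_px=win,
                                   min_region_px=int(kcfg.get("min_island_px", 20)))
            vol = pt.apply_tracks(cells, mains)
            vol_isl = pt.apply_tracks(islands, isl, min_region_px=int(kcfg.get("min_island_px", 20)))
            merged = np.where(vol > 0, vol, vol_isl)
            tifffile.imwrite(tracked_path, merged, photometric='minisblack')

        stage("track", kcfg, [cells_path, islands_path], [tracked_path], do_track)

        # --- features -----------------------------------------------------------
        feats_path = out / "features.csv"
        fcfg = dict(config.get("features", {}))

        def do_features():
            tracked = tifffile.imread(tracked_path)
            organelles = {}
            for cls in classes:
                if cls != "cell":
                    pth = out / f"prob_{cls}.tif"
                    from scipy import ndimage as ndi
                    m = threshold_map(tifffile.imread(pth))
                    lab, _ = ndi.label(m)
                    organelles[cls] = lab
            df = feat.per_cell_report(tracked, organelles, voxels,
                                      voxel_size_nm=stack.voxel_size_nm,
                                      compute_texture=bool(fcfg.get("compute_texture", False)))
            df.to_csv(feats_path, index=False)

        stage("features", fcfg, [tracked_path], [feats_path], do_features)

    # --- evaluate --------------------------------------------------------------
    if stack_path is None:
        eval_path = out / "evaluation.csv"

        def do_evaluate():
            import pandas as pd

            rows = []
            train_slices = set(range(0, voxels.shape[0], stride))
            held = [z for z in range(voxels.shape[0]) if z not in train_slices]
            for cls in classes:
                if cls == "cell":
                    continue
                pred = threshold_map(tifffile.imread(out / f"prob_{cls}.tif"))
                truth = label_volume(cls) > 0
                r = metrics.evaluate(pred[held], truth[held])
                rows.append({"class": cls, "dice": r.dice, "precision": r.precision,
                             "recall": r.recall, "n_slices": len(held)})
            pd.DataFrame(rows).to_csv(eval_path, index=False)

        inputs = [out / f"prob_{c}.tif" for c in classes if c != "cell"]
        if inputs:
            stage("evaluate", {"classes": classes}, inputs, [eval_path], do_evaluate)

    log(f"pipeline complete: {len(ran)} stage(s) ran, {len(skipped)} skipped")
    return out


def export_mesh(label_volume: np.ndarray, ids, out_dir, fmt: str = "ply"):
    """One isosurface mesh per requested label id (PLY/OBJ via trimesh).

    Absent ids are listed in the returned report instead of failing.
    """
    import trimesh
    from skimage.measure import marching_cubes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"written": [], "missing": []}
    vol = np.asarray(label_volume)
    for i in ids:
        mask = vol == i
        if not mask.any():
            report["missing"].append(int(i))
            continue
        verts, faces, _, _ = marching_cubes(np.pad(mask, 1).astype(float), level=0.5)
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        path = out / f"label_{int(i)}.{fmt}"
        mesh.export(path)
        report["written"].append(str(path))
    return report
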