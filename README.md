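# vemseg

Segmentation and quantification of cells and subcellular ultrastructure in
sparsely labeled 3D FIB-SEM image stacks.

Volume electron microscopy of tissue (FIB-SEM) resolves nuclei, nucleoli,
mitochondria, endosomes and lysosomes at nanometer scale, but turning a
multi-thousand-slice stack into labeled objects normally means months of
manual annotation. `vemseg` implements the sparse-label workflow for this
problem, aimed at microscopy/image-analysis groups working with tumor or
tissue vEM data:

* a **residual U-Net** (pre-activation residual blocks, strided encoder,
  skip-concatenating decoder, sigmoid head) trained with the **soft Dice
  loss** on a handful of annotated slices — as few as 7 — drawn evenly
  from the stack, with a nucleolus-aware batch sampler for very sparse
  classes;
* **tiled inference** with tapered-cosine (Tukey) blending and inclusive
  0.5 thresholding, so full-width slices are predicted seam-free;
* **cell separation** for touching cells whose shared membranes the
  network cannot see: cell boundaries are propagated from annotated
  slices with **Farneback dense optical flow**, fused with the network
  boundary (overlay / selective / frame-chained strategies), and split by
  a **seeded watershed** on the distance transform;
* **protrusion tracking**: filopodium-like protrusions appear in single
  slices as island blobs detached from any cell; islands are tracked
  along z by maximum **IoU** in a local 512×512 window and retroactively
  relabeled to the cell they meet;
* a **3D morphology and texture suite**: solidity, sphericity
  π^⅓(6V)^⅔/A, circular variance, fenestrated volume percentage,
  nucleolus-to-membrane proximity d_cc/(d_cc+d_s), 26-offset GLCM
  features, gray-level size-zone features, and a granulometric pattern
  spectrum;
* a **synthetic phantom generator** producing FIB-SEM-like stacks with
  complete ground truth (packed cells with partially invisible membranes,
  oblique protrusions, fenestrated nucleoli, brightness jitter, noise) so
  the whole pipeline is testable without external data.

The network and the optical flow run on a compact numpy autograd engine
included in the package; no GPU or deep-learning framework is required.

## Worked example

Separate touching cells on a phantom whose cell-cell membranes are 75%
invisible, comparing the three boundary-fusion strategies against using
the network mask alone:

```python
import numpy as np
from scipy import ndimage as ndi
from vemseg.phantom import PhantomConfig, generate_phantom_stack, make_sparse_labels
from vemseg.stack_io import equalize_stack
from vemseg.cell_separation import FusionMethod, separate_stack
from vemseg.metrics import pooled_label_dice

cfg = PhantomConfig(membrane_visible_fraction=0.25, seed=21)
stack, truth = generate_phantom_stack(cfg)
eq = equalize_stack(stack)

# what a boundary-aware network could see: foreground everywhere,
# boundaries only where a membrane is actually rendered
cells = truth.cell_labels
vis = set(truth.visible_interfaces)
net_mask = np.zeros(cells.shape, np.uint8)
net_boundary = np.zeros(cells.shape, np.uint8)
for z in range(cells.shape[0]):
    lab = cells[z]
    b = (lab > 0) & ndi.binary_dilation(lab == 0)
    for (a, c) in vis:
        ma, mc = lab == a, lab == c
        b |= (ma & ndi.binary_dilation(mc, iterations=2)) | \
             (mc & ndi.binary_dilation(ma, iterations=2))
    net_boundary[z] = b
    net_mask[z] = (lab > 0) & ~b

sparse = make_sparse_labels(truth, 10, class_name="cell")   # slices 0,10,...,60
held = [z for z in range(64) if z % 10 != 0]
for name, method in [("mask alone", None),
                     ("overlay", FusionMethod.OVERLAY),
                     ("selective", FusionMethod.SELECTIVE),
                     ("frame-chained", FusionMethod.FRAME_CHAINED)]:
    pred, _ = separate_stack(eq.voxels, sparse, net_mask, net_boundary, method)
    print(f"{name:14s} pooled cell Dice = "
          f"{pooled_label_dice(pred[held], truth.cell_labels[held]):.3f}")
```

Output:

```
mask alone     pooled cell Dice = 0.379
overlay        pooled cell Dice = 0.916
selective      pooled cell Dice = 0.916
frame-chained  pooled cell Dice = 0.767
```

With no barrier, the watershed mis-partitions the merged foreground
(Dice 0.38). Every flow-fusion strategy recovers the individual cells;
here overlay and selective coincide because almost all interfaces need
the propagated boundary, and frame-chaining trails slightly because
watershed errors accumulate between annotated slices.

The same workflow runs from the shell:

```bash
vemseg phantom --out run/phantom --seed 11
vemseg train --class nucleus --stack run/phantom/image.tif \
             --labels run/phantom/nucleus.tif --stride 10 \
             --updates 1500 --base-filters 8 --tile 64 --out run/nucleus.npz
vemseg predict --model run/nucleus.npz --stack run/phantom/image.tif \
               --out run/prob_nucleus.tif
vemseg run --out run/full          # whole pipeline with cached stages
```

On a 64×256×256 phantom with 7 labeled slices, the 1500-update,
8-filter configuration above reaches a held-out nucleus Dice of ≈0.97 in
about 4 minutes on one CPU core (`tests/test_acceptance.py` runs exactly
this experiment).

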