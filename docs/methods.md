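# Methods

## Problem setting

Volume electron microscopy (FIB-SEM) of tumor tissue produces isotropic 3D
stacks in which organelles — nuclei, nucleoli, mitochondria, endosomes,
lysosomes — are well contrasted, while the membranes separating adjacent
cells are often invisible. `vemseg` implements the sparse-label workflow
for such stacks: a 2D residual U-Net is trained on a handful of annotated
slices and used to segment the rest; touching cells are separated by
combining the network's boundary output with cell boundaries propagated
from annotated slices by dense optical flow, followed by a seeded
watershed; the island-like 2D cross-sections of filopodium-like
protrusions are associated with their parent cells by IoU tracking along
z; and segmented objects are quantified with 3D morphology and texture
features.

## Synthetic phantom

No public FIB-SEM volume ships with the package, so all end-to-end
behavior is validated on a seeded phantom with complete ground truth.

Geometry. Cells are a Voronoi partition of an elliptic cylinder that runs
through the whole z range. A real FIB-SEM crop is a few hundred nanometers
deep — far less than a cell diameter — so cells and nuclei must cross the
entire stack; an earlier ellipsoidal design produced nucleus-free slices
near the z poles whose equalized histograms remapped cytoplasm onto
nucleus gray levels, a content artifact no 2D model can resolve, and was
replaced for that reason. The Voronoi z-distance is down-weighted (factor
0.09 on the squared difference) so inter-cell boundaries drift slowly with
depth, giving the optical-flow stage realistic inter-slice motion.
Protrusions are straight tubes (radius 4 px, length 18–36 px) leaving the
cell surface at 30–60° to the imaging plane; the generator resamples a
tube until it has at least one slice where its cross-section is attached
to the cell body in-plane (a protrusion emerges laterally through the
membrane) and at least one slice where it is detached — the island
configuration the tracker must resolve. Every adjacent-cell interface is
rendered with a dark membrane only with probability
`membrane_visible_fraction` (default 0.6); external cell surfaces are
always membranous. Nuclei carry envelope dents and a low-amplitude
chromatin-like texture; each nucleus holds 1–6 nucleoli; nucleoli are
fenestrated by interior spherical cavities carved until a target cavity
fraction (default 0.125) is reached, which makes the fenestrated-volume
measure testable against an analytic value. Mitochondria are small
stretched ellipsoids; endosomes and lysosomes are darker spheres.

Rendering. 8-bit intensities with fixed class means (background 195,
cytoplasm 150, nucleus 120, mitochondrion 95, nucleolus 70, endosome 55,
lysosome 35, membrane 40), per-slice uniform brightness jitter (±25 gray
levels, exercising histogram equalization) and additive Gaussian noise
(σ = 5). All randomness flows from one seed; identical (config, seed)
pairs are bit-identical.

What the phantom does not emulate: electron-optics physics, curtaining and
charging artifacts, anisotropic voxels, membrane thickness variation, and
the intra-class intensity diversity of real tissue. Passing the recovery
suites therefore demonstrates that the algorithms are implemented
correctly and are learnable/stable under controlled conditions — not that
the reported Dice levels transfer to any particular real dataset.

## Preprocessing

Each slice is globally histogram-equalized over 256 bins (constant slices
pass through with a warning). Per-slice global equalization — rather than
CLAHE — matches the motivation: inter-slice brightness drift, not
intra-slice contrast. Equalization maps brightness-shifted copies of the
same scene to identical outputs, and is idempotent up to one gray level.

## Segmentation network

A pre-activation residual U-Net: four encoder residual blocks (each
batch-norm → ReLU → 3×3 conv twice, plus a projection shortcut where
shape changes), the first convolution of each block strided so the
spatial size halves while feature count doubles; a bridge block at 1/16
resolution; four decoder steps of nearest-neighbor 2× upsampling followed
by a 2×2 convolution halving the features, concatenation with the
matching encoder map (the full-resolution step concatenates the input
image), and a residual block. A 1×1 convolution with sigmoid yields one
output head for organelle tasks or two (interior mask + boundary) for the
cell task, trained with equally weighted summed Dice losses.

The network, its batch normalization, and Adam are implemented on a small
tape-based autograd over float32 numpy arrays (`vemseg.nn`). Convolution
is evaluated as a shift-accumulate — one BLAS matmul contracts the channel
dimension for all k² kernel offsets over the full padded grid, and the
partial products are added at their spatial shifts — which avoids im2col
copies and keeps single-core CPU training practical. Weights use He
fan-in initialization drawn from the model seed; checkpoints (weights +
batch-norm statistics + architecture/training configs) round-trip
bit-exactly through `.npz`.

Training follows the reference configuration: Adam with learning rate
1e-4, β₁ = 0.9, β₂ = 0.999, ε = 1e-7, a fixed number of weight updates,
batches of five tiles sampled from the labeled slices with independent
horizontal/vertical flips. For the nucleolus class — below 1% of a full
image — at least four of the five tiles must contain at least 100
nucleolus pixels; sampling retries are bounded and exhaustion raises with
a hint to lower the threshold. Tiles may be cropped at a larger context
size and mean-pool downsampled to the network input (the 2048→512 scheme);
labels are subsampled by striding, and context predictions are bilinearly
upsampled back before blending. The soft Dice loss uses the
squared-denominator form with smoothing ε_s = 1.0 in numerator and
denominator — a standard stabilization; with a uniform 0.5 prediction on a
half-foreground tile it evaluates to 1/3, which the tests pin.

Desk scale. The full-scale configuration (512×512 tiles, 32 base
filters, 5000 updates) is the default; the validation experiments in this
repository run the same algorithm at 64×64 tiles, 8 base filters and 1500
updates on 64×256×256 phantoms with 7 labeled slices — the smallest
training-set regime the sparse-label workflow targets — where held-out
nucleus Dice reaches ≈0.97. Problem sizes were chosen so the full suite
runs on a single CPU core.

## Tiled inference

Slices larger than the network input are parsed into overlapping tiles
(default overlap: half a tile). Each tile's probability map is multiplied
by a separable 2D Tukey window (α = 0.5 default) and accumulated; the
accumulated sum is divided by the accumulated window weight, so a constant
field is reproduced exactly (a partition of unity after normalization —
without the normalization a constant could not be reproduced, which is why
it is part of the contract). Edge tiles come from reflect-padding, and
window values are floored at 1e-3 during accumulation so every pixel
keeps positive weight even at α = 1. The blended map is thresholded at
0.5, inclusive.

## Cell separation

Dense optical flow between adjacent equalized slices uses a from-scratch
implementation of Farneback's polynomial-expansion algorithm (quadratic
local models under a Gaussian applicability; per-pixel normal equations
averaged over a box window; coarse-to-fine pyramid with warping
iterations). The parameter set follows the reference configuration:
6 pyramid levels, scale 0.2, 3 iterations, polynomial neighborhood 5,
averaging window 30. Pyramid levels that would shrink an image below a
usable size are skipped. On synthetic translations the implementation
recovers a 4 px shift with sub-half-pixel median error.

Labels are propagated from each unlabeled slice's nearest annotated slice
(ties to the lower index), chaining one-slice warps because flow accuracy
decays with distance. Three fusion rules combine the network boundary
with the propagated labels: OVERLAY burns all propagated boundaries onto
the network mask; SELECTIVE keeps the network boundary and adds
propagated boundaries only inside mask components containing ≥2 distinct
propagated labels of ≥50 px each (the operationalization of "regions with
overlapping cells"); FRAME_CHAINED applies the SELECTIVE rule but
propagates each slice's final fused segmentation to the next slice.
Passing `method=None` runs the mask-alone ablation baseline. The interior
mask is then split by watershed on the negated distance transform, seeded
at the centroids of the propagated labels (`seed_mode="warped"`; centroids
of the annotated slice via `seed_mode="gt"` are available, but warped
centroids lie nearer the true position). Seeds outside the interior snap
to the nearest interior pixel within 50 px, else are dropped with a
warning. Interior components without a seed are returned as candidate
islands. On phantoms with 75% invisible cell-cell interfaces, all three
fusion methods clearly outperform the mask-alone baseline in pooled
per-cell Dice, mirroring the expected ordering.

## Protrusion tracking

Regions are matched slice-to-slice by maximum IoU, with candidates
restricted to a 512×512 window centered on the region's bounding box (an
efficiency device; on phantom-scale motion the windowed result equals
exhaustive global matching, which the tests verify). Main cell bodies are
tracked first, keeping the ids assigned at separation; new regions with no
overlap receive fresh labels. Islands are then tracked against both the
previous slice's islands and its cell regions: when an island's best
predecessor is a cell region, the island's entire track — including all
earlier slices — is relabeled to that cell id, and keeps it if the
protrusion later detaches. The converse event (an island track ends
because its continuation was absorbed into the cell body) also merges the
track, but only when the cell covers at least half of the island's last
section — a grazing 1–2 px overlap with a passing neighbor cell must not
capture the track. Ties break by overlap area, then the smaller label.
Islands below 20 px are discarded as specks. On the standard phantom,
retroactive merging assigns >95% of protrusion voxels their true parent
cell id.

## Morphology and texture features

Morphology (per object, on voxel masks):

* solidity — volume over the rasterized convex hull volume (hull over
  voxel centers, rasterized back to the grid so convex digital bodies
  score 1);
* sphericity — π^{1/3}(6V)^{2/3}/A with V the voxel count and A from a
  marching-cubes isosurface of the lightly smoothed mask (raw binary
  meshes overestimate area ≈8% and would bias the measure low);
* circular variance — the variance of surface-voxel radii about the mean
  radius, normalized by μ_r², making it scale-invariant;
* fenestrated volume percentage — 100·(filled − net)/filled after 3D hole
  filling; open surface dents do not count, distinguishing the measure
  from solidity;
* nuclear-membrane proximity — d_cc/(d_cc + d_s) with d_cc the
  nucleus–nucleolus centroid distance and d_s the distance from the
  nucleolus centroid to the nearest nuclear surface voxel; 0 when
  centered, →1 at the envelope.

Texture (per object, after quantizing the masked intensities to 32
uniform bins over their min–max range — hence invariance to constant
intensity shifts):

* GLCM — co-occurrences accumulated symmetrically over all 26 unit 3D
  offsets restricted to in-mask pairs, then normalized. Homogeneity
  Σp/(1+(i−j)²), contrast Σ(i−j)²p, correlation
  (Σ ijp − μ²)/σ² (reported as 0 with a warning when σ = 0), and variance
  as the dispersion about the marginal mean Σ(i−μ)²p. The source formula
  for variance prints the same expression as contrast, which contradicts
  its own prose description of dispersion; the standard dispersion form is
  used here.
* Size-zone matrix — 26-connected constant-level zones; zone percentage =
  number of zones / number of voxels; SZHGE defaults to the printed
  reading Σ P(i,j)·i² normalized by the zone count, with the conventional
  small-zone form (i²/j²) behind `variant="standard"` — the source's two
  definitions of the normalizer are mutually inconsistent, so both
  readings are preserved rather than guessing; plus the (i, j) centroid
  of the matrix.
* Pattern spectrum — granulometry by openings (n ≥ 0) and closings
  (n < 0) with Euclidean balls of radius |n| (default n_max = 15).
  Because flat-structuring-element gray morphology obeys threshold
  decomposition, each ∫γ_n f is computed as a weighted sum of binary ball
  openings, each evaluated exactly in O(N) with two distance transforms.
  Digital balls only approximately satisfy the sieve axiom, so the
  integral sequences are forced monotone before differencing, which
  guarantees PS_n ≥ 0. The mean and standard deviation of the spectrum
  are reported as summary signatures.

Per-cell reporting assigns each organelle instance to the cell holding the
majority of its voxels (background row if none), and emits per-cell
volume fractions, per-class counts (including nucleoli per nucleus), and
per-instance morphology; texture columns are optional
(`compute_texture=True`) since they dominate runtime on large objects.

## Evaluation

Dice, precision, recall and IoU follow the set-overlap definitions, with
audited conventions for degenerate inputs (empty ground truth → recall 1
with a warning; both masks empty → Dice 1 / IoU 0 with warnings). Instance
segmentations are scored with pooled label Dice: per-id true positives
summed over ids before forming 2TP/(|P|+|G|). Evaluation excludes
training slices. The identity Dice = 2·IoU/(1+IoU) and monotonicity under
correct additions are property-tested.

## Pipeline

`vemseg run` orchestrates phantom → train → predict → split-cells → track
→ features → evaluate with a JSON manifest of parameter and content
hashes; stages re-run only when their inputs or parameters change. Label
volumes export to per-id PLY/OBJ meshes via marching cubes for 3D
rendering.

## Known limitations

* The network engine targets small CPU experiments; it has no GPU path
  and no 3D convolutions (the method is deliberately 2D).
* Stack alignment/registration is out of scope; inputs are assumed
  aligned.
* FRAME_CHAINED accumulates watershed errors along z between anchors and
  can trail the other fusion rules on phantoms even while beating the
  mask-alone baseline.
* Transformer baselines are not included; the model construction is the
  single pluggable seam for alternatives.
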