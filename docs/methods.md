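# Methods

## Pipeline overview

The package reconstructs individual parenchyma cells from micro-CT-like
volumes in five stages:

1. **Cell matrix and pore labelling** (conventional volume): 3×3×3 median
   filter → Otsu threshold over a 256-bin histogram (bright class = cell
   matrix) → morphological opening with a ball element → inversion to the
   pore space → marker-based watershed on the Euclidean distance transform
   (EDT).  Watershed markers are the regional maxima of the EDT after
   H-maxima suppression with depth equal to the *marker extent*; the
   extent is selected among candidates (default 0–4) by the highest
   Calinski–Harabasz index of the voxel-coordinate clustering, subsampled
   to 50 000 voxels with a fixed seed.
2. **Ground-truth cell labels** (contrast-enhanced volume): voxels
   brighter than the cell interiors (walls, contrast-filled pores,
   vasculature, stone cells) are removed with threshold `t_high`; residual
   walls with `t_wall`; the remainder is watershed-segmented, labels below
   `min_cell_volume` are dropped, and each label is dilated by up to
   `dilation_radius` voxels by nearest-label assignment, which cannot
   merge labels.  The interactive steps of a scanner workflow (threshold
   picking, manual tracing of vasculature and stone clusters) are replaced
   by config values and by the phantom generator's structure masks.
3. **Flow-field segmentation**: per 2D slice and per instance, heat is
   repeatedly injected at the cell centre (median pixel, snapped into the
   mask) and diffused by in-mask neighbour averaging for 2× the instance's
   bounding-box extent; the targets are the two unit-normalized spatial
   gradients of log(1+heat) plus the binary ROI mask.  A 2D
   encoder–decoder predicts these three channels on every XY, YZ and XZ
   slice; each 3D vector component is the mean of the two orientations
   that observe it and the ROI the mean of all three.  After multiplying
   the ROI by the binary cell matrix, voxels above `roi_threshold` (0.5)
   are advanced 200 Euler steps of 1 voxel along the unit-normalized
   field; terminal positions are binned to the grid, bins merged by
   26-connectivity, and each attractor basin becomes one label (labels
   below `min_size` dropped).
4. **Benchmark**: the same watershed machinery applied directly to the
   binary cell matrix, swept over marker extents 0–4, best extent by
   highest AJI against ground truth.
5. **Evaluation and morphometry**: Aggregated Jaccard Index with greedy
   matching, and the morphometric parameter vector per sample.

## The network and its training

The encoder–decoder is a U-Net: `depth` resolution levels with two 3×3
convolutions + ReLU each, 2×2 max pooling, nearest-neighbour upsampling
with skip concatenation, and a 1×1 head with three outputs.  It is
implemented directly in numpy (im2col convolutions, manual
backpropagation) so the whole package runs on a plain CPU stack; the
backward pass is verified against finite differences in the test suite.

Training uses RAdam (β₁ = 0.95, β₂ = 0.999, weight decay 10⁻⁵, ε = 10⁻⁸)
with batch size 8 and loss `5 × MSE(gradient channels) + BCE(ROI logit)`.
The full-scale defaults are 250 epochs, 48 base feature maps, depth 4,
initial learning rate 0.002 decayed ×0.1 at epoch 200, with a 10-epoch
linear warmup (without it, a fraction of fresh initializations falls into
a dead-ReLU basin and never recovers).  Augmentation
applies joint flips, 90° rotations and 0.85–1.15× scalings to image and
target, permuting and negating the gradient components consistently with
the spatial transform (verified against recomputed flows on symmetric
instances; the source pixel itself has arbitrary gradient direction and is
excluded from those checks).

**Desk-scale protocol.**  Tests and the acceptance script run a reduced
configuration chosen for CPU minutes rather than GPU hours: 48³-voxel
phantoms, 96 training slices (two phantoms, XY+YZ, spacing 2), 8 base
feature maps, depth 3, 100 epochs at learning rate 0.005 (decay at epoch
80).  With batch size 8 this is ~1200 optimizer steps; the loss plateaus
after roughly half of them.  The learning rate is higher than the
full-scale default because the run is three orders of magnitude shorter;
it was fixed from convergence curves on training data only.

## The synthetic tissue generator

Phantoms emulate the two parenchyma organisations of pome fruit:

* **apple-like** (default: porosity 19%, 200 cells mm⁻³): cells are
  deleted whole and adjacent deletions merge — lysigenous pore formation —
  giving few large, low-SSA pores.  The seed count is inflated by
  1/(1−porosity) so the surviving cell density matches the target.
* **pear-like** (default: porosity 4.5%, 650 cells mm⁻³, 2 stone-cell
  clusters mm⁻³): whole cell-contact faces are opened into one-voxel-thick
  channels — schizogenous pore formation — giving many small, high-SSA,
  connected pores.  `pore_connectivity` sets whether opened faces grow as
  one connected complex (1.0, strongly negative Euler number of the pore
  network) or scatter as isolated patches (small values, positive Euler
  number); the Euler number decreases monotonically in this parameter.

Cells are Voronoi regions of jittered-grid seeds (polyhedral,
space-filling, roughly uniform in size, as in real parenchyma);
`anisotropy_stretch` scales the tessellation metric to elongate cells.
Stone-cell clusters are solid spheres that displace the surrounding label
map through a radial outward warp (surrounding cells wrap around the
cluster); vascular strands are smooth tubes along the z axis.  Cell walls
are the one-voxel one-sided label boundaries; ground-truth labels are the
wall-free cell interiors, which a one-voxel wall still separates under
26-connectivity.

Rendering is a two-level-per-phase intensity model plus additive Gaussian
noise (default SD 5 on a 0–255 scale), not a physics-based CT forward
model: conventional = matrix 150, pores 30, vasculature 170, stone 230,
with *no* contrast at cell–cell interfaces; contrast-enhanced additionally
sets walls and contrast-filled pores to 240.  Downstream stages depend
only on these ordering relations, which is exactly what the renderings
guarantee — but it also means passing tests show correctness of the
*pipeline machinery*, not robustness to beam hardening, rings, partial
volume effects, texture, or registration error, none of which the
generator produces.

**Resolution.**  Real scans resolve parenchyma cells at ~70–90 voxels
across; that is far outside desk-scale budgets, so the default phantoms
emulate a coarser scan (voxel size 24 µm apple / 16 µm pear, 64³ default,
48³ in tests) in which cells are ~9 voxels across while the *physical*
porosity, cell density and stone-cell density keep their realistic
values.  Two consequences are documented rather than hidden: (i) pear
pore channels can cover only a fraction of the cell faces (channel
thickness is resolution-limited), and (ii) the watershed benchmark, whose
markers need pore outlines around most of a cell, under-segments far more
severely than on real data.  The benchmark's label-count property (count ≈
cell count at extent 2) is therefore exercised on a coarse-celled
phantom (96³, ~50 cells, porosity 10%) where pore outlines are resolved;
the qualitative ordering "flow model > benchmark" holds at every scale.

## Evaluation conventions

Greedy AJI matching visits ground-truth labels in ascending id and breaks
Jaccard ties toward the smaller predicted id, making the metric fully
deterministic.  With contended predictions the greedy order can matter;
the metric is therefore invariant under order-preserving relabelings (and
under arbitrary relabelings when objects are uncontended), and the greedy
result is verified against an exhaustive sequential-best assignment oracle
on hundreds of random volumes.  Predicted labels that overlap no
ground-truth label enter the false-positive set `U`; unmatched ground-truth
labels contribute `|G_i|` to the denominator.

## Morphometry

* **Surface area**: marching-cubes boundary mesh with 10 iterations of
  shrink-free Taubin smoothing.  Voxel-face counting overestimates a
  sphere's area by ~50% and raw marching cubes by ~9%; the smoothed mesh
  is within ~2% of 4πr² for a radius-20 ball and ~4% of 6s² for a cube,
  the two closed-form oracles in the tests.
* **Anisotropy** has two estimators: sample level uses the
  mean-intercept-length fabric tensor over 128 uniform directions (MIL(u)
  = 2V/S(u) with S(u) the boundary area projected onto u, tensor fitted to
  1/MIL²); object level uses the voxel-coordinate covariance tensor.  Both
  report 1 − λ_min/λ_max.
* **Euler number**: 26-connected foreground (ball 1, torus 0, shell 2;
  a well-tunnelled pore network is negative).
* **Distribution statistics** per object parameter: mean, SD, mode
  (midpoint of the densest Freedman–Diaconis bin, Sturges fallback), IQR
  (linear-interpolation quartiles), Fisher skewness g₁ and *excess*
  kurtosis g₂.  Border-touching objects are excluded from the statistics
  (their truncated shapes bias size metrics) but flagged in the per-object
  table.  The parameter vector concatenates the 11 sample-level values
  with 6 statistics × 8 object parameters × {cells, pores} = 107 named
  entries; the schema is fixed across samples.

## Numerical choices and degenerate inputs

* Otsu thresholding errors on constant volumes; watershed returns an empty
  labelling for an empty mask, and components whose maxima were all
  suppressed by H-maxima still receive one label each (every foreground
  voxel is labelled).
* Gradient tracking normalizes the field to unit steps (direction is
  trustworthy where magnitude is not, because slice averaging and
  regression shrinkage attenuate predicted magnitudes); voxels with
  magnitude < 0.05 stay put, so a zero field reduces clustering to
  connected components.
* Dilation of ground-truth labels is nearest-label assignment
  (`expand_labels`), never free morphological dilation, so labels cannot
  merge.
* `min_cell_volume` (default 64 voxels) and `min_size` (default 64) are
  debris filters tuned to full-scale resolution; phantom-scale runs pass
  8–16 because a 64-voxel object at 24 µm voxels is a legitimate small
  cell.
* All randomness flows from integer seeds through named
  `numpy.random.Generator` instances; identical configs give bit-identical
  phantoms and, up to BLAS reduction order, identical training runs.

## Known limitations

* The grayscale model has no texture: a network trained on phantoms
  learns geometry-from-pores, not the subtle interface cues present in
  real scans, so desk-scale AJIs (~0.3 apple, ~0.4 pear) sit well below
  full-scale values.  The ordering "flow model ≫ watershed benchmark"
  holds for both styles with large margins; the apple-vs-pear ordering,
  however, *inverts* at desk scale: the pear phantom's schizogenous
  channels are fully resolved one-voxel seams along many cell faces — a
  stronger learning cue than apple's cell-sized pores — whereas in real
  2.5 µm pear scans those channels are sub-voxel, noisy, and confounded
  by stone clusters.  The relative difficulty of pear tissue is an
  emergent property of real contrast that the two-level rendering cannot
  reproduce, and the acceptance suite reports this honestly rather than
  degrading the pear phantom to force the ordering.
* The per-sample parameter list approximates the field's usual 80-odd
  parameters; the exact composition of published parameter sets varies
  and the count here (107) is documented rather than matched.
* Isotropic voxels are assumed throughout; stone-cell interiors are
  rendered as a single solid intensity; style/texture embeddings of
  generalist segmentation models are out of scope.
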