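# cfcnn — central-focused CNN lung-nodule segmentation

Segmenting lung nodules in chest CT is hard because nodules are
heterogeneous (solid, cavitary, calcified, ground-glass) and often share
intensity with what they touch — the pleural wall, vessels. `cfcnn`
implements a voxel-classification approach to this problem as a pure-Python
library, built so that every stage is verifiable on synthetic CT phantoms
with exact ground truth, with no clinical data or GPU required.

The method, in the field's standard notation:

* **Two-branch patch network.** For each voxel, a 3-D branch sees the
  z-scored tri-slice neighbourhood (3 × 35 × 35) and a 2-D branch sees a
  two-channel multi-scale axial patch (a 65 × 65 context patch downscaled to
  35 × 35 by third-order spline interpolation, stacked with the native
  35 × 35 patch). Each branch is three blocks of two 3 × 3 convolutions
  (batch norm + PReLU, slope a_j initialised to 0.25) with a pooling layer
  between blocks; branch features are fused by fully connected layers into
  a binary softmax p(nodule).
* **Central pooling.** Instead of uniform 2 × 2 max pooling, each axis of
  length *O* is tiled by 1-D max-pooling kernels of sizes s ∈ {1, 2, 3}
  with counts solving n₁ + 2n₂ + 3n₃ = O, n₁ + n₂ + n₃ = O/2, n₁ + n₃ = n₂
  (floors plus a fixed residual look-up table when O is not divisible by 8),
  laid out symmetrically with the size-1 kernels at the centre — features at
  the patch centre, i.e. at the voxel being classified, pass through
  unpooled. The layer ships with an exact argmax-routing backward pass.
* **Difficulty-weighted sampling.** Training voxels are drawn per slice
  from an 8-voxel-expanded nodule bounding box: nodule voxels with weight
  PWᵢ = exp(−min_{j∈N} d(i,j))/Z (edges preferred), background voxels with
  NWᵢ = Iᵢ·exp(−min_{j∈P} d(i,j))/Z (bright, nodule-adjacent structures
  preferred; the dark lung field suppressed); 40% of nodule voxels and the
  same number of background voxels per slice, so classes stay balanced.
* **Training.** Cross-entropy plus 1-norm weight regularisation
  (λ = 5·10⁻⁴), momentum SGD (μ = 0.9, batch 128) under the inverse decay
  αₜ = α₀(1 + γt)^(−p) with α₀ = 6·10⁻⁵, γ = 10⁻⁴, p = 0.75.
* **3-D segmentation by slice propagation.** From a user box on one
  starting slice, voxels inside the box are classified, the probability map
  thresholded at 0.5, and the connected component nearest the box centre
  kept; the same box then walks to preceding and subsequent slices, keeping
  the component nearest the previous slice's centroid, until a slice is
  empty or its area drops below 30% of the preceding kept area.
* **Evaluation.** Dice, Jaccard overlap, sensitivity, positive predictive
  value, and symmetric average surface distance in millimetres, plus
  50%-consensus fusion of multi-rater ground truth.

## Worked example

`examples/` holds one short script per capability. The pooling-plan demo:

```bash
$ python examples/01_central_pooling_plan.py
axis length 9 -> n1=2, n2=2, n3=1 (residual 1)
kernel layout: [3, 2, 1, 1, 2]
  -> size-1 kernels sit at the axis centre: centre voxels pass through
axis 35 -> output 18 with counts (5, 9, 4)
axis 18 -> output 9 with counts (2, 5, 2)
```

A 9-voxel axis gets two size-1 kernels, two size-2 and one size-3, laid out
{3, 2, 1, 1, 2}; the network's 35 × 35 patches pool to 18 and then 9. The
oracle demo isolates the 3-D propagation rules from model quality:

```bash
$ python examples/03_oracle_segmentation.py
kept slices and areas: {10: 21, 11: 57, ..., 16: 137, ..., 22: 21}
stopped going up: empty_slice; down: empty_slice
dice=1.0000 jaccard=1.0000 asd=0.0000 mm
```

With a perfect classifier the box/threshold/component/propagation chain
reconstructs a spherical phantom exactly and stops at the empty slices
beyond its poles. `examples/05_train_and_evaluate.py` runs the full
desk-scale experiment — generate a seeded phantom cohort, draw weighted
training patches, train the slimmed network on CPU, segment held-out
phantoms, print the per-case dice / Jaccard / SEN / PPV / ASD table and its
mean ± sd summary (a few minutes on one CPU).

## Acceptance script

`scripts/acceptance.py` recomputes the package's reference quantities from
scratch by running the library — the central-pooling kernel-count solver at
axis length 9 and the residual look-up table with its column-coverage
identity — and writes them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/cfcnn/
  volumes.py       NIfTI I/O, CtVolume / NoduleMask / BoundingBox2D
  phantoms.py      synthetic CT nodule phantoms (isolated, juxtapleural,
                   cavitary, calcific, GGO) with exact ground truth
  patches.py       tri-slice 3-D and multi-scale 2-D patch extraction
  pooling.py       central pooling: solver, look-up table, forward/backward
  model.py         the two-branch network, loss, schedule, momentum SGD
  sampling.py      difficulty-weighted training-voxel selection
  segmentation.py  slice classification, component selection, propagation
  metrics.py       DSC / Jaccard / SEN / PPV / ASD, consensus fusion
  pipeline.py      end-to-end seeded experiment driver (YAML configs)
```

See `docs/methods.md` for the modelling assumptions, numerical choices and
the limits of what phantom-scale verification establishes.
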