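# Methods

This note records the model, the assumptions behind the synthetic data, the
numerical choices, and what the test suite does and does not establish.

## The segmentation model

`cfcnn` treats nodule segmentation as per-voxel binary classification
followed by rule-based 3-D assembly. The classifier is a two-branch
convolutional network over two views of the same voxel:

* **3-D branch input** — the 35 × 35 axial neighbourhood on the voxel's own
  slice plus the preceding and subsequent slices, stacked as a 3-channel
  image and z-scored jointly (f(x) = (x − x̄)/s over all patch voxels).
  Because every patch is z-scored, the global intensity scale of the volume
  is irrelevant; raw HU-like values are passed through unwindowed.
* **2-D branch input** — a 65 × 65 axial context patch downscaled to
  35 × 35 by third-order spline interpolation, stacked with the native
  35 × 35 patch; channels z-scored independently. Independent per-channel
  z-scoring (a package choice, switchable via `PatchSpec.normalize_2d`)
  keeps both branches on the same input scale.

Each branch is `[conv 3×3 → BN → PReLU] × 2`, central pooling (35 → 18),
the same block pair, central pooling (18 → 9), a third block pair, then a
fully connected layer with PReLU. Branch outputs are concatenated, fused by
another FC + PReLU, and a linear layer feeds the binary softmax.
Convolutions are zero-padded "same", so the two pooling stages alone govern
spatial size; filter counts default to (36, 36)/(72, 72)/(108, 108) with FC
widths 256/128, all configurable (`ModelConfig.tiny()` shrinks everything
for CPU-scale work). Weights are Xavier-uniform initialised; PReLU slopes
start at 0.25.

### Central pooling

For an axis of length O, kernel counts (n₁, n₂, n₃) for 1-D max-pooling
kernels of sizes 1/2/3 solve: total length O, output O/2, half the kernels
size 2. The ideal solution (O/8, O/4, O/8) is floored and the *coverage
residual* r = O − (⌊O/8⌋ + 2⌊O/4⌋ + 3⌊O/8⌋) ∈ [0, 7] is converted into
extra kernels by a fixed look-up table whose column r always covers exactly
r voxels. Columns r = 6, 7 are included for completeness although the
coverage residual never exceeds 5.

Layout: size-3 kernels outermost, the size-1 run centred. The run is
centred by splitting the *combined* size-2/3 flank between the two halves
(odd remainders to the left) rather than splitting each size independently;
this reproduces the canonical {3, 2, 1, 1, 2} layout for counts (2, 2, 1)
and guarantees that an odd-length output with any size-1 kernels has a
size-1 window at its centre — the property that motivates the layer.

Row pooling is applied first, then column pooling; the composition equals a
max over the rectangles formed by the two axis tilings, which is how the
forward pass is implemented. The backward pass routes each upstream
gradient to the recorded argmax coordinate (ties broken by lowest linear
index, making training deterministic); windows never overlap, so no
accumulation ambiguity exists. A uniform all-size-2 plan reproduces classic
2 × 2/stride-2 max pooling bit-exactly and serves as the ablation variant;
for an odd axis the model's uniform variant appends one size-1 kernel at
the edge so both variants share the 35 → 18 → 9 chain and parameter count.

### Training

Loss: mean binary cross-entropy (probabilities clamped at ε = 10⁻⁷) plus
λ Σ|W| with λ = 5·10⁻⁴ over convolution and FC weights and biases — batch
norm parameters and PReLU slopes are exempt. Optimiser: momentum SGD,
V ← μV − α∇L, W ← W + V, μ = 0.9, batch 128, under
αₜ = α₀(1 + γt)^(−p), α₀ = 6·10⁻⁵, γ = 10⁻⁴, p = 0.75. Default budget 21
epochs; after each epoch every validation phantom is segmented end-to-end
and scored by dice, and the best-dice weights are retained (optional early
stopping on that signal). Batch norm uses batch statistics in training and
running statistics (momentum 0.1, unbiased variance) at inference.

The network is implemented directly in numpy with hand-written backward
passes (im2col convolutions, exact BN/PReLU/pooling adjoints), verified by
finite differences end to end. Compute precision is a config switch:
float32 by default for speed, float64 for gradient checks. There is no GPU
path; CPU determinism given the seed is the contract.

## Weighted sampling

Within each slice's nodule bounding box expanded by 8 voxels per side:
nodule voxel weights PWᵢ = exp(−d(i, N))/Z (d = exact 2-D Euclidean
distance transform, voxel units; physical spacing deliberately ignored),
background weights NWᵢ = Iᵢ exp(−d(i, P))/Z with Iᵢ the box-min-max
normalised intensity. If the intensity factor annihilates every background
voxel (constant box, or a uniformly dark background at the box minimum —
common in noise-free phantoms) the weights fall back to distance-only.
Per slice, round(0.4 · #nodule-voxels) nodule draws (round half away from
zero) and the same number of background draws are made without replacement
via exponential-key sorting, which is equivalent to sequential
probability-proportional draws. The 40% fraction is applied per slice, so
every nodule contributes samples regardless of size.

A consequence worth knowing: deep dark lung-field voxels are essentially
never sampled (their weight carries both a small Iᵢ and exp(−d) decay), so
the classifier's output there is weakly constrained early in training.
The 3-D assembly rules — component selection and the propagation stops —
exist precisely to discard such stray responses.

## 3-D assembly

Probability ≥ 0.5 is nodule (inclusive threshold; the binarisation rule is
a package choice). In-plane components are 8-connected. The starting slice
keeps the component nearest the box centre; propagated slices keep the one
nearest the preceding slice's kept centroid (centroids are unweighted voxel
means; ties keep the larger area, then the lower first-voxel index).
Propagation in each direction stops at an empty slice or when the kept area
falls strictly below 30% of the preceding kept area — the comparison uses
the post-component-selection area, and the starting slice itself is exempt.
The violating slice is excluded.

## Metrics

DSC = 2|Gt∩Auto|/(|Gt|+|Auto|); Jaccard overlap |∩|/|∪| (= D/(2−D));
SEN = |∩|/|Gt|; PPV = |∩|/|Auto|. ASD is computed on 3-D surfaces: a
surface voxel has at least one non-mask 6-neighbour (volume borders count
as outside); voxel centres are scaled anisotropically by the spacing and
the symmetric mean of directed mean-minimum distances is reported in mm.
Consensus ground truth includes a voxel marked by ≥ 50% of raters (exact
halves included). Cohort summaries report mean ± sample (n−1) sd.

## Synthetic phantoms: what they are and are not

Phantoms are ellipsoidal nodules in a uniform lung field (−800 HU) with
optional wall slab (30 HU), calcified core (300 HU), internal air cavity
(kept inside the ground-truth mask — a cavity belongs to its nodule),
reduced-contrast GGO variant, tangent vessel cylinder, and additive
Gaussian noise (default sd 20 HU). These levels are typical clinical
magnitudes; the defaults are fixed once and not tuned per experiment.
Phantoms exercise the *local intensity structure* the patch classifier
consumes — contrast, edges, wall adjacency, cavities — and give exact
ground truth for every stage.

They do not contain lung texture, partial-volume effects, respiratory
artefacts, or annotation ambiguity. A green phantom test therefore
establishes that the machinery is implemented correctly and can learn and
reconstruct nodules under realistic contrast and noise — not that
clinical-scale accuracy figures are reproduced. Full-scale benchmarking on
clinical datasets is explicitly out of scope.

One geometric subtlety: a lattice sphere of integer radius has single-voxel
polar slices whose area ratio trips the 30% stop rule, so the
reconstruction (correctly, per the rules) omits the poles; half-integer
radii avoid the degeneracy, which is why exactness demonstrations use
radius 6.5.

## Desk-scale experiment

The end-to-end smoke experiment (`pipeline.run_pipeline`, exercised by the
acceptance suite and `examples/05`) generates 30 seeded phantoms
(17 train / 1 validation / 12 test; 60% isolated, 40% GGO), radius 5 ± 20%
in 28 × 56 × 56 volumes — scaled down from clinical dimensions purely for
CPU budget — draws the 40% weighted sample (~7.5k patches), trains a
slimmed network ((4,4)/(6,6)/(8,8) filters, FC 24/12) with the stated
optimiser settings for up to 14 epochs with early stopping (patience 4),
and segments the held-out phantoms (mean test dice ≈ 0.87 at seed 1, about
ten CPU-minutes). All randomness flows from one seed through per-stage
derived seeds, so a run is reproducible end to end.

The smoke cohort deliberately contains the easy nodule classes. At this
training budget (~1.5k SGD steps versus the ~67k implied by full-scale
data) the juxtapleural wall-versus-nodule distinction is undertrained and
the mask leaks into the wall; juxtapleural phantoms are still generated by
the pipeline's default mix and exercised by the generator and
oracle-classifier tests, but their quantitative parity is a full-scale
result, not a desk-scale one.

## Known limitations

* Patch extraction is reflect-padded at volume borders; a nodule hugging
  the volume edge sees mirrored context no scanner would produce.
* The sampler never sees deep lung-field patches (by design of the
  weighting); stray classifier responses there are handled by the assembly
  rules rather than prevented.
* Training-time batch norm couples samples within a batch, so exact loss
  values depend on batch composition; determinism holds for a fixed seed
  but not across batch-size changes.
* Multi-nodule volumes and automatic nodule detection are out of scope;
  the user-supplied starting box defines the target.
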