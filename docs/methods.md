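# Methods

## The segmentation model

`macgan` implements a conditional generative-adversarial segmentation
network for 3-D liver/tumor CT, built from three pieces.

**Generator.** A U-shaped volumetric encoder/decoder. The encoder applies
four 2×2×2 max-pool downsamplings with a channel schedule
16 → 32 → 64 → 128 → 256, so a `C×D×256×256` input is compressed to a
`256 × D/16 × 16 × 16` bottleneck. Every convolution is 3×3×3 with batch
normalization and ReLU; the decoder mirrors the encoder with
linear-interpolation upsampling, so each upsampled map matches the shape of
the corresponding pre-pool encoder map before skip concatenation. A 1×1×1
convolution with a sigmoid produces a per-voxel foreground probability.
The pipeline trains one binary model per structure — liver (labels {1,2}
merged) and tumor (label 2) — binarized at 0.5 at inference; whether the
original system trained the two structures jointly or separately is not
something the architecture fixes, and per-structure models keep the
1-channel sigmoid head simple.

**Multi-axis attention (MA).** Each skip connection is gated by a fusion of
three *slice feature projection* (FP) branches. FP pools the feature map
along one anatomical axis — axial (drops D), sagittal (drops W), coronal
(drops H) — via `K = Q = max + mean`, runs two 3×3 convolutions on K (ReLU
between them), concatenates with Q, reduces 2C → C with two 1×1
convolutions, and broadcasts the 2-D attention map back along the reduced
axis to form `R` of the input shape. `R` modulates a 1×1×1 value projection
`V`; the mixed response `R⊙V + x` is averaged over all spatial dimensions
into a per-channel gate `C×1×1×1`. The three gates are combined as
`y = Σ_α β_α · gate_α ⊙ x` with learnable weights β on the probability
simplex. Design choices worth flagging:

- β is the softmax of three unconstrained logits, so `Σβ = 1` holds to
  machine precision after every optimizer update rather than needing a
  projection step.
- The reduction of the mixed response to `C×1×1×1` is done as (sum over the
  stacked pair) followed by a mean over D, H and W. Other reduction orders
  are conceivable; this one is the only one that lands exactly on a
  `C×1×1×1` gate, and it is what the zero-weight oracle in the tests pins
  down: with all convolution parameters zero the gate equals the
  per-channel spatial mean of the input.
- The 2-D attention map is replicated along each branch's own reduced axis
  (D for axial, W for sagittal, H for coronal).
- Whether the two 3×3 convolutions on K carry an activation is an open
  choice; a ReLU between them is used.

**Discriminator.** The CT volume is the condition: it is concatenated with
a real or generated label map and passed through three stride-2 3×3×3
convolutions (32, 64, 128 channels), each followed by dropout 0.5, then
global average pooling and a fully connected sigmoid head giving the
probability that the label is real. Global pooling keeps the critic
input-size agnostic.

## Losses

The segmentation term is the Tversky loss `1 − T` with

    T = ΣTP / (ΣTP + α·ΣFP + β·ΣFN),   α = 0.7, β = 0.3,

which penalizes false positives harder than false negatives while keeping
recall on the small tumor class; α = β = 0.5 recovers soft Dice. A
smoothing constant (default 1e−6) guards the empty-foreground case. Note
the index itself is a similarity (1 = perfect); the quantity that decreases
during training is `1 − T`.

Two adversarial modes exist. The default `nolog` drops the logarithm from
the GAN objective (the Wasserstein-distance rationale: bounded, non-vanishing
gradients): the critic minimizes `−E[D(real)] + E[D(fake)]` and the
generator minimizes `−E[D(fake)] + λ·(1 − T)` with λ = 1. The `bce` mode is
the classical ones/zeros cross-entropy. No gradient penalty or weight
clipping is applied in either mode, and the generator consumes only the CT
(no noise vector): the model is a deterministic conditional translator.

## Training

One generator step (critic frozen) then one critic step (fake labels
detached) per batch, strictly 1:1. AdamW (decoupled weight decay 1e-2) at
lr 2e-4, batch size 2. The mean validation Dice of the trained structure
drives the schedule: if it fails to improve by more than 1e−5 for 30
epochs the learning rate is halved; 60 stale epochs or 300 epochs end the
run. Training samples are random depth crops of 32 slices (any multiple of
16 works) so variable-depth volumes batch together; validation and
inference run on whole volumes reflect-padded in depth to a multiple of 16
and un-padded afterwards.

Because batches are tiny, the batch-norm running averages lag the batch
statistics the generator is actually trained with. After training, the
running statistics are re-estimated with one pass over the training set
(per-batch statistics averaged), which makes eval-mode predictions
consistent with training behavior; the recalibrated model is stored as
`final.npz` alongside the best-validation checkpoint `best.npz`. For the
critic step the frozen generator produces fakes without gradient tracking;
the implementation reuses the generator output already computed for the
same batch.

All randomness (initialization, crops, shuffling, dropout) derives from the
run seed, so identical seeds reproduce loss traces bit-for-bit on one CPU.

## Numerical core

The networks run on a small reverse-mode automatic-differentiation engine
over float32 numpy arrays (`macgan.nn`): broadcast arithmetic, reductions,
concatenation, 3-D convolution with arbitrary stride/padding/kernel
anisotropy (a 1×k×k kernel doubles as the 2-D convolution used on
projected maps), 2×2×2 max pooling, linear-interpolation upsampling, a
fused batch-norm op with the standard analytic backward, dropout, and
AdamW. Convolutions are evaluated as GEMMs over column buffers assembled
from contiguous shifted slices, processed in depth slabs capped at ~256 MB
so whole 256×256 volumes fit in memory. Every op's gradient is verified in
the test suite against brute-force loops (convolution) or central finite
differences (the rest).

## Synthetic phantoms

The phantom generator emulates the statistical structure of annotated
abdominal CT so the whole pipeline is testable without a download: an
elliptical soft-tissue "body" (default −80 ± 20 HU) against air at
−1000 HU — giving the windowing step something to clip at both ends — a
liver ellipsoid (60 ± 10 HU) jittered off-center, and 0–3 hypodense
spherical tumors (25 ± 10 HU) rejection-sampled to lie entirely inside the
liver. Intensities are drawn per voxel, Gaussian-smoothed (σ = 1 voxel) so
boundaries blur as in real CT, then corrupted with additive noise
(σ = 5 HU). The default volume is 32×64×64 voxels at 1 mm spacing with two
tumors; tumor voxels are always a small fraction of liver voxels, so the
class imbalance the Tversky loss addresses is present. Output is a pure
function of (config, seed).

What the phantoms do *not* model: anatomy beyond one organ, lesion texture
and rim enhancement, contrast phases, breathing/metal artifacts, scanner
noise spectra, or anisotropic slice spacing. Tests passing on phantoms
demonstrate that the machinery (shapes, gradients, losses, schedule,
metrics, post-processing) is correct and that the model class can fit
CT-like contrast — not clinical-grade accuracy on real LiTS volumes.

## Preprocessing conventions

Arrays are `[depth, height, width]`, 0-based; an axial plane is a
fixed-depth slice. The chain is: drop depth slices outside the first..last
labeled slice; clip intensities to the display window [−30, 170] HU (level
70, width 200 in level/width terms); map that fixed window linearly to
[0, 1] (fixed scale, not per-volume min/max, so intensities are comparable
across cases); optionally resize in-plane (linear for images,
nearest-neighbor for labels, spacing rescaled). Windowing is idempotent and
cropping never drops a labeled voxel.

## Metrics

Dice `2|S∩G|/(|S|+|G|)`, Jaccard `|S∩G|/|S∪G|`, HD95 and ASD. Surfaces are
foreground voxels with a background 6-neighbor. HD95 takes the directed
95th-percentile surface distance in each direction (numpy linear
interpolation between order statistics — published values differ across
toolkits precisely in this convention, so it is explicit here) and returns
the larger; ASD is the symmetric mean of directed mean distances. Distances
are in mm when a spacing is supplied, else voxel units. Degenerate masks:
both empty → dice = jaccard = 1 and distances 0 (a perfect prediction of an
absent structure); exactly one empty → dice = jaccard = 0 and distances
undefined (NaN, or a configurable sentinel).

## Post-processing

Connected-component cleanup of the liver mask: with `x` the voxel count of
the largest component, components with count strictly below `rate·x`
(default rate 0.3) are removed; ties survive, the largest component always
survives, and no voxel is ever added. Default connectivity is 26
(configurable — component counts depend on it). At composition time the
tumor mask is intersected with the surviving liver mask (tumors live inside
the liver); this never alters the liver channel itself.

## Scaled-down convergence check

The convergence test overfits the full MA-cGAN (attention-gated generator,
conditional critic, no-log adversarial + Tversky loss, 1:1 alternation) on
two phantoms of 32×64×64 voxels with 4 base channels and learning rate
2e-3 — problem sizes chosen so the check runs on a single CPU — stopping
once the training liver Dice reaches 0.96. It must reach 0.95 within 300
alternating steps with a non-increasing trailing Tversky trace, and the
recalibrated eval-mode model must recover the liver of a training phantom
at Dice ≥ 0.9 after component cleanup.

## Known limitations

- CPU-only and single-threaded; full-resolution (256×256) training is out
  of reach at realistic epoch counts — the design targets correctness and
  small-scale convergence, not LiTS-scale benchmarks.
- GAN training remains sensitive to learning rate and initialization; the
  no-log mode has no Lipschitz control, so very long runs can drift.
- The per-structure binary models do not enforce tumor ⊂ liver during
  training, only at post-processing.
- Phantom realism limits as above; no claims transfer to clinical data
  without retraining and validation on real volumes.
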