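# Methods

`fedpet` is a reproducible desk-scale bench for a question from multi-center
quantitative PET: can federated training of a deep attenuation/scatter
correction model match centralized training, and by how much does
single-center training fall short?  The package implements the complete
chain — simulation of heterogeneous multi-center paired data, the
preprocessing protocol, the network, four training strategies, and the
evaluation/statistics protocol — so that the comparison runs end to end in
minutes on one CPU.

## The task

PET images reconstructed without attenuation correction and scatter
compensation (NAC) are quantitatively biased: annihilation photons are
absorbed or Compton-scattered along their path, so deep tissue loses counts
while a low-frequency scatter haze adds spurious ones.  The model learns the
direct image-domain mapping from a NAC slice to its attenuation/scatter
corrected (ASC) reference, in normalized SUV units.

## Synthetic multi-center bench

The clinical-scale experiment needs hundreds of patient studies; the bench
replaces them with a 2D phantom world whose physics keeps exactly the
features the task depends on.

**Anatomy.** Each "patient" is one transaxial slice: an elliptical body
(100–160 mm across, unit-SUV background with ±15% smooth texture), a
lung-like low-attenuation organ pair (µ = 0.0028 /mm, 20–40% uptake), a
liver-like hot organ, and 0–3 focal lesions at 2–5x background uptake.
Attenuation is 0.0096 /mm (soft tissue at 511 keV) inside the body.
Defaults are plausible magnitudes, not fits to clinical distributions.

**Attenuation.** For every pixel the simulator computes the angular mean of
chord survival factors exp(-∫µ dl) over 32 directions, with line integrals
ray-marched at half-pixel steps.  This is a per-pixel surrogate for the
sinogram-domain physics: it preserves the two facts that matter — larger
bodies attenuate more, and the loss is geometry dependent — while avoiding
projection/reconstruction entirely.  On a uniform disc (µ = 0.0096 /mm,
r = 100 mm) the center-pixel factor agrees with the closed form exp(-1.92)
to 0.2%.

**Scatter.** A broad Gaussian blur (FWHM = 0.4 x body diameter) of the
attenuated primary, rescaled so the scatter fraction
sum(S)/(sum(S)+sum(P)) matches the center's profile exactly.  Whole-body
scatter fractions span 30–60% across centers.

**Noise and scanners.** Pseudo-Poisson noise (zero-mean Gaussian with
variance proportional to local intensity) at center-specific scales
0.01–0.05; center-specific PSF blur (4–8 mm FWHM), matrix size (48–96 on a
fixed 192 mm field of view) and slice thickness (3.0–4.3 mm).  Six default
profiles are deterministic and pairwise different, so the silos are non-IID
by construction.  Phantom anatomy for study *i* depends only on
(master seed, *i*), never on the profile — two centers sharing a master seed
image the same patients through different scanners.

What the bench does **not** emulate: sinogram-domain effects (randoms,
detector normalization, time-of-flight), 3D context, realistic anatomy
variability, pathology spectra, or inter-scanner reconstruction artifacts.
Passing results therefore demonstrate correctness and the qualitative
strategy ordering under controlled heterogeneity, not clinical performance.

## Preprocessing

Identical for every center: convert both images to SUV
(SUV = concentration [kBq/mL] x weight [kg] / injected activity [MBq]),
resample to the common grid (3 x 3 mm in-plane; the 4 mm slice dimension is
metadata in the 2D bench), then divide NAC by 3 and ASC by 9 and clip to
[0, 5].  The clip realizes the harmonized 0–5 intensity range as a hard
guarantee; clipped-voxel counts are logged so the choice is auditable.
Normalization and its inverse are exact on the representable range.

## Network

A two-level nested U-structure: the outer U-Net's stages are ReSidual
U-blocks (RSU), each itself a small U-shaped encoder–decoder whose output
adds to its (convolved) input, giving intra-stage multi-scale receptive
fields.  Each decoder stage and the bridge emit a single-channel side
output; a 1x1 convolution fuses them.  The deep-supervision loss is the
equal-weight sum of mean squared errors of every side output and the fused
output against the target.

Design choices where the published architecture family leaves freedom:

- **Residual-correction regression.** Every side output and the fused
  output add the input slice to a predicted correction field, and the
  fusion head is zero-initialized, so optimization starts from the identity
  mapping.  This is the standard formulation for image restoration and is
  physically natural here (the correction restores attenuated counts); it
  also removes the long warm-up that plain regression needs at this scale.
- ReLU hidden activations, linear output heads (targets live in [0, 5]).
- Bilinear up-sampling (no checkerboard artifacts), max-pool down-sampling.
- No batch normalization: batches are small, and federated averaging of
  running statistics is a research topic of its own.
- Inputs are zero-padded to the required divisibility and cropped back.

The `desk` preset (default) has 3 encoder/decoder stage pairs plus a bridge
(RSU depths 3-2-2-1, base width 8, 45,017 parameters) and trains on 64x64
slices in milliseconds per batch on a CPU.  A `full` preset mirrors the
publication-scale topology (6 stages, depths 7-6-5-4 with dilated bottom
blocks) and is provided for completeness, not used by the tests.

The network and its training loop run on a small reverse-mode autodiff
engine over numpy written for this package (same-padding dilated
convolution, ReLU, 2x2 max-pool, bilinear resize, concatenation, MSE), kept
dependency-free and verified against numerical differentiation and scipy
oracles.

## Training strategies

All strategies share the recipe: Adam, learning rate 0.001, weight decay
0.0001 (classic L2, folded into the gradient), deep-supervision L2 loss.
With K silos holding N_k samples (N = Σ N_k), the global objective weights
each local objective F_k by N_k/N.

- **CB** (center-based): train on one silo only.
- **CZ** (centralized): pool all silos on one server.
- **FL-PL** (parallel federated): per round, broadcast θ_t, train locally
  everywhere, then either take the exact weighted gradient step
  θ_{t+1} = θ_t − η Σ_k (N_k/N) ∇F_k(θ_t) (gradient mode, which requires a
  single full-batch local pass so the update equals the pooled-gradient
  step to machine precision), or average parameters FedAvg-style
  (the default; reduces to the gradient step when each silo takes one
  full-batch SGD step).
- **FL-SQ** (sequential federated): the model visits silos serially for E
  local epochs each, R rounds total; no aggregation.

Only θ crosses silo boundaries.  Adam moments stay local; for FL-PL the
default schedule *resets* them each round — after the server-side parameter
jump the stale second-moment estimates are misleading, and resetting
restored parity with centralized training in validation loss.  Every run is
a pure function of (data, config, seed): mini-batch permutations derive
from (seed, global epoch counter), which makes the degenerate reductions
exact — one silo turns every strategy into CB, and identical silos make the
FL-PL trajectory coincide with CZ.

Default schedules are sized so each strategy reaches its validation
plateau on the bench (best-validation checkpoint selection throughout):
CZ 40 epochs, CB 60 epochs, FL-PL 20 rounds x 1 epoch at batch 2 with the
moment reset, FL-SQ 20 rounds x 1 epoch at batch 4 with the center order
shuffled each round.  The shuffle removes FL-SQ's recency bias toward the
last silo in a fixed visiting order, which otherwise dominates its
seed-to-seed variance.

## Evaluation protocol

Per center, studies split 60/20/20 (50 studies → 30/10/10) into
train/validation/test by a seeded shuffle; non-CB strategies pool training
and validation and are all evaluated on the same union of test studies.  CB
models are evaluated on their own center's test split (`CB`) and, as a
clearly labeled extension, on every center's test split (`CB_cross`) to
quantify the generalizability loss.

Voxel metrics against the reference (normalized units): ME, MAE, RE%, ARE%,
PSNR with Peak = max of the masked reference (a fixed Peak = 5 is
configurable), and SSIM (Gaussian window 11 px, σ = 1.5, K1/K2 = 0.01/0.03,
L = 5).  The relative errors divide by the reference, so every metric is
computed on the mask reference > 0.01 normalized units (the body); the mask
is a reported parameter.  Pooled voxel-wise agreement is summarized by a
128x128 joint histogram over [0, 5]² and the R² of the ordinary
least-squares fit of predicted on reference values.

Strategies are compared per metric with two-sided Mann–Whitney tests
(midranks under ties), Benjamini–Hochberg adjusted across the family of
pairwise comparisons, significant at q < 0.05.  Summary tables report
mean ± SD and normal-theory 95% CIs.

The headline qualitative check is the ordering of mean test ARE%:
CZ ≤ min(FL-PL, FL-SQ) + 2.5 percentage points and
max(FL-PL, FL-SQ) < CB_cross.  The 2.5-point margin encodes "federated
tracks centralized", at the same scale as the CZ-to-FL gap reported on
clinical whole-body data; the CB side is strict.

## Numerical notes and limitations

- Desk training uses float32; the identity-style exactness tests run the
  same code in float64 on a micro configuration, where trajectory
  equalities hold to 1e-9 or bit-exactly.
- Ray marching uses bilinear map sampling organized per projection line
  (the chord integral is constant along the line), which is the prescribed
  half-pixel-step quadrature at ~50x less cost.
- Scatter rescaling is exact by construction; with noise enabled the
  realized scatter fraction fluctuates with the noise.
- The strategy comparison at desk scale is high-variance: 18 test studies
  and ARE%'s sensitivity to low-uptake voxels leave a few percentage points
  of seed-to-seed noise, which is why the ordering is asserted across
  multiple master seeds rather than per seed.
- PSNR of a perfect prediction is reported as +inf; SSIM needs images of at
  least 11 px and is NaN on smaller fixtures.
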