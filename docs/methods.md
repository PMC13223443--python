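# Methods

## Model

The package implements a denoising diffusion probabilistic model for
single-channel images. The forward process is the fixed Markov chain
q(xₜ | xₜ₋₁) = N(√(1−βₜ)·xₜ₋₁, βₜI); its marginal at level t is sampled in
closed form, xₜ = √ᾱₜ·x₀ + √(1−ᾱₜ)·ε. The reverse process is parameterized
through a noise predictor ε_θ(xₜ, t); one ancestral step is

xₜ₋₁ = (xₜ − βₜ/√(1−ᾱₜ)·ε_θ)/√αₜ + σₜ·z.

Assumptions: pixel intensities are mapped affinely to [−1, 1] before any
diffusion computation; images are square with side divisible by
2^(levels−1); the model is unconditional (labels in MedMNIST archives are
read but never consumed).

### Conventions that affect numbers

- **Timesteps are 1-based** (t = 1..T) at every public boundary; internal
  arrays are 0-based with a fixed +1 mapping. This avoids off-by-one drift
  between loss sampling and the reverse loop.
- **σₜ variants.** σₜ² = βₜ is the default; the posterior variance
  βₜ(1−ᾱₜ₋₁)/(1−ᾱₜ) is available as `sigma_variant: posterior` (with
  ᾱ₀ := 1, making the t = 1 step noiseless). Both obey σₜ² ≤ βₜ. The simpler
  βₜ choice is the default because the two are numerically close for small
  βₜ and the βₜ form is the common baseline.
- **z suppressed at t = 1**: the last reverse step is deterministic.
- **No clamping along the reverse trajectory.** Only the final x₀ is clamped
  to [−1, 1] before uint8 conversion; mid-trajectory clamping would change
  the sampler. Latents therefore legitimately leave [−1, 1], which is why the
  NORMALIZED image domain enforces finiteness rather than a hard range.
- **Loss scalings.** L2 is the plain mean square (no ½); Huber carries ½ on
  its quadratic branch, so Huber → ½·L2 as δ → ∞ and Huber ≤ ½·L2 always.
  Loss curves are means over all elements (not per-image sums). Huber
  δ = 1.0 by default.
- **T = 1 degenerate schedule**: betas = [beta_start]; the end value is
  unused, matching the inclusive-endpoint linspace convention.

## Network

A U-Net with pre-activation ResNet blocks (GroupNorm → SiLU → 3×3 conv,
additive timestep conditioning between the convolutions), multi-head
self-attention over flattened spatial positions, strided 3×3 convolution for
downsampling, kernel-2 stride-2 transposed convolution for upsampling, skip
concatenation between matching resolutions, and a zero-initialized output
convolution (the untrained model predicts exactly zero noise, which
stabilizes the first optimizer steps). Timesteps enter through a sinusoidal
position embedding (sin half then cos half, frequencies geometrically spaced
from 1 to 1/10000) passed through a two-layer MLP.

Group-norm group count: the largest divisor of the channel width that is at
most 8. A fixed count of 8 does not divide the default widths (28, 56, 112),
so the divisor rule keeps normalization well-defined at every width while
reducing to 8 wherever 8 divides.

Defaults (paper-scale): base width 28, multipliers (1, 2, 4) giving
28×28 → 14×14 → 7×7, two ResNet blocks per stage, attention at every level,
4 heads, embedding dim 56. The architecture widths, head count, and
embedding size are declared defaults, not values inferred from any source.

The network, reverse-mode automatic differentiation, and the Adam optimizer
(β = (0.9, 0.999), ε = 1e−8, lr 1e−3 default) are implemented directly on
NumPy in float32. Convolutions run as single GEMMs via an im2col layout
whose backward pass is a col2im scatter-add. Every differentiable primitive
is checked against central finite differences in the test suite, and a
whole-network gradient check runs in float64.

## Training

One update: draw one timestep per batch image uniformly on {1..T}, draw ε,
form xₜ by the closed-form marginal, regress ε_θ(xₜ, t) on ε under the
configured loss, apply Adam. Defaults follow the full-scale protocol:
40 epochs × 300 updates, batch 32 with drop-last (the unique reading
consistent with 78,468 images divided into 2,453 batches), fixed epoch
budget with no early stopping. A non-finite loss raises a divergence error
carrying the epoch and step.

Randomness is organized as sub-streams of one master seed, derived by
hashing (seed, purpose-string) — data shuffling, timestep draws, noise
draws, parameter initialization, and sampler noise are independent, so e.g.
changing the number of generated images cannot perturb a training history.
All runs are bitwise reproducible on a fixed platform.

## Synthetic phantoms

The generator renders 28×28 pseudo-radiographs: a soft-edged bright
elliptical thorax on a dark background, two darker lung ellipses, a brighter
mediastinal column, faint sinusoidal rib bands, and mild Gaussian pixel
noise. Five per-image draws emulate the main axes of variability in real
chest X-ray populations: overall body scale (body shape / BMI proxy),
rotation (posture), lung-field area (lung volume), global brightness (gray
value), and integer translation jitter (field of view).

The phantoms are deliberately crude. They exist to give the pipeline a
learnable, low-entropy distribution at desk scale — not to be radiologically
plausible. They lack the texture, pathology, device artifacts, and
inter-patient diversity of real radiographs, so passing tests demonstrate
that the pipeline's mechanics (corruption, learning, reversal, evaluation)
work, not that the model generates clinically useful images.

## Fréchet-distance evaluation

Features are summarized by their mean and n−1 sample covariance
(symmetrized); the n−1 denominator matters at small n and matches the
dominant convention. The matrix square root of Σ_r Σ_g uses
`scipy.linalg.sqrtm`; on failure or a large imaginary residue the
computation retries with diagonal jitter (1e−6, then 1e−4), and small
negative distances from rounding are clipped to zero and logged.

The built-in extractor ("projection-pool") maps pixels to [0, 1], flattens,
and applies a fixed-seed semi-orthogonal linear map: orthonormal columns for
dim ≤ 784 (a true orthogonal projection), orthonormal rows for dim > 784 (an
isometric embedding — more than 784 orthonormal directions do not exist for
784 pixels). It is deterministic given (dim, seed) and requires no
downloads. Dimensions 64 and 2048 mirror the widths of the pooling layers
conventionally used for this metric; no pretrained-network extractor is
shipped, so absolute values are not comparable to published
Inception-feature scores — comparisons are meaningful within one extractor.

## Desk-scale study sizes

The end-to-end study exercised by the tests and by `scripts/acceptance.py`
uses: 512 training phantoms and 256 held-out phantoms, a tiny U-Net (base 8
channels, one block per stage, attention at the 7×7 level only, 2 heads,
embedding 16), T = 100, 5 epochs × 50 steps at batch 32, one run per loss
(L1, L2, Huber), 128 generated images, and FID at dims 64 and 2048 against
the held-out set. These sizes were chosen so the whole three-loss study
completes in minutes on one CPU while still showing a clear loss decrease
and a generated-vs-noise FID separation; the paper-scale defaults remain in
the configuration layer.

## Known limitations

- No DDIM or other accelerated samplers; generation costs T network
  evaluations per batch.
- No EMA of parameters, learning-rate schedules, mixed precision, or
  multi-device support.
- Float32 arithmetic on a single thread; bitwise reproducibility is
  guaranteed on a fixed platform, not across differing BLAS builds.
- The Fréchet evaluator ships no pretrained feature extractor; scores are
  internally consistent but not comparable to published values.
- Cosine or learned noise schedules and conditional generation are out of
  scope.
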