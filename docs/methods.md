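# Methods

## The problem

A spectral-domain OCT instrument records, for every A-scan, one spectrum of
interference fringes on a line camera and digitizes it to 12 bits.  Reducing
the ADC depth to N bits replaces each count I with ⌊I·2ᴺ/2¹²⌋, which is an
information-destroying right shift: any fringe whose amplitude is below the
step 2¹²⁻ᴺ survives only through noise dither.  Because the choroid returns
far less light than the inner limiting membrane (ILM) or retinal pigment
epithelium (RPE), choroidal structure is the first to disappear.  The
package simulates this end to end and trains a paired image-to-image model
to restore the lost SNR.

## Forward model (phantom module)

Per A-scan column, the detected spectrum at spectral pixel i is

    I(λᵢ) = ⌊clip( g·S(kᵢ)·[1 + Re Σ_z A_z e^{i(2 kᵢ z + φ_d(kᵢ))}] + n, 0, 4095 )⌋

with kᵢ = 2π/λᵢ, Gaussian source envelope S(k), dispersion phase
φ_d(k) = a₂(k−k₀)² + a₃(k−k₀)³, and scatterer amplitudes
A_z = 2√(r_z)·e^{iθ_z}.  Layer interfaces are specular (θ = 0); tissue bodies
are collections of sub-resolution scatterers with circular-Gaussian complex
amplitudes (fully developed speckle; the coefficient of variation of linear
intensity inside a homogeneous band is ≈ 0.5).  The noise n is Poisson shot
noise on the pre-digitization counts plus Gaussian read noise — the standard
OCT detection model; the source texts give none.

Scene geometry mimics a macular B-scan: ILM at ≈ 250 µm, two inner-retina
interfaces, the RPE at ≈ 520 µm, a textured vascular choroid band, and a
choroid–sclera interface (CSI) at ≈ 700 µm.  Three presets: `flat`
(constant boundaries — exact segmentation truth), `curved` (bowl curvature
plus smooth choroidal-thickness variation), `pathological` (an RPE
elevation).  Two deliberate physical features matter downstream:

- **Depth attenuation.**  Scatterer amplitudes decay as
  exp(−(z − z_ILM)/L) with L = 400 µm, the single-pass Beer–Lambert loss
  through the tissue above.  This keeps the choroid near the noise floor,
  so its visibility — and CSI segmentability — genuinely tracks bit depth.
  The CSI carries no specular interface: it is a pure
  scattering-contrast boundary, which is what makes it fuzzy.
- **Vessel shadows.**  2–3 Gaussian-profiled columns attenuate everything
  below the inner retina by 35–65%, giving the translation model projection
  structure to preserve.

Key acquisition defaults: 2048 spectral pixels (tests and studies use 512,
which leaves a 1.12 mm unambiguous range at 4.39 µm/px), 840 nm center, 80 nm
span sampled uniformly in wavelength, 45 nm FWHM source, a₂ = 30, a₃ = 120
(≈ 4–5 rad of uncompensated phase at the band edge), source peak at 800 of
4095 counts.  The exposure level was chosen so that the bright-layer fringe
amplitudes (≈ 160–230 counts) sit between the 5-bit and 4-bit quantization
steps (128 and 256): 3- and 4-bit acquisitions then lose even the bright
layers while 5-bit keeps them, reproducing the characteristic jump in image
similarity between 4 and 5 bits.  A `sample_in_k` switch produces
wavenumber-uniform sampling for oracle tests.

## Quantization and background (quantize module)

Quantization is exact integer arithmetic (`I >> (12−N)`, verified
exhaustively against big-integer floor).  The background estimate is the
per-A-scan spectral mean (each output column sums to zero); a
`mean_fringe` mode subtracts the across-A-scan average spectrum instead.
The order is fixed: quantize first, subtract second, on the N-bit values.

## Processing chain (octproc module)

background-free fringe → cubic resampling onto a uniform k grid → Hilbert
transform along the spectral axis → multiply by e^{−iφ_d(k)} (a pure phase:
energy preserved to round-off) → FFT per column → keep the positive-depth
half → 20·log₁₀(|·| + ε), ε = 10⁻⁶ → linear map of a dB window to [0, 1].

Two scale conventions make images comparable across bit depths: (i) the
N-bit fringe values are multiplied by 2¹²⁻ᴺ after background subtraction,
undoing the known representation gain of the floor division, and (ii) the
display window of every variant of a scene is taken from that scene's
12-bit image ([5th percentile, max] of its log image).  Without both, a
low-bit image would sit below the window floor and PSNR across bit depths
would be meaningless.  Images are log-scaled at display normalization when
fed to the network — consistent with how such B-scans are viewed; linear
images are recoverable by inverting the window map.

The mean spectral subtraction leaves a residual of the (non-flat) source
envelope that transforms to the first ~10 depth rows; analyses that look
for bright layers skip this zero-delay guard band.

## Translation network (gan module)

Generator: U-shape encoder–decoder, 4×4 stride-2 convolutions, channel
widths doubling per level (capped at 8× base), skip concatenation between
mirror levels, batch normalization (instance norm by config), tanh output;
inputs mapped [0,1] → [−1,1].  The decoder upsamples with 4×4
fractionally-strided convolutions by default; an upsample-then-convolve
variant (`up_mode="resize"`, nearest 2× + 3×3 conv) is available for runs
where the uneven kernel overlap of strided deconvolution leaves periodic
intensity stripes — at the small training budgets used here neither decoder
dominates the other on every study, so the classic form stays the default.  Discriminator: patch classifier over the
channel-concatenated (input, candidate) pair; with the default three
stride-2 stages each output logit sees a 70×70 px receptive field.  Losses:
the printed minimax objective is trained in the standard non-saturating
stable-logit form; the generator objective adds λ·L1 with λ = 10.  Both
optimizers are Adam (lr 2×10⁻⁴, β₁ = 0.5, β₂ = 0.999), constant learning
rate by default with optional linear decay.  No data augmentation.  One
model per bit depth.  Disabling the discriminator leaves the pure-L1
U-shape baseline.

All layers are implemented in NumPy with hand-written backward passes,
gradient-checked against central finite differences.  The network is fully
convolutional: any input whose sides are divisible by 2^levels passes
through at native size (e.g. 256×128 B-scans); other shapes are resized
through the configured model size and back.  Default configuration follows
the published recipe (256×256, batch 16, 200 epochs, 8 levels); the studies
in this repository run scaled-down versions (64×64–256×128, 8–16 base
channels, 10–25 epochs, tens to hundreds of scenes) chosen as the smallest
budgets at which the qualitative results are stable.

## Metrics (metrics module)

PSNR uses the nominal representation maximum (1.0 for the normalized
images; observed-max by flag) and returns an infinity sentinel at zero MSE
(excluded, with a count, from aggregate tables).  The structural-similarity
score implements the multi-scale form at M = 1 with absolute constants
C₁ = C₂ = 10⁻⁴, C₃ = C₂/2 and exponents α = 1, β = γ = 0.0448 — the
luminance term dominates and contrast/structure enter weakly; negative
structure terms contribute a negative signed magnitude so anticorrelation
lowers the score.  Windowing is the standard 11×11 Gaussian (σ = 1.5)
sliding construction (a global mode exists; windowed is the default, and a
conventional 5-scale variant is available for comparison only).  CORR2 is
the 2-D Pearson correlation; it raises on two constant images rather than
returning a silent zero.  With α = β = γ = 1 and canonical constants the
windowed score agrees with scikit-image's SSIM, which the tests use as an
independent cross-check.

## CSI segmentation (segment module)

A Chiu-style shortest-path boundary search, used purely as a quality probe:
within a band below the RPE (default offsets +12 to +80 px — the band must
clear the RPE line's own point-spread tail), pixels carry the normalized
bright-to-dark axial gradient g of the laterally smoothed image
(Gaussian σ = (1.5, 4) px; speckle decorrelates across columns, the
boundary does not), and the trace is the exact minimum of
Σ (2 − g_a − g_b + 10⁻⁵) over all left-to-right paths with |Δrow| ≤ 1,
computed by dynamic programming with topmost-path tie-breaking.  The RPE
anchor is the deepest prominent peak of the lateral-mean profile (the ILM
is the shallower of the two bright lines), refined per column and
median-filtered.  Errors are mean absolute per-column deviations from
phantom truth, in µm, per B-scan.  This is a standard gradient graph
search of the package's own design, not a reproduction of any specific
published segmenter.

On flat phantoms the 12-bit trace lands within ~1.5 px of truth, and mean
errors grow monotonically as bit depth falls (≈ 7 µm at 6 bits to ≈ 50–60 µm
at 3 bits over the default bank).  The segmentation study trains one small
model per bit depth on B-scans cropped to the 128-row anatomy band at
native pitch, so network capacity is spent on the retina and choroid rather
than empty vitreous.  Reconstruction cuts the segmentation error severalfold
at 3 and usually 4 bits — the regime where quantization visibly destroys the
choroid.  At 5 and 6 bits this phantom's originals already segment at the
probe's speckle-limited floor (detector noise and the bright-layer fringes
dither the quantizer, preserving choroidal texture), so reconstructions,
which also land at that floor, show no measurable segmentation advantage
there; the corresponding strict per-bit-depth check in the acceptance suite
documents this as an expected shortfall of the synthetic conditions relative
to clinical data, where low-bit originals are far more degraded.

## Harness and reproducibility

A dataset is a set of simulated scenes; scenes act as subjects for the
disjoint 70/10/20 train/val/test split.  Every random choice (geometry,
speckle, detection noise, weights, shuffling) draws from a named substream
of one root seed (`SeedSequence`-hashed, < 2³¹), so full experiment reruns
are byte-identical down to the report CSVs.  Reports: a quality table
(bit depth × original/reconstructed, mean ± sample std of the three
metrics), a segmentation summary, a metric-vs-bit-depth plot, and
MSSSIM-vs-value sweep tables over batch size, λ, epochs, learning rate and
image size.

## Numerical details and edge cases

- Quantization validates its input range and bit depth; non-12-bit inputs
  to the quantizer are rejected rather than silently rescaled.
- Cubic spline resampling is exact (to 10⁻⁶ relative) when the input is
  already k-uniform; non-monotonic wavelength axes are rejected.
- Scenes whose deepest scatterer exceeds the unambiguous axial range
  π/(2Δk_px) raise an aliasing error instead of wrapping.
- Degenerate display windows (low ≥ high), empty fringes, mixed-shape or
  mixed-bit-depth training sets, unknown presets/axes raise immediately.
- The boundary search clamps its band inside the image and raises only if
  the band is empty or gradient-free (a uniform image has no boundary).
- Checkpoints store generator weights, batch-norm running statistics and
  the full configuration; reload reproduces inference bit-for-bit.

## What the synthetic studies do and do not show

The phantom reproduces the mechanisms that make low bit depth destructive —
quantization-step loss of weak fringes, envelope staircase artifacts after
background subtraction, SNR-limited choroidal visibility — and the studies
reproduce the qualitative orderings: metrics rise with bit depth with the
4→5 leap, reconstructions beat originals on PSNR/MSSSIM, segmentation
errors fall with bit depth and improve markedly after reconstruction at the
lowest bit depths (see the segmentation section for the 5–6-bit caveat).  It does not emulate real ocular
scenes (no pathology statistics, motion, galvo artifacts, polarization,
sensitivity roll-off, or instrument calibration), and the models here are
orders of magnitude smaller than a full GPU training on clinical data, so
absolute metric values are not comparable to a clinical study — only the
directions and mechanisms are.
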