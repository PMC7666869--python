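# octbit — low bit-depth SD-OCT simulation, reconstruction and evaluation

Lowering the ADC bit depth of a spectral-domain optical coherence
tomography (SD-OCT) system cuts hardware cost and shrinks the data that a
telemedicine link must carry, but it also destroys detection sensitivity:
at 3–4 bits the spectral fringes of weakly scattering tissue — above all
the vascular choroid — fall below the quantization step and the B-scan
turns blurry and noisy.  `octbit` is a toolkit for studying, and undoing,
that degradation:

- **simulate** 12-bit spectral interferograms of retina-like phantoms
  (layered reflectivity, speckle, vessel shadows, depth attenuation,
  wavelength-uniform sampling, source envelope, dispersion, shot/read
  noise, 12-bit ADC);
- **quantize** the raw fringes to N ∈ [1, 12] bits by exact integer floor
  scaling, `I′ = ⌊I·2ᴺ/2¹²⌋`, and remove the DC background per A-scan,
  `DSⱼ = I′ⱼ − ave(I′ⱼ)`;
- **process** fringes into B-scans through the standard SD-OCT chain:
  k-linearization (cubic resampling onto a uniform wavenumber grid),
  analytic-signal dispersion compensation
  `exp(−i[a₂(k−k₀)² + a₃(k−k₀)³])`, FFT, log-magnitude display through a
  window shared with the scene's 12-bit reference;
- **translate** low-bit B-scans toward 12-bit quality with a paired
  conditional GAN — a U-shape generator with skip connections against a
  patch discriminator, trained with
  `G* = arg min_G max_D L_GAN(G,D) + λ‖y − G(x)‖₁` (λ = 10, Adam 2×10⁻⁴,
  β₁ = 0.5, β₂ = 0.999) — implemented on a small self-contained NumPy layer
  library with explicit backpropagation, so everything runs on a CPU;
- **evaluate** with PSNR, a single-scale-parameterized MS-SSIM
  (C₁ = C₂ = 10⁻⁴, C₃ = C₂/2, M = 1, α = 1, β = γ = 0.0448) and 2-D Pearson
  correlation, aggregated into per-bit-depth report tables; and
- **probe** image quality downstream by segmenting the choroid–sclera
  interface (CSI) with an exact dynamic-programming graph search over
  bright-to-dark gradient costs, scored in µm against phantom truth.

It is intended for researchers in computational OCT who want a fully
synthetic, seeded, CPU-sized testbed for intensity-undersampled OCT
reconstruction.

## Worked example

`examples/02_bit_depth_degradation.py` quantizes one simulated acquisition
to every bit depth and scores it against the 12-bit reference:

```
bits   PSNR(dB)  MSSSIM   CORR2
   3     11.84  0.3207   0.5056
   4     14.06  0.5197   0.6295
   5     17.20  0.8123   0.7589
   6     21.12  0.9641   0.8819
   7     25.87  0.9911   0.9584
   8     31.30  0.9977   0.9880
```

Every metric rises with bit depth, and the similarity metrics leap between
4 and 5 bits — the point where the bright retinal layers' fringe amplitude
first clears the quantization step.  `examples/03_train_and_reconstruct.py`
then trains the translation model on 80 four-bit/12-bit pairs at 64×64 and
prints

```
trained 25 epochs; L1 went 0.477 -> 0.093
test PSNR original 4-bit: 15.88 dB
test PSNR reconstructed:  24.03 dB
```

an ~8 dB SNR recovery on held-out scenes.  The other examples cover
simulation/processing, CSI segmentation, and the end-to-end experiment
harness.  A thin CLI wraps the same calls:

```sh
octbit simulate --preset curved --width 128 --seed 1 --out scene/
octbit quantize --in scene/fringe.tif --bits 4 --out scene/fringe4.tif
octbit process  --in scene/fringe4.tif --out scene/bscan4.tif
octbit segment  --in scene/bscan4.tif --out scene/trace.csv
```

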