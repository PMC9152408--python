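# dtseg

Segmentation of 2-D brain-tumor image slices by dual-tree complex wavelet
denoising, multiscale Bayesian MAP labelling, and reinforcement-learning
mask refinement — with a synthetic phantom generator so the whole pipeline
is testable end-to-end without clinical data.

Medical slices (CT/MR) reach segmentation tools noisy; naive labelling
then bleeds across blurred boundaries and speckles flat regions. `dtseg`
addresses this in stages, each usable on its own:

1. **Denoise** — the slice is decomposed by a 2-D dual-tree complex
   wavelet transform (DTCWT): six complex directional subbands per scale
   with approximately shift-invariant magnitudes and exact inversion.
   Each coefficient β₁ and its parent β₂ at the next coarser scale are
   shrunk by the bivariate MAP rule

   α̂₁ = β₁ · max(m − √3 σ_n²/σ, 0)/m,  m = √(|β₁|² + |β₂|²),

   the posterior maximizer under a circular bivariate Laplacian-type prior
   with wavelet-domain noise SD σ_n (robust median estimate) and local
   signal SD σ (windowed moment estimate). A Perona–Malik anisotropic
   diffusion step then smooths residual noise without moving edges.
2. **Initial segmentation** — per-pixel feature vectors (subband-energy
   channels plus intensity) are classified by minimizing
   `E(f) = Σ_s [−log P(x_s|f_s) − log P(f_s)] + β · #{4-neighbour pairs with f_s ≠ f_t}`,
   a diagonal-Gaussian data energy plus a Potts smoothness energy, via
   deterministic iterated-conditional-modes sweeps with EM-style robust
   refits (intensity-mode initialization, pooled variances, core-pixel
   estimates).
3. **Refine** — a PPO-trained agent (clipped surrogate, ratio clip σ=0.2;
   value loss ½(V−R)²; GAE advantages; entropy regularizer) walks the
   image's superpixels and edits the mask with discrete morphological
   actions (dilate/erode/relabel per class, STOP), rewarded in training by
   the change in F-measure against ground truth.
4. **Evaluate** — Rand-index similarity, normalized variation-of-
   information ("information loss"), symmetric mean boundary distance,
   and per-class/macro F-measure, each with brute-force-verified
   implementations.

The phantom module generates brain-like test slices (skull ring, smooth
tissue, 1–3 irregular tumor blobs, Gaussian noise of chosen SD) with
ground-truth masks, so every claim above is checked against known truth.

## Worked example

```bash
dtseg synth --n 1 --height 128 --width 128 --classes 4 --sigma 0.05 --seed 11 --out demo
dtseg run --in demo/noisy_0000.tiff --out demo_out --classes 4 --truth demo/truth_0000.png
```

writes the denoised slice, the 4-class mask (indexed PNG) and a JSON
report to `demo_out/`, and prints:

```json
{
  "similarity_index": 0.999662979441746,
  "information_loss": 0.0005146634392726277,
  "boundary_error": 2.8732833330696666e-05,
  "f_measure_macro": 0.9990624814443321,
  "missegmentation_rate": 0.00030517578125
}
```

Read: of all pixel pairs, 99.97% are co-assigned consistently with the
truth (similarity index; 1.0 is perfect); almost no partition information
is lost (variation of information near 0); predicted region boundaries sit
within a few hundredths of a percent of the image diagonal from the true
ones; macro F-measure 0.999 over the four classes; 0.03% of pixels are
mislabelled.

The same flow in Python:

```python
from dtseg.denoise import denoise_image
from dtseg.phantom import PhantomSpec, add_noise, generate_phantom
from dtseg.pipeline_io import initial_segmentation

clean, truth = generate_phantom(PhantomSpec(seed=11))
noisy = add_noise(clean, sigma=0.05, seed=1)
labels = initial_segmentation(denoise_image(noisy), n_classes=4)
```

Other subcommands: `dtseg denoise`, `dtseg segment`, `dtseg refine-train`,
`dtseg refine-apply`, `dtseg evaluate`; `dtseg --help` lists options.

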