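# Methods

This note documents the models, the synthetic data, the numerical
choices, and the places where the design was genuinely open.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Paired conditional GAN

**Generator.**  U-Net with `n_levels` stride-2 4×4 convolutions
(default 8), channel schedule `min(64·2^i, 512)` =
64-128-256-512-512-512-512-512, batch normalisation after each encoder
convolution, leaky rectifier (slope 0.2) in the encoder, transposed
4×4 stride-2 convolutions with plain rectifiers in the decoder, skip
concatenation between levels of equal resolution, tanh output in
[−1, 1].  Dropout (rate 0.5) sits in the three innermost decoder blocks
and is the model's only stochasticity (the noise *z*); it stays active
at inference by default and is disabled by the `deterministic` switch.

**Input sizes.**  Eight stride-2 levels need sides that are multiples
of 256.  Inputs are reflect-padded up to the next multiple before the
encoder and centre-cropped back after the decoder; 500 × 500 patches
therefore run through a 512 × 512 interior, preserving the eight-level
architecture.  Sides must be even; the minimum side is
`2^n_levels`.

**Discriminator.**  PatchGAN on the 6-channel concatenation of
condition and candidate: five stride-2 4×4 down blocks
(64-128-256-512-512, batch norm from the second block), then a 4×4
stride-1 convolution to one channel with asymmetric (1, 2) padding so
the map size is preserved — a 512 input yields a 16 × 16 probability
map — and a sigmoid.  The losses average the map (treating each patch
location as one sample); reading the output as a single scalar would
only change the batch-mean weighting, not the optimum.

**Losses.**  Natural logarithms throughout; probabilities are clamped
to [10⁻⁷, 1 − 10⁻⁷] before any log (float32 sigmoids saturate to exact
0/1).  The discriminator ascends
`E[log D(x,y)] + E[log(1 − D(x,G(x,z)))]`; the generator descends its
second term plus `λ·E‖y − G(x,z)‖₁` with λ = 100.  The L1 term is the
mean absolute difference over all pixels and channels in the [−1, 1]
network range.  With λ = 100 the regression term dominates, so the
literal minimax generator term is used (its small-gradient regime is
irrelevant here; the multi-domain model below is the exception).

**Training.**  Batch size 1; exactly one discriminator update then one
generator update per pair (a loop counter asserts the 1:1 ratio);
Adam(β₁ = 0.5, β₂ = 0.999) with constant learning rates 0.001 (G) and
0.0002 (D); 200 epochs by default, an epoch being one seeded-shuffle
pass over the training pairs.  Runs abort on a non-finite loss, keeping
the last finite checkpoint.  Checkpoints are `.npz` weight archives
plus a JSON architecture manifest.

**Initialisation.**  Kernels default to U[0, 0.02] and biases to
U[0, 0.01] — a uniform distribution with minimum zero, upper bounds
declared here since only the minimum is fixed by the design.  A
`gaussian` switch (N(0, 0.02) weights, zero biases) is provided because
nonnegative initialisation is atypical; both schemes train on the
scaled-down problems in the test suite.  One measured consequence of
the nonnegative scheme: a *fresh* discriminator is not indifferent (its
sigmoid saturates), so the classic −2 ln 0.5 initial-loss expectation
holds only under the gaussian switch.

**Batch normalisation with batch size 1.**  Statistics are always
computed from the tensor at hand (over N, H, W per channel), i.e.
instance normalisation.  This keeps inference deterministic with no
running-average bookkeeping; at a 1 × 1 bottleneck with batch 1 the
normalisation is skipped and only the affine transform applies.

## Multi-domain stain translation

A single generator covers all three stains.  Conditioning is the
one-hot domain label broadcast (a) as three extra input channels and
(b) as three constant channels into every decoder block.  Two
normalisation-related facts forced deliberate deviations from the naive
port of the paired model, both verified in pilots of the test
configurations:

* the first encoder block's batch norm is **disabled** — per-image
  statistics would subtract the constant label planes away entirely,
  leaving the generator blind to the target domain;
* the generator uses the **non-saturating** adversarial term
  (−E[log D(G(x, d))]).  The multi-domain loss has no paired L1 term,
  so colourisation pressure must come through the discriminator; the
  minimax form's gradient vanishes through the saturated sigmoid and
  the generator never leaves its grey initial regime.

The discriminator sees the image alone: the adversarial head reuses the
PatchGAN layout, while the auxiliary domain classifier is a private
shallow branch (two norm-free stride-2 convolutions, global average
pooling to 3 logits, softmax).  A shared-trunk 1×1 classifier head was
tried first and stayed at chance cross-entropy: the trunk's per-image
normalisation removes exactly the global colour statistics that
identify a stain.

Loss: adversarial + λ_cls · cross-entropy + λ_rec · cycle L1, with
λ_cls = 1 and λ_rec = 10.  The discriminator's classifier trains on
real stained images; the generator is pushed to produce images the
classifier assigns to the target domain.  The cycle pass translates the
generated stain back to the unstained source; since "unstained" is not
one of the three domains, back-translation conditions on the all-zero
label vector.  The logged per-epoch total equals the sum of the three
logged components by construction, and the tests assert it.

## Registration

Staining rigidly misaligns the unstained and re-imaged fields of view.
`register_rigid` recovers rotation + translation by maximising mutual
information (64-bin joint histogram of the two grey-level images, in
nats) — a multimodal metric, since the two images differ in contrast
and colour.  Search: a coarse stage at 4× (configurable) downsampling
sweeps rotation over ±10° in 1° steps, proposing the translation per
rotation by phase correlation; the best coarse candidate seeds a
Nelder-Mead refinement of (rotation, tx, ty) on full-resolution MI.
Non-convergence or a final metric below a configurable floor flags the
result (`converged=False`) rather than failing silently — the
reproducible counterpart of visually rejecting deformed slides.
Transforms rotate about the image centre then translate (tx along
columns, ty along rows); composition and inverse are exact, and the
identity transform short-circuits to a bit-exact copy.

## Dataset preparation

WSI pairs are registered, randomly cropped into overlapping square
patches (default 25 crops of 500 px from a 1079 px slide; origins
uniform over the valid half-open window, deterministic per seed), and
filtered by tissue content: a patch is kept when its intima + media
fraction reaches 0.10.  The fraction comes from ground-truth masks when
available (phantoms) and otherwise from a colour heuristic
(saturation > 0.08 or luminance < 0.85).  The crop-then-filter order is
the default; both orders are reachable through the API since the
original pipeline's order is ambiguous.  Splits are WSI-grouped by
default — overlapping crops of one slide never straddle train/test —
with whole slides assigned to the test side first and each side trimmed
to the exact requested size.

## Synthetic phantom

Geometry: concentric annuli around a configurable centre — lumen
(radius r), neointima (thickness tᵢ), media (thickness tₘ) — plus
`lamina_count` thin elastic-lamina rings spaced just outside the
media's outer boundary (width ≤ 2 px).  Eccentricity e ∈ [0, 1) is an
affine stretch of the radial coordinate (axes scaled by √(1−e) and its
inverse), keeping areas near their circular values.  Masks are exact
pixel-centre classifications, so intima area matches
π[(r+tᵢ)² − r²] to < 2 % for r ≥ 40 px.

Renderings: each stain has a declared palette chosen for hue
separability (H&E magenta-pink tissue ≈ 310–320°, PSR red media
≈ 350–356°, orcein dark-brown laminae ≈ 15–25°), with darker nuclei
speckle Poisson-scattered over the cellular layers (density 4·10⁻⁴
px⁻², disks of radius 2).  The unstained image is the luminance of the
noiseless H&E rendering remapped into the narrow grey band
[0.55, 0.85] — visible but low-contrast tissue.  All images receive
independent Gaussian noise (default σ = 0.02 on the [0, 1] scale) and
are bit-reproducible for a fixed spec + seed.

**What the phantom does and does not emulate.**  It reproduces the
*structure* the pipeline depends on — annular layer geometry with known
ground truth, multimodal unstained/stained contrast, stain-specific
colour statistics, rigid misalignment, sensor noise — but not the
texture of real histology: no cellular detail beyond nuclei dots, no
staining gradients, no dust or deformation artifacts, no slide-to-slide
colour variability.  Tests passing on phantoms therefore validate the
machinery (registration, bookkeeping, optimisation, measurement), not
clinical image quality.

## Morphometry

* Segmentation: ground-truth masks pass through unchanged; stained RGB
  images are classified pixel-wise to the nearest palette colour,
  nuclei speckle is absorbed by a disk(3) morphological closing, and
  the lumen is the enclosed background component at the tissue
  centroid.  A blank image returns an explicit empty status.  The path
  taken is recorded in the result's provenance field.
* Areas: pixel count × (pixel size)².
* Intima thickness: mean over 360 equiangular rays from the lumen
  centroid of the intima chord length along the ray, sampled at
  quarter-pixel steps — chosen because it converges to the analytic
  annulus thickness and agrees with a 3600-ray computation to < 1 % on
  eccentric phantoms.
* IMR = mean intima area / mean media area; RE = |VS − HS| / HS × 100
  with the histological value as reference — this denominator
  convention reproduces 14 of the 15 bundled RE cells and all 10 IMR
  cells at printed precision.  The one non-reproducing cell (tissue 4
  IT: 1.5 recomputed vs 1.6 printed, under every denominator variant)
  is flagged in the report table rather than matched.
* Summaries are mean ± sample SD (ddof = 1); a single section yields a
  NaN SD rather than a silent zero.  Table emission rounds half-up:
  IT/RE to one decimal, IMR and grade averages to two.
* Blind scores: integer grades 1–5 per pathologist, averaged to two
  decimals; out-of-range grades are rejected.
* The bundled example dataset defaults to three sections per tissue
  when the synthetic pipeline generates new summaries.

## Problem sizes in the test suite and acceptance script

Adversarial runs are scaled to desk size as the package's own test
conditions: 64 × 64 patches, a 6-level generator with base 16 channels,
a 16-channel discriminator; 20 pairs × 30 epochs for the learning test
(held-out L1 must at least halve), 500 update pairs for the single-pair
overfit (final L1 < 0.05), 10 pairs per domain × 30 epochs for the
multi-domain run (domain accuracy > 0.8) and 3 pairs per domain × 60
epochs for its overfit palette check.  Registration and morphometry use
512 px phantoms.  Default configurations keep the full-scale values
(8 levels, 64 base channels, 200 epochs, λ = 100).

## Known limitations

* Pure-NumPy training is CPU-bound; full-scale runs (500 px patches,
  thousands of pairs, 200 epochs) are out of desk reach by design.
* The colour-threshold segmentation is calibrated to the phantom
  palettes; real histology would need stain-specific thresholds or a
  learned segmenter.
* Mutual-information registration assumes a dominant rigid component;
  non-rigid tissue deformation is out of scope.
* The multi-domain translator's output quality is below the paired
  models' (consistent with its role as a convenience: one generator,
  all stains).
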