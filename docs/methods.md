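# Methods

`imfquant` quantifies intramuscular fat in H&E-stained muscle cross-sections
and tests group differences in a hierarchical animal study. Because the
package is developed and validated entirely on synthetic images with exact
pixel-level ground truth, this note describes both the measurement pipeline
and the image model behind the validation, and states where the synthetic
setting does and does not speak for real data.

## The measurement

For one section image the pipeline computes

1. **Tissue mask.** HSV saturation S = (max − min)/max per pixel; stained
   tissue is `S >= 0.15` (eosin-pink cytoplasm and hematoxylin-dark nuclei
   are chromatic, the slide background and unstained lipid vacuoles are
   not). The binary mask is despeckled with a 31 px square median filter —
   on 0/1 data a majority vote, implemented with box sums so the cost is
   independent of window size — and closed with a disk of radius 13 px
   (implemented with exact Euclidean distance transforms, equivalent to the
   disk structuring element). These pixel defaults correspond to imaging at
   0.442 µm/px: the despeckle window (≈14 µm) and the closing diameter
   (≈23 µm) both stay below the adipocyte scale (40–80 µm), so adipocyte-
   sized white holes survive as holes while staining debris and small
   perforations are removed. Manual exclusion masks (cartilage, pollution)
   are subtracted afterwards.
2. **Hull clip.** The convex hull of the final tissue mask bounds every fat
   prediction; stray detections on the slide background cannot contribute.
3. **Fat segmentation**, by either of two methods (below).
4. **Fat fraction.** `100 · |fat ∩ hull| / |cross-section|`, where the
   cross-section mask is the tissue mask *united with* the clipped fat
   mask. The union matters: adipocytes are unstained, hence holes in the
   saturation mask, yet they are part of the muscle cross-section the
   percentage refers to. Using the lean mask alone as denominator would
   inflate a true fraction f to f/(1−f) — a 1.3-point bias at 11% fat.
   Per-section output reports both pixel counts so either convention can be
   recomputed.
5. **Aggregation.** Sections flagged unusable at QC are dropped; usable
   sections of a slide are averaged to one data point. The slide is the
   statistical unit; the animal is the grouping factor.

## The two segmenters

**CIELAB k-means.** Pixels inside the hull are converted from sRGB to
CIELAB (D65) and clustered with k-means, k = 3 (fat, stained tissue,
background), scikit-learn implementation, explicit seed, fit on at most
2·10⁵ subsampled hull pixels and applied to all of them. The fat cluster is
the one with the highest L* centroid; a manual index override exists, as
does a full-frame fitting mode. k-means sees only color: any bright,
unstained structure inside the hull — cracks from sectioning, air-bubble
rims, background slivers inside tissue concavities — is assigned to the fat
cluster. This is the method's characteristic over-detection failure mode,
and the package reproduces it on synthetic artifact sections.

**Encoder-decoder network.** A compact SegNet-style fully-convolutional
network written in NumPy (`imfquant.nn`): per level two 3×3 convolutions
with ReLU and a 2×2 max-pool whose argmax indices are stored; the decoder
mirrors the encoder and upsamples by placing values back at the stored
indices; a final 1×1 convolution yields a per-pixel fat logit. Defaults:
depth 3, channels (8, 16, 32), ~19k parameters. Training minimizes
binary cross-entropy with Adam on labeled tiles.

Numerical/optimization choices that proved to matter:

- **Internal downsampling** (default 2×, validation runs use 3×): the net
  sees block-averaged tiles and its score map is nearest-neighbor
  upsampled. An adipocyte interior is indistinguishable from slide
  background except through context, so the effective receptive field must
  exceed the adipocyte diameter; downsampling buys that at a quarter (or
  ninth) of the compute. The boundary quantization this introduces is well
  below the 1-percentage-point accuracy target.
- **Positive-class weight 3** in the loss: fat occupies ~2–12% of pixels;
  unweighted training lingers near the constant-prediction solution.
- **Gradient clipping (global norm 5), best-epoch snapshot, and up to two
  deterministic restarts** when the best epoch loss stays above 0.3: Adam
  at lr 5·10⁻³ occasionally destabilizes mid-run and falls back to the
  constant-prediction saddle; the snapshot and restart rule make training
  outcomes reproducible and seed-robust. Flip/transpose augmentation was
  tried and removed — it reliably prevented escape from that saddle.
- **Threshold calibration on held-out sections**: `train_segnet` sets a
  first threshold from a 15% validation slice of the tiles (matching the
  aggregate predicted and labeled fat fraction); the pipeline protocol
  then recalibrates on whole held-out sections scored through the actual
  tiled inference path, taking the median over sections of each section's
  exactly-matching threshold. Two lessons are baked in here: calibrating
  on *training* tiles fails because memorized probabilities saturate and
  bias the quantile high, and tile-level calibration is off because the
  score distribution of tissue-rich training crops differs from that of
  overlap-averaged whole sections.
- **A two-member ensemble** (independently seeded networks, score maps
  averaged) halves the per-section variance of the estimated fraction;
  the validation protocol trains on tiles from 12 sections and calibrates
  on 8 further sections.
- Whole-section inference tiles the image with 50% overlap and averages
  scores in overlaps.

## The synthetic study

The generator (`imfquant.synth`) emulates a 22-animal stimulation study on
the posterior cricoarytenoid (PCA) muscle: groups CT (4 animals, no
electrode), SHAM (8, electrode without stimulation), DC04 (4) and DC07 (6)
(stimulated at 40%/70% duty cycle); two muscle sides per animal — nPCA
(intact recurrent laryngeal nerve) and cdPCA (cryo-damaged); electrode
regions el+ (far) and el++ (near) for implanted groups; 4 slides × 4
sections per animal, slides assigned one per (side, region) cell (two per
side for CT). Two DC07 animals lack their nPCA slides, giving 336 sections;
a defect rate of 10/336 flags exactly 10 sections unusable, so the default
study analyzes 326.

Default cell means (percent fat) follow the group summaries the study
design is parameterized with — CT 5.7 ± 2.4 (nPCA) and 7.0 ± 1.5 (cdPCA);
SHAM 3.3/4.1 (nPCA el+/el++) and 6.2/11.5 (cdPCA el+/el++). The stimulated
groups' cell values are not published at that granularity and are set to
plausible levels near control (4.0–6.5%, with wider nPCA spread); they are
configuration, not ground truth.

Each animal draws one standard-normal fat propensity shared by all its
cells and scaled by the cell SD; sections add 0.5-point jitter around the
cell level. This makes the generated hierarchy exactly the structure the
downstream random-intercept model assumes. (Drawing each cell's level
independently was tried first; it induces within-cell correlation that an
animal-level intercept cannot absorb, and the group tests become
anti-conservative through no fault of the test.)

Rendering: a wobbly-boundary tissue blob, tessellated into ~60 µm fibers
(jittered-grid nearest-seed labels) in eosin pink with lighter endomysium
borders and dark nuclei; adipocytes as clusters of white ellipses with
40–80 µm diameters, placed strictly interior to the tissue (margin one cell
radius) and added until the realized fraction is within 0.5 points of
target, shrinking the final cells to land inside the tolerance; near-white
background; ±3 intensity noise. Palette margins guarantee background/fat
saturation < 0.15 and stained-tissue saturation ≥ 0.15, so the threshold
separates them by construction. Artifacts: background-colored cracks
(removed from both truth masks — a crack is an absence of tissue), dark
dirt blobs, bright bubble rings. Exact fat and tissue masks are recorded.

Interior placement of fat is a deliberate modeling choice: intramuscular
fat is interstitial. It also has a technical consequence — a cell piercing
the tissue outline carves a bite whose convex-hull chord clips the cell out
of every prediction, an artifact of rasterized geometry rather than a
property of the methods under study.

**What passing on synthetic data shows, and what it does not.** The images
are far simpler than real H&E: no stain gradients, no out-of-focus regions,
no fascia or cartilage, fat color exactly equals background color, and
ground truth is exact. Pipeline accuracy here demonstrates correctness of
the implementation and the claimed failure-mode ordering (k-means
over-detects in the presence of bright artifacts; the trained network is
closer to truth), not expected accuracy on real slides. Conversely the
statistical layer's calibration results transfer directly, since they
depend only on the data hierarchy, not on pixels.

## Statistics

- **Method comparison** (two segmenters on the same animals): Welch's
  unequal-variance t-test from group summaries and pooled-SD Cohen's d.
  Welch is the default because it reproduces all printed two-decimal
  p-values of the reference comparison from the published group summaries
  (0.04, 0.01, 0.02, 0.40), which the pooled-variance test does not; the
  pooled test remains available.
- **Group contrasts** on slide-level values: Gaussian linear mixed model
  with a single random intercept per animal. REML estimation profiles the
  criterion down to the variance ratio λ = σ²ₐ/σ²ₑ and minimizes it over
  log λ with Brent's method (boundary λ = 0 included), which reaches
  closed-form balanced-case optima to ~1e-9. Contrast p-values use
  Satterthwaite df: df = 2·Var(c'β̂)² / Var[Var̂], with the variance of the
  variance from the inverse expected REML information of (σ²ₐ, σ²ₑ) via the
  delta method. In balanced designs this reproduces the classical
  animals-minus-groups df exactly.
- **Degenerate cases**, handled explicitly rather than silently: with one
  observation per animal the two variance components are only jointly
  identified and the model degenerates to OLS (the naive information
  matrix is exactly singular there); at a boundary estimate σ̂²ₐ = 0 the df
  uses the residual component alone, giving N − p. The df is therefore
  discontinuous at the boundary — a tiny positive σ̂²ₐ yields the
  between-animal df, σ̂²ₐ = 0 yields the residual df — which mirrors how
  the estimated model changes its effective structure.
- **Multiplicity**: Benjamini–Hochberg across the whole contrast plan (one
  family per analysis; the family is a parameter), significance at
  q < 0.1. The default plan holds 19 contrasts: side contrasts within each
  group, region contrasts within each side of implanted groups, and
  matched-cell contrasts across groups.
- Effect-size classes on |d|, left-closed: < 0.2 negligible, [0.2, 0.5)
  small, [0.5, 0.8) medium, ≥ 0.8 large.

Calibration is verified by simulation: across ≥ 300 replicated null
studies (every cell sharing one fat distribution) the fraction of
replicates with any q < 0.1 stays at ~8%, i.e. below the nominal 10%.

## Problem sizes

Validation and the acceptance script run at 384×384 px and 0.884 µm/px —
the full-scale geometry at a quarter of the pixel count — with 12 training
sections (220 tiles of 144 px), 20 held-out clean sections, 10 artifact
sections, and 300 null-study replicates. These sizes are the package's
choice of a desk-scale experiment; every component accepts full-scale
inputs (1024×1024 at 0.442 µm/px is the rendering default).

## Known limitations

- The network is a reduced re-implementation; no claim is made of matching
  any originally trained network's weights or accuracy on real slides.
- The synthetic image model omits staining physics (no chromatic gradients
  within a structure class) — k-means on clean synthetic sections is
  therefore *more* accurate than on real H&E.
- One convex hull over the whole mask assumes one tissue piece per image;
  multi-fragment sections would be bridged.
- The mixed model supports a single random intercept only; crossed or
  nested random effects (e.g. slide within animal) are out of scope.
- Whether despeckling should run before thresholding (on grayscale) is an
  open reading of the reference pipeline; here it runs on the binary mask,
  where the deviation threshold of the classical "remove outliers" filter
  becomes irrelevant.
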