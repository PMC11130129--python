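# imfquant

Automated quantification of intramuscular fat in H&E-stained muscle
cross-sections, with the hierarchical statistics needed to compare
treatment groups in animal studies.

The package targets the kind of question asked in laryngeal-pacing
research: after months of functional electrical stimulation of the
posterior cricoarytenoid (PCA) muscle, has fat infiltrated the muscle?
Fat appears in H&E sections as unstained white vacuoles, so "how much
fat" becomes a segmentation problem — and the choice of segmenter changes
the biological conclusion. `imfquant` implements both contenders behind
one interface:

- **CIELAB k-means** (k = 3: fat / stained tissue / background), fast and
  annotation-free but color-only, with a characteristic *over-detection*
  of bright artifacts such as sectioning cracks;
- a **SegNet-style encoder-decoder network** (pure NumPy: paired 3×3
  convolutions, max-pooling with stored indices, index-based unpooling,
  per-pixel sigmoid) trained on labeled tiles, which also uses local
  structure.

Both predictions are clipped to the convex hull of a reproducible tissue
mask (15% saturation threshold → 31 px majority despeckle → closing with
a 13 px disk → manual exclusions), and each section is reduced to

&nbsp;&nbsp;&nbsp;&nbsp;fat% = 100 · |fat ∩ hull| / |cross-section|,

with slides averaged to one data point each. Group contrasts use a linear
mixed model y = Xβ + u_animal + ε (REML, Satterthwaite degrees of
freedom), Benjamini–Hochberg q-values (significance q < 0.1), Welch
t-tests and pooled-SD Cohen's d for method comparisons.

Because the original slide images are not required, the package ships a
first-class synthetic-study generator: H&E-like sections (pink fiber
tessellation, dark nuclei, clustered white adipocytes, crack/dirt/bubble
artifacts) with pixel-exact ground-truth masks, arranged in a 22-animal
hierarchy (groups CT/SHAM/DC04/DC07, nerve-intact nPCA vs cryo-damaged
cdPCA sides, electrode regions el+/el++, 4 slides × 4 sections). Every
stage of the pipeline is validated against that ground truth. See
`docs/methods.md` for the image model, the estimation details, and what
synthetic validation does and does not demonstrate.

## Worked example

```python
import imfquant as q

# effect sizes / tests from published-style group summaries (mean, SD, n)
km  = q.SummaryStats(mean=10.56, sd=2.92, n=4)   # k-means, natural side
net = q.SummaryStats(mean=5.73,  sd=2.37, n=4)   # network, natural side
d = q.cohens_d(km, net)
t, df, p = q.welch_t(km, net)
print(f"k-means vs network (nPCA): d = {d:.2f} ({q.classify_effect(d)}), "
      f"Welch t = {t:.2f}, df = {df:.2f}, p = {p:.3f}")

# one synthetic section through the full measurement
params = q.RenderParams(canvas=(384, 384), um_per_px=0.884)
spec = q.SectionSpec("CT01", "CT", "nPCA", "none", slide=0, section=0,
                     target_fat=5.7)
section = q.render_section(spec, params, seed=42)
tissue, hull = q.tissue_pipeline(section.image)
pred = q.kmeans_fat(section.image, hull, q.KMeansConfig(seed=0))
cross = q.cross_section_mask(tissue, pred.fat, hull)
print(f"true fat fraction: {q.realized_fat_fraction(section):.2f}%  "
      f"k-means estimate: {q.fat_fraction(pred.fat, cross, hull):.2f}%")

# group comparison on a simulated slide table
table = q.simulate_slide_table(q.default_study_design(), seed=3)
result = q.run_group_comparisons(table)
row = result[result.contrast == "SHAM: cdPCA el+ vs el++"].iloc[0]
print(f"{row.contrast}: diff = {row.estimate:+.2f} pp, p = {row.p:.2e}, "
      f"q = {row.q:.2e}, d = {row.d:.2f} ({row.effect_class})")
```

prints

```
k-means vs network (nPCA): d = 1.82 (large), Welch t = 2.57, df = 5.76, p = 0.044
true fat fraction: 5.69%  k-means estimate: 5.82%
SHAM: cdPCA el+ vs el++: diff = -5.37 pp, p = 9.70e-07, q = 9.22e-06, d = -4.22 (large)
```

The first line is the method comparison: k-means reports roughly twice the
fat of the network on the same animals, a significant difference with a
large effect — the over-detection signature. The second line shows the
pipeline recovering a known ground-truth fraction on a clean synthetic
section to within a fraction of a percentage point. The third detects a
deliberately elevated near-electrode region in the simulated SHAM group.

## Command line

```sh
imfquant synth    --out data/ --seed 1            # generate a synthetic study
imfquant mask     data/images/*.png --out masks/  # tissue + hull masks
imfquant train    --data data/ --out model.npz    # train the network
imfquant quantify --data data/ --method both --model model.npz --out results/
imfquant compare  --slides results/slides.csv --out stats/
imfquant reproduce-pattern --out run/ --seed 1    # all of the above, scaled down
```

Every output directory carries a manifest with the seed and content
checksums; reruns with the same seed are byte-identical.

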