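# spotpatterns

Objective quantification of complex mammal coat spot patterns from
photographs, and the downstream evolutionary analyses those measurements
support: trait repeatability, mother–offspring heritability, multivariate
phenotype grouping, and juvenile-survival (fitness) modelling. The package
was built around the biology of wild Masai giraffes (*Giraffa camelopardalis
tippelskirchii*), whose torso spots range from round and smooth-edged to
elliptical and heavily incised, but every step is generic to spotted coats.

## What it computes

**Spot extraction (giraffe units).** A photograph plus a manually defined
analysis rectangle is cropped, converted to 8-bit greyscale
(0.299 R + 0.587 G + 0.114 B), contrast-stretched, thresholded by iterated
intermeans (isodata), and binarised with spots as the dark phase. Connected
particles (8-connectivity) are labelled; components cut off by the rectangle
edge and speckles below 10⁻⁵ GU² are excluded. All lengths are expressed in
*giraffe units*, 1 GU = the pixel height of the analysis rectangle, making
measurements approximately scale-invariant across photos and animal sizes.

**Eleven traits per animal.** Number of spots plus per-spot means of: area,
perimeter (chain-code boundary length), fitted-ellipse angle, circularity
4πA/P², maximum caliper (Feret diameter), Feret angle, aspect ratio,
roundness 4A/(πM²), solidity A/A_hull (tortuousness), and the mode shade of
the colour rectangle packed as 65536·r + 256·g + b.

**Repeatability and heritability.** Repeatability R is the intraclass
correlation from a one-way ANOVA over repeated photographs of the same
animals, with parametric-bootstrap SEs. Narrow-sense heritability comes from
mother–offspring regression: h² = 2 × slope, with Bonferroni control
(α/m = 0.05/11 ≈ 0.0045) across the eleven trait tests and Shapiro–Wilk /
Breusch–Pagan regression diagnostics.

**Phenotype groups.** The ten measured traits are z-scored, summarised by
PCA on the correlation matrix, and clustered by k-means; the number of coat
phenotypes is selected with the gap statistic (uniform reference,
first-SE-max rule), with support for lumping overlapping groups.

**Survival.** Maximum-likelihood Pollock robust-design capture–mark–
recapture models, {S(A), γ′(A), γ″(A), p(t), c(t)}: age-structured apparent
survival with temporary emigration and time-dependent detection within
closed two-event occasions, phenotype-group and spot-trait covariate effects
on survival, AICc ranking, Akaike weights, likelihood-ratio tests and
Burnham–Anderson model averaging. MARK-style `.inp` files are read and
written directly.

**Synthetic data.** `spotpatterns.synthetic` generates every input with
known ground truth — rendered spotted coats, mother–calf pairs with a stated
regression slope, repeated measurements with a stated repeatability,
separated trait clusters, and robust-design encounter histories with stated
S/γ′/γ″/p/c — so the full pipeline is testable without any field data.

## Worked example

```python
import numpy as np
from spotpatterns import (CoatSceneParams, gen_coat_image, extract_spot_map,
                          measure_all, aggregate_profile)

params = CoatSceneParams(n_spots=1, mean_radius_gu=0.1, radius_cv=0.0,
                         aspect_ratio_mean=1.0, aspect_ratio_cv=0.0,
                         boundary_roughness=0.0, illumination_gradient=0.0,
                         noise_sd=0.0, placement_margin_gu=0.3, seed=5)
image, rect, truth = gen_coat_image(params)
labeled, color_rect = extract_spot_map(image, rect)
spot = measure_all(labeled)[0]
print(f"analytic area {truth[0].analytic_area:.5f} GU^2, "
      f"measured {spot.area:.5f} GU^2")
print(f"circularity {spot.circularity:.3f}, aspect ratio {spot.aspect_ratio:.3f}")
```

prints

```
analytic area 0.03142 GU^2, measured 0.03137 GU^2
circularity 0.922, aspect ratio 1.003
```

— the rendered 0.1-GU circle's raster area matches πr² = 0.03142 GU² within
0.2%; circularity sits below 1 because the chain-code perimeter of a
digitised circle slightly exceeds 2πr (the familiar behaviour of
particle-analysis software), and the moment-fit aspect ratio is 1 as it
should be for a circle.

The heritability arithmetic is a one-liner:

```python
from spotpatterns import heritability_from_slope
h2, _ = heritability_from_slope(0.52)   # -> 1.04
```

A full synthetic study (images → traits → heritability → clustering →
survival) runs from the command line:

```bash
spotpatterns full --seed 20120101 --output out/
```

which writes trait and summary CSVs, a gap curve, phenotype assignments,
model-selection and survival-estimate tables, and a manifest of output
hashes (rerunning with the same seed reproduces every byte).

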