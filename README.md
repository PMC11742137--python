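# metalmap

Co-registration of elemental imaging maps with whole-slide histology,
annotation transfer, and region-wise abundance statistics — as a headless,
fully tested Python library with a thin CLI.

## The problem

Spatially resolved elemental imaging (LA-ICP-MS, XRF) maps metal abundance
across a tissue section at 1–10 µm/pixel, but an elemental map carries no
histology: deciding *which tissue structure* a pixel belongs to requires the
H&E-stained whole-slide image (WSI, ~0.25 µm/pixel) of a serial section,
annotated by a pathologist. Because elemental imaging destroys the profiled
section, the two modalities can only be related by aligning serial sections.
`metalmap` implements that workflow for people doing spatial metallomics:

1. **Ingest** — per-element grid exports (CSV/XLSX, one rectangular grid per
   element, blank cells = missing data) are consolidated into one
   multichannel map with physical pixel size and a first-class missing-data
   mask, persisted as a chunked zarr store.
2. **Tissue detection** — aggregate channels, pseudo-log transform
   `log(1+x)`, Gaussian smoothing, Otsu or fixed thresholding, and
   morphological cleanup (remove specks, fill holes).
3. **Registration** — landmark-based planar transforms (rigid / similarity /
   affine) estimated by least squares in *physical* µm coordinates, so the
   4–40× difference in raster scale between modalities is irrelevant. The
   affine fit uses the normal equations; similarity/rigid use the centered
   cross-covariance SVD (orthogonal Procrustes, reflections rejected). For
   landmark pairs (mᵢ, fᵢ) the estimate minimizes Σᵢ ‖T(mᵢ) − fᵢ‖².
4. **Annotation transfer** — QuPath GeoJSON and ASAP XML polygons are
   parsed, mapped through the (inverse) transform, and rasterized onto the
   elemental grid (even-odd rule at pixel centers, last-drawn wins).
5. **Region statistics** — per-(region, element) summaries and a two-part
   **hurdle-gamma** model for zero-inflated, right-skewed abundance:
   P(y > 0) by logistic regression, positive values by a gamma GLM with log
   link, shape α by profile maximum likelihood. Group contrasts report the
   log ratio of positive-part means, the detection odds ratio, a Wald
   p-value and Benjamini–Hochberg q-values across elements.

Patient imaging cannot ship with a package, so a seeded synthetic-fixture
generator produces paired WSI + elemental map + annotations + landmarks with
known ground truth (transform, tissue disc, per-region hurdle-gamma laws);
every stage is validated against it.

## Worked example

```python
from metalmap import (FixtureSpec, make_fixture, detect_tissue,
                      estimate_transform, invert, transform_annotations,
                      rasterize, summarize_regions, compare_groups)

fix = make_fixture(FixtureSpec(seed=7))          # synthetic section pair
tm = detect_tissue(fix.emap)
T = estimate_transform(fix.landmarks, "affine")  # elemental -> WSI, µm
moved = transform_annotations(fix.annotations, invert(T))
labels = rasterize(moved, fix.emap.shape, fix.emap.pixel_size_um)
for r in summarize_regions(fix.emap, labels):
    if r.element == "Zn66":
        print(r.region_label, r.n_pixels, round(r.detect_frac, 3),
              round(r.mean_positive, 2))
```

prints

```
Tumor 2025 0.787 7.98
Stroma 2025 0.703 4.05
Duct 2025 0.746 6.08
Fat 2025 0.512 1.96
```

— for each annotated region: the number of elemental pixels it received,
the fraction of pixels with detectable Zn66, and the mean over detected
pixels. Tumor carries roughly twice the Zn66 of stroma here because the
generator planted exactly that contrast. The scripts in `examples/` walk
through each capability (ingest, detection, registration, transfer,
statistics, simulation) and print what the numbers mean; the same pipeline
is available from the shell via the `metalmap` CLI (`simulate`, `convert`,
`detect`, `register`, `transfer`, `stats`).

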