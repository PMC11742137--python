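# Methods

This note records the models, conventions and design choices behind
`metalmap`, in enough detail to reproduce or audit any stage.

## Coordinates and rasters

One convention everywhere: rasters are row-major; `(x, y) = (col, row)`;
origin at the top-left; pixel centers at integer pixel coordinates; 0-based,
half-open extents. Physical position is `x_um = x_px * pixel_size_um`
(square pixels). All transforms are estimated and stored in physical µm, so
a 0.25 µm/px WSI and a 5 µm/px elemental map share one frame vocabulary and
estimation never depends on raster scale. The stored direction is
elemental map → WSI (annotations originate on the WSI and travel through
the inverse); frame ids are carried on every object and checked at each
hand-off.

## Missing data

Elemental maps routinely have unablated rows or dropouts. Missingness is
first-class: values are NaN internally, a parallel boolean mask is persisted
in the store and is authoritative. Missing is *absence of measurement*, not
low abundance: no stage converts a missing entry into a finite value, missing
pixels are excluded from aggregation (mean divides by the non-missing count),
never classified as tissue, and excluded — not zeroed — in all statistics.

## Tissue detection

Chain: aggregate selected channels (sum or mean) → `log(1+x)` → Gaussian
smoothing → threshold → morphological cleanup. Choices:

- *Pseudo-log* is fixed as natural `log(1+x)`: standard, exact at zero, and
  compresses the heavy right tail so a global threshold is meaningful.
- Smoothing uses reflective boundaries and normalized convolution
  (mask-weighted blur divided by blurred mask), so missing pixels neither
  leak values nor bias local means. Default σ = 2 px: bridges scan-line
  noise at 1–10 µm/px without erasing anatomy.
- Threshold: Otsu over the non-missing histogram by default; a fixed
  user value is supported. A constant image is degenerate: all-False mask
  plus a warning.
- Morphology: remove 8-connected objects with area < `min_object_px`
  (default 64), then fill 4-connected *enclosed* holes with area ≤
  `fill_hole_px` (default 64). Objects and holes use the conventional
  complementary connectivity pair. Removal runs first so specks cannot
  block hole-filling; border-touching background is never treated as a
  hole. The operation is idempotent. The returned params (including the
  resolved Otsu value) reproduce the mask bit-exactly.

## Registration

Landmark pairs in µm; least squares for three nested model classes:
affine (6 d.o.f., normal equations), similarity (4 d.o.f.) and rigid
(3 d.o.f.) via centered cross-covariance SVD (orthogonal Procrustes; the
similarity scale is the Umeyama estimator). Reflections are rejected for
rigid/similarity (det forced +1): silently mirroring a flipped section is a
classic registration error — flips must be an explicit preprocessing step.
Default model is affine; rigid/similarity exist for degraded landmark sets.
Rank checks name their deficiency (too few, collinear, coincident).
Resampling maps each output pixel center through T⁻¹ with nearest or
bilinear interpolation; out-of-bounds samples are zero-filled and flagged
missing; label/mask images must use nearest.

## Annotations

GeoJSON (QuPath dialect) coordinates are WSI pixels at base resolution,
converted to µm on ingest via an explicit pixel size; labels come from
`classification.name`, then `name`, else `"unclassified"`; MultiPolygons
split per part. ASAP XML vertices are ordered by their `Order` attribute
regardless of document order; labels come from `PartOfGroup` with the
annotation `Name` as fallback. Rasterization assigns each pixel the id of
the **last** annotation (input order) whose polygon strictly contains the
pixel center under the even-odd rule with holes excluded — last-drawn-wins
matches annotation-tool z-order, and strict center containment makes the
semantics deterministic and oracle-checkable. Label ids are contiguous from
1 and only the label table maps ids to strings.

## Hurdle-gamma region statistics

Abundance within a region is non-negative with excess zeros (non-detects)
and a skewed positive part. The two-part hurdle gamma factorizes the
likelihood: a Bernoulli part for detection, fitted as logistic regression of
`1{y > zero_eps}` on the design, and a gamma law with log link for the
positives, fitted as a gamma GLM (the mean coefficients are ML regardless of
shape, which is ancillary). The shape α is then profiled by Newton's method
on `n(log α − ψ(α)) + Σ(log(yᵢ/μᵢ) − yᵢ/μᵢ) + n = 0`, initialized from the
standard deviance-based approximation. Standard errors: logistic from the
GLM information; gamma coefficients from the exact log-link information
`α·XᵀX`; shape from `n(ψ′(α) − 1/α)`. Degenerate inputs (no zeros, no
positives, constant positives) are flagged, with the estimable part still
reported — constant positives use the exact closed form for the mean and no
shape.

Two-group comparisons fit the model with an intercept and a group indicator
(1 for the alphabetically later group) on pixel-level values: the gamma
group coefficient is the log ratio of positive-part means, the logistic one
the log detection odds ratio; the p-value is a Wald test on the gamma
contrast and q-values apply Benjamini–Hochberg across the elements tested in
one call. `zero_eps` (default 0) defines non-detects on non-missing pixels.

Deliberate simplifications: the fit is frequentist with fixed effects only —
no patient-level random effects and no Bayesian machinery — and pixels are
treated as independent within a region, with no spatial autocorrelation
adjustment. Both matter for real multi-patient studies: standard errors here
are anti-conservative under spatial correlation, and cross-patient
generalization needs a hierarchical model. The package reports the
likelihood pieces needed to build either on top.

## Synthetic fixtures

A fixture emulates one serial-section pair with full ground truth, sized so
the whole pipeline runs in seconds: a 160×160 elemental map at 5 µm/px
(800×800 µm) holding a tissue disc of radius 345 µm, four disjoint square
regions of 45×45 px (2025 pixels — enough for stable per-region fits) using
labels from a breast-pathology vocabulary (Tumor, Stroma, Duct, Fat), and an
H&E-style RGB rendering of the same geometry at 0.25 µm/px. Region squares
are placed with edges strictly *between* elemental pixel centers; an edge
exactly on a line of centers would make entire rows of the rasterization
knife-edge and unreproducible under float round-trips.

The element panel is P31 + Fe57 + Zn66 + Cu63: P31 acts as the matrix
element — high and nearly ubiquitous across tissue, as phosphorus is in real
sections — which is what makes tissue detection from elemental data
well-posed; the trace metals differ by region so group contrasts carry
signal. Per-pixel abundances are hurdle-gamma draws per (region, element);
non-region tissue uses a baseline law, off-tissue background is near-zero
sparse noise. Values are rounded to 4 decimals, matching the limited
precision of real instrument exports and making CSV/XLSX text round trips
exact (XLSX cannot hold more than 15 significant digits).

The ground-truth transform is sampled as a similarity about the tissue
center — rotation ≤ 15°, scale 0.95–1.05, translation 100–500 µm — a
plausible serial-section mounting offset; landmarks are true correspondences
plus optional Gaussian jitter; listed scan rows are masked missing. Both
modalities render the *same* geometry: true section-to-section biological
drift is not simulated, so passing tests demonstrate correctness of the
computational chain, not robustness to tissue deformation — consistent with
the strictly linear registration model. No H&E texture, ablation physics or
detector noise spectra are emulated. Everything is a deterministic function
of the seed.

## Storage

The consolidated store is one zarr group: `data` (float64, chunked
1×512×512), `missing_mask` (bool), attributes `channel_names`,
`pixel_size_um`, `frame_id`, plus a human-readable `metadata.json` sidecar;
companion arrays (`tissue_mask`, `region_labels`) join the same group.
Single scale, no pyramid — the smallest chunked-store layout that
round-trips bit-exactly. Intensity units (counts vs µg/g) are deliberately
opaque metadata; no calibration is attempted.

## Verification strategy and problem sizes

Every vectorized computation is checked against an independent brute-force
oracle: per-pixel Python loops for aggregation and region summaries, an
even-odd crossing-number point test for rasterization, exhaustive
between-class-variance search for Otsu, direct hurdle-density summation for
the fitted log likelihood, and shoelace areas for the affine area law.
Pipeline-level tests run on the seeded fixtures: 50-seed transform recovery,
20-seed tissue IoU, and full ingest→stats recovery of the generator's
parameters. The acceptance script uses the same problem sizes as the tests
(50 transform seeds, n = 5000 hurdle fit, 1000 null replicates at 500
pixels/group, one full fixture) — large enough for stable estimates, small
enough to re-run casually on a laptop.

## Known limitations

- Strictly linear registration: no deformable alignment, no automatic
  feature matching, no intensity-based refinement.
- No pyramidal WSI decoding — operates on exported raster levels.
- Statistical caveats as above (independence within region, fixed effects).
- Otsu assumes a bimodal aggregate; panels without a matrix-like channel may
  need a fixed threshold.
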