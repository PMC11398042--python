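# Methods

## The measurement model

Computed digital absorptiometry (CDA) turns a plain radiograph into a
relative bone-density measurement by reading the gray scale behind a
co-imaged aluminum step wedge.  The wedge has ten steps S1–S10 of strictly
increasing thickness (S1 thinnest); aluminum's attenuation is a practical
bone surrogate, so the HU-like value behind each step defines one
relative-density band.  The protocol implemented here is:

1. **Calibration** — for each step, a measuring line is placed horizontally
   through the center of the step's footprint, spanning it edge to edge.
   The raw minimum and maximum of the sampled values define the step's
   closed range [Min, Max].  No smoothing or outlier rejection is applied
   (the published protocol records raw extremes), and the default sampling
   band is one pixel wide.  Ranges are kept per radiograph; replicate tables
   are summarized as mean ± sample SD (n−1).
2. **Decomposition** — each range is painted with its fixed palette color
   (S1 yellow #FFFF00 … S10 light blue #A6CAF0) over a background sentinel
   (#404040, deliberately outside the palette); the union of all ten ranges,
   restricted to the limb, is painted white (#FFFFFF) as the bone-reference
   image.  All eleven images are resized to 899×847 with nearest-neighbor
   interpolation and written as 24-bit uncompressed BMP.
3. **Quantification** — the density standard is masked black (#000000) and
   excluded from the counting domain.  Each remaining pixel is credited to
   the palette entry with the smallest CIE76 distance (Euclidean ΔE in
   CIELAB, sRGB D65, 2° observer) when that distance is within the matching
   tolerance; ties break to the lowest step.  %color pixels for step s is
   100·N(s)/N(white).
4. **Artifact detection** — colored pixels outside the limb mask are
   background artifacts.  The per-step artifact fraction f = artifacts /
   N(white) grades the image group: mild f ∈ (0.005, 0.05], moderate
   (0.05, 0.20], severe > 0.20.
5. **Statistics** — reference-attenuation series (one value per limb) are
   compared across tube settings with one-way repeated-measures ANOVA and
   Holm–Šídák-adjusted paired t tests; %color series are compared across
   steps with the Friedman rank test (mid-rank ties) and Dunn's pairwise z
   tests with Bonferroni family correction.  Normality is screened with
   Shapiro–Wilk.  A tube setting is *recommended* when, among settings with
   zero artifact occurrences, its coverage interval reaches lowest on the HU
   scale (ties break toward wider total coverage); if every setting shows
   artifacts the least-affected one is returned with a warning flag.

## Design choices where the protocol is open

- **Closed intervals.**  Min/Max are attained sample values, so range
  membership uses `min ≤ HU ≤ max`.  Overlapping consecutive ranges are left
  as-is: each step's mask is built independently, so a pixel may be colored
  in two images when ranges overlap.
- **Nearest-neighbor resize, counting after resize.**  Any interpolating
  kernel would invent colors outside the categorical palette before
  counting.  Counting happens on the resized rasters; %color is a ratio of
  counts subjected to the same area distortion, so the distortion largely
  cancels.
- **Limb-restricted white reference.**  Only under this reading can %color
  exceed 100% in artifact-affected images: stray colored background pixels
  inflate the numerator while the denominator stays anatomical.  This is
  also what makes artifact inflation detectable.
- **Matching tolerance ΔE = 10 (configurable).**  Synthetic images are
  exact-palette, so results are tolerance-insensitive; the default guards
  against codec rounding on real files.  The background sentinel sits
  ΔE ≈ 58 from the nearest palette entry, far beyond the tolerance.
- **Severity thresholds are configuration, not measured facts.**  The
  source grading is visual; the numeric cut-offs above are declared
  operational defaults.
- **Dunn's family correction is Bonferroni**, the common convention when the
  correction is unnamed.  The RM-ANOVA applies no sphericity correction
  (known limitation).  The Friedman p-value is asymptotic χ² by default,
  with an exact permutation mode (all (k!)^n within-row rank arrangements,
  Monte-Carlo sampled above an enumeration limit) for small designs.

## The synthetic radiograph generator

Real radiographs are not deposited, so a phantom generator emulates the
study conditions.  It is a monoenergetic Beer–Lambert projector: each pixel
accumulates an optical depth A = Σ_m μ_m(kV)·t_m over the materials along
its ray and stores HU = −1000 + 1000·A plus Gaussian quantum noise with
sd = 35·√(1.2/mAs) HU, clipped at 3 sd (so air stays within ±3 sd of
−1000).  Effective attenuation coefficients (mm⁻¹) are tabulated at
50/60/70/80 kV and interpolated linearly; μ falls with kV for every solid
material, which produces the downward shift of all wedge ranges as kV
rises.  Defaults, chosen once to reproduce the published reference-range
ordering and magnitudes (e.g. aluminum S1 at 50 kV; 1.2 mAs renders near
1005 HU, inside the published 880.6–1130.6 band):

| material | μ(50) | μ(60) | μ(70) | μ(80) |
|----------|-------|-------|-------|-------|
| aluminum | 0.2228 | 0.1996 | 0.1327 | 0.1106 |
| bone     | 0.2117 | 0.1896 | 0.1261 | 0.1051 |
| soft     | 0.0458 | 0.0429 | 0.0395 | 0.0376 |
| hair     | 0.1350 | 0.1197 | 0.1160 | 0.1020 |

- **Wedge.**  The physical standard's per-step heights are not published;
  the defaults (9.0–19.8 mm in 1.2 mm increments, vertical column of step
  bands at the image's left edge, 512×512 at 0.2 mm/pixel) are free
  parameters and make no claim to equal the physical block (density
  2.65 g/cm³ and mass 9.39 g are carried as metadata).
- **mAs dispersion.**  Overexposure disperses the ranges and drags the thin
  steps toward (and below) the soft-tissue range.  This is modeled as an
  empirical HU shift subtracted from aluminum pixels,
  435·ln(mAs/1.2)·exp(−1.6·(t−t₁)/(t₁₀−t₁)), largest at S1 and decaying
  toward S10 — at 12 mAs, S1 drops ≈ 1000 HU and S10 ≈ 200 HU, matching the
  published dispersion pattern qualitatively.
- **Knee.**  A soft-tissue ellipse (ellipsoid chord profile, 24 mm max,
  landing at ≈ 30 HU at the 60 kV reference) encloses a bone core with a
  cusped, tapered thickness profile T·(1−ρ)², 16 mm max.  The taper makes
  the projected HU histogram decrease monotonically — a stylized stand-in
  for the scarcity of thick, dense bone paths in a lateral knee projection —
  which reproduces the observed gradual decline of %color pixels from S1 to
  S10.  Limb size varies ±8% between subjects.
- **Hair-like clutter.**  Background artifacts are thin filaments of a
  fixed low-attenuation "hair" material drawn outside the limb.  Because
  the material is fixed, its rendered HU tracks kV (≈ 350/197/160/20 HU at
  50/60/70/80 kV) and lands inside the S1–S3 ranges only for the tube
  settings that shift those ranges down (60 kV;12 mAs, 70 kV, 80 kV) — at
  50 and 60 kV;1.2 mAs the same filaments sit far below S1's Min and stay
  invisible to decomposition, exactly the published artifact pattern.
  Severity scales the filament count (1/4/16).
- **Cohort.**  The default synthetic study uses nine limbs and the five
  presets (50;1.2, 60;1.2, 60;12, 70;1.2, 80;1.2 kV;mAs); five limbs carry
  clutter (two mild, one moderate, two severe), mirroring the published
  4 clean / 5 affected split.  All randomness derives from one seed via
  spawned seed sequences; renders are bit-reproducible.

### What the generator does *not* emulate

Polyenergetic spectra, scatter, heel effect, detector MTF, flat-field
inhomogeneity, anatomical realism (separate femur/tibia/patella, joint
space), and the real HU heterogeneity within a wedge step (synthetic steps
are flat plus noise, so range widths come from the noise model rather than
from material texture).  Passing tests therefore demonstrate that the
*pipeline arithmetic and decision logic* are correct and that the
qualitative physics (kV shift, mAs dispersion, artifact confinement) is
reproduced — not that the absolute published HU values would be recovered
on real animals.

## Numerical notes

- Calibration on noise-free renders recovers the generator's per-step
  extremes exactly (bit-identical float paths), which the tests use as an
  oracle.
- Noise-free is an explicit render flag; noisy renders clip noise at 3 sd,
  so per-radiograph Min/Max differ from the step mean by at most 3 sd.
- Degenerate inputs raise: empty sample lists, empty limb masks, zero white
  reference, constant series in Shapiro–Wilk, mixed exposures in replicate
  summaries, overlapping or out-of-bounds wedge footprints.
- Problem sizes: unit tests render 64–512 px scenes; the cohort study (45
  radiographs, 495 decomposed images) runs in about a minute on one core.
- DICOM output stores unsigned 16-bit values with a data-derived rescale
  intercept; round-trips are exact to the 1-HU storage quantization.
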