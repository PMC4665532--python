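# Methods note

This note records the model behind `cardioseg`, the meaning and default of
every parameter, the numerical conventions, and the known limitations.

## 1. Segmentation model

The method assumes bright-blood short-axis cine frames (SSFP-like contrast):
the ventricular blood pool is the brightest tissue class, the myocardium is
intermediate, air/background is dark. All frames of a study are min-max
normalized to 0–255 *per study* (not per frame) so that one threshold and one
initial value are comparable across slices and phases.

For one frame and one seed pixel the pipeline is:

| Step | Operation | Output |
| --- | --- | --- |
| 1 | Sobel/Prewitt gradient magnitude, renormalized 0–255 | edge image |
| 2 | kernel-seeded isodata threshold; *object = below* threshold | binary image 1 (edges are background barriers) |
| 3 | kernel-seeded isodata threshold on the grayscale frame; *object = at/above* | binary image 2 (bright blood) |
| 4 | OR of backgrounds = AND of objects | binary image 3 |
| 5 | 8-connected region growing from all object pixels under the kernel, then hole filling and contour extraction | cavity mask + contour |

### Isodata threshold selection

With kernel pixel sample *P* and current threshold *k* (integer, 0–255):

k′ = round(( mean{p ∈ P : p < k} + mean{p ∈ P : p ≥ k} ) / 2)

iterated from k₀ until k′ = k (round = half-up; cap `max_iter` = 100, a cycle
raises `NonConvergenceError`; none has been observed). Two policies govern
the degenerate case where one class is empty:

- **`mean`** (default of `isodata_threshold`): restart from the rounded mean
  of all kernel pixels and continue iterating. A uniform kernel converges to
  its own value; the converged threshold is insensitive to k₀ even when k₀
  lies outside the data range (verified for k₀ ∈ {0, 64, 128, 192, 255} on
  1000 bimodal kernels — 100% identical).
- **`hold`** (used by `segment_frame` for the grayscale cut): keep the
  current threshold. Rationale: in the normal one-click case the kernel lies
  wholly inside homogeneous bright blood and carries *no information about
  the blood/myocardium boundary*. Thresholding such a kernel at its own mean
  bisects the pool under noise (measured ≈ −23 mL EDV on a 150 mL noisy
  phantom). Holding the study-wide prior k₀ = 128 — set once and valid for a
  whole normalized study — keeps the cut between the myocardium (~75 after
  normalization) and blood (~255). A background click instead yields
  threshold 0 for the edge cut, an empty binary image 1 under the kernel, and
  a deliberate `SeedOffObjectError` naming the click.

The edge-image threshold's kernel statistics are taken on the **grayscale**
window by default (`edge_kernel_source="gray"`). Statistics on the edge
image itself (`"edge"`, selectable) degenerate in flat neighbourhoods
(all-zero window → threshold 0 → no object anywhere) and, in noisy
interiors, threshold at the noise floor and erase half the pool.

### Click propagation and phases

End-diastole is phase 0 by convention (maximal cavity); end-systole defaults
to `n_phases // 2` and both can be overridden or auto-selected as the
argmax/argmin of segmented area on the seed slice. Slices are segmented
outward from the clicked slice at ED, each seeded at the rounded centroid of
the nearest segmented ED mask; each slice's ES frame is seeded from that
slice's ED centroid. A frame whose segmentation fails (apical slice without
cavity, seed drifted off the pool) is recorded and skipped; only failure of
the clicked frame itself aborts.

## 2. Quantification

Simpson's method: V = Σ areaₛ × d, with d = slice thickness × (1 + gap
fraction), area in mm² (pixel count × row spacing × column spacing), V
reported in mL. The acquisition gap is *metadata*: it is not recoverable from
pixel data or common headers and must be supplied (`gap_fraction`, e.g. 0.2
for a 20% gap). EF = (EDV − ESV)·100/EDV. The most basal covered slice may
differ by one position between ED and ES (through-plane motion); a larger
mismatch raises `BasalOffsetError`. Volumes may be BSA-indexed (mL/m²).

## 3. Agreement statistics

For paired series of the same parameter: Pearson r; two-tailed paired t-test
(df = n − 1, sample SD); a Lilliefors-style one-sample KS normality check per
series, whose p-value comes from 10 000 Monte-Carlo standard-normal samples
of the same size (fixed internal seed, so reports are reproducible);
Bland-Altman bias ± 1.96 SD limits of agreement plus the fraction of observed
differences inside them (0.952 on 10 000 simulated N(2, 5²) differences). A
|bias| of ≥ 10 mL (EDV, ESV) or ≥ 3 percentage points (EF) is flagged as
clinically relevant (inclusive thresholds).

## 4. Phantom

The synthetic study rasterizes, per slice and phase: an LV blood disk inside
a myocardial ring, an RV crescent (a disk centred on the septal epicardial
border, clipped outside the LV epicardium) with its own wall, dark
background, and papillary inclusions strictly inside the LV cavity on the
mid slices. Radii contract cosinusoidally from ED (phase 0) to ES (half
cycle); apical slices are tapered. Gaussian noise (if any) is added, clipped
to [0, 255], then the study is normalized exactly as the file reader
normalizes a loaded study, so in-memory and written/reloaded phantoms
segment identically.

Defaults (all overridable in `PhantomConfig`): 10 slices × 25 phases,
224×224 px, 0.8 mm pixels, 6 mm slices, no gap; LV ED/ES radius 36.3/25.2 px
and 12 px wall → truth EDV 152.6 mL, ESV 73.8 mL, EF 51.6% (a typical mildly
dilated adult LV); intensities 200/80/30 (blood/myocardium/background); two
papillary inclusions of radius 2.5 px at 0.6 cavity radius on slices 2–6;
RV crescent ED/ES radius 34.4/27.3 px. Centres and radii are deliberately
sub-pixel (e.g. centre (112.4, 123.6)): grid-aligned integer circles are a
degenerate rasterization case in which dozens of boundary pixels tie at the
exact global gradient maximum — an alignment no anatomy produces.

Ground truth is defined **on the rasterized grid**: truth masks are the
noiseless rasterized cavities (papillary pixels counted as cavity, the usual
volumetric convention) and truth volumes integrate the truth-mask areas
through the same Simpson formula the analysis uses. Segmentation error is
therefore not confounded with rasterization error. The phantom does *not*
emulate: flow artefacts, bias fields (available separately via
`perturb_study`), basal outflow-tract anatomy, through-plane motion, or
trabeculated RV walls.

## 5. Numerical conventions

- Integer thresholds 0–255; rounding is half-up everywhere
  (`floor(x + 0.5)`), including normalization and centroid seeding.
- Objects are 8-connected; enclosed background for hole filling is
  4-connected (the standard duality).
- Contours are closed polygons whose vertices lie on pixel-edge midlines at
  half-integer (row, col); for a hole-free mask the shoelace area equals the
  object pixel count exactly (a single pixel has area 1.0).
- The whole chain is deterministic: fixed seeds give byte-identical frames,
  masks, contours and JSON reports across runs.

## 6. Measured performance and limitations

On the default phantom (one click, 20 frames segmented, no failures):
minimum Dice 0.988 noiseless and ≈ 0.975 at noise SD 10; EDV/ESV errors
−1.4%/−1.9% noiseless and ≈ −3.2/−2.3 mL noisy; EF error ≤ 0.6 pp in both.
Problem sizes exercised routinely: 224×224×10×25 studies (segmenting 20
frames takes well under a second; phantom generation a few seconds).

Known limitations:

- **Systematic slight underestimation.** The edge barrier removes the
  strongest-gradient pixels of the cavity boundary, so masks sit just inside
  the true boundary (< 2% volume here). This is intrinsic to using edges as
  barriers, not a bug; it is visible as the consistently negative volume
  errors above.
- **Homogeneous-pool assumption.** The grayscale cut relies on the blood
  pool being the brightest class after per-study normalization; strong bias
  fields or flow voids violate this (use `perturb_study` to probe).
- **Thin-cavity failure at the apex.** When a tapered apical cavity thins to
  a few pixels the seed kernel may contain no object; the frame is skipped
  and reported, and the stack integrates over the remaining slices.
- **RV accuracy is lower than LV.** The thin crescent tips blur into the
  walls; expect Dice ≈ 0.93–0.95 there rather than ≥ 0.98.
- The Monte-Carlo KS p-value is resolution-limited to ~10⁻⁴ by the 10 000
  replicates.
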