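# Methods

## Data model

A slide is a rectangular mosaic of equally sized monochrome tiles, one
image per fluorescence channel (DAPI, GFP/FITC, TxRed, Cy5; 8- or
16-bit). Coordinates are 0-based and row-major; the global pixel
coordinate of offset (i, j) in tile (r, c) is
(r·tile_rows + i, c·tile_cols + j), and this mapping is bijective over
the slide. Polygon ROIs live in continuous pixel coordinates with pixel
centers at integer + 0.5; rasterization includes a pixel iff its center
lies inside the polygon (even-odd rule), so an axis-aligned n×n square
covers exactly n² pixels. Masks are stored as single-channel 8-bit PNG
(0/255), bit-exact on round trip. The physical pixel edge defaults to
0.323 µm and is overridable.

## Enhancement and virtual channels

Each channel is enhanced as `Ie = (max(I − c, 0))^p`. The difference is
clamped at zero *before* exponentiation: negative differences carry no
staining evidence and clamping keeps the transform monotone and defined
for non-integer `p`. Defaults: `c` is the mode of the channel's
intensity histogram (a robust background estimate when background
dominates the frame) and `p = 2`; both are per-channel configurable,
and for a given staining batch `c` is better set explicitly just above
the glass/lumen level (the benchmark configuration uses
c = 8/6/10/6 for DAPI/GFP/TxRed/Cy5). Enhanced images stay in floating
point; every histogram used for thresholding has 256 uniform bins over
the observed range of the branch's population, shared between the
slide-global reference and all tiles so their thresholds are directly
comparable (and so the degenerate-collapse equivalences below are
pixel-exact).

`VC_tissue` sums the four enhanced channels; `VC_epi` is
`Ie(TxRed) − Ie(GFP) − Ie(Cy5)` clamped at zero. A pixel equally
enhanced in TxRed and GFP — the erythrocyte/folded-tissue signature —
contributes exactly zero epithelial evidence.

## AGS thresholding

Otsu's criterion is maximized exactly over all histogram cut points
(between-class variance `w0·w1·(µ0−µ1)²`, computed from bin centers);
ties — which occur when an empty histogram gap separates two classes,
making every in-gap cut equivalent — resolve to the smallest threshold,
for determinism. A histogram with all mass in one bin is *degenerate*:
no two-class split exists and the caller decides (tiles inherit the
reference threshold, flagged in the audit trail).

Per tile, the raw Otsu threshold is accepted iff it lies in
`[T_ref − α, T_ref + α]`. A rejected tile is re-thresholded on its
pixels inside `[T_min, T_max]`; if that clipped population holds less
than `min_fallback_fraction` of the tile's pixels the fallback is
considered unsupported and `T_ref` applies instead — a threshold
estimated from a handful of pixels is noise. The fallback threshold is
applied as computed by default in the benchmark configuration;
`clamp_fallback` (the package default) instead clamps it onto the
nearer guard endpoint, trading adaptivity for bounded behavior. Both
choices are recorded per tile in the decision audit trail (tile index,
raw Otsu, accepted / fallback / degenerate / forced flags, final
threshold).

**Reference placement.** On a slide whose virtual channel has more than
two intensity classes — e.g. a wide staining gradient spreads the
bright class several-fold after squaring — an unrestricted whole-slide
Otsu tends to cut *inside* the broad bright class rather than at the
class boundary of interest (the same failure that makes the GT baseline
collapse on such slides). `clip_reference=True` therefore computes
`T_ref` on the population clipped to the same `[T_min, T_max]` corridor
used by the fallback, keeping the reference at the boundary the
corridor brackets. This option requires absolute corridor bounds and is
off by default (the plain contract computes `T_ref` on the unrestricted
histogram); the benchmark configuration enables it on both branches.

**Two branches.** Branch 1 runs AGS on `VC_tissue` over the whole
slide; the high class, AGSm-smoothed, is the tissue mask T and the
lumen mask is its exact complement. Branch 2 runs AGS on `VC_epi`
restricted to T — its reference threshold is likewise computed only
over T pixels, since including lumen would bias it — and its smoothed
high class, intersected with T, is the epithelium mask E; S = T \ E.
Smoothing each branch's high mask independently can break the exact
partition, so complements are recomputed after smoothing (partition
repair). `L ⊎ T = slide` and `S ⊎ E = T` are asserted on every
segmentation.

**AGSm smoothing** is one closing followed by one opening with a disk
of radius ≤ 5 (default 2): the closing fills keratin-negative nuclear
holes up to ≈ 2·radius across, the opening removes isolated noise
specks, and the close-then-open composite is idempotent. Radii above 5
are deliberately unsupported in AGSm — large filters bridge thin stroma
bands (a disk of radius r closes gaps narrower than 2r, so radius 2
preserves 5-px bands while radius ≥ 3 would not).

**Parallelism.** Tiles are independent given the reference threshold;
the tile loop runs on a thread pool and results are assembled by tile
position, so masks are bit-identical for any worker count and tile
order.

## Baselines

GT applies the whole-slide Otsu threshold to every pixel; LT applies an
unconstrained per-tile Otsu (degenerate tiles inherit the global
threshold, flagged). Both use the same two-branch structure, binning
and partition repair as the main method, but re-implement the threshold
application directly — which makes the degenerate-collapse checks
meaningful: AGS with `force_reference` is pixel-identical to GT, and
AGS with `α = ∞` is pixel-identical to LT. MP is a closing with a disk
(default radius 3) applied to each branch's high mask in place of AGSm;
radii above 5 warn and above 10 are refused, since closing at that
scale erases thin stroma outright.

## Measurement and aggregation

Per ROI compartment, E and S areas are the pixel counts of the E and S
masks inside the union of that compartment's rasterized polygons
(lumen and out-of-tissue pixels count toward neither); mm² areas are
`count · (pixel_size_um/1000)²`, and the E/S ratio is undefined — not
infinite — when the stromal area is zero, flagged in the export.
Overlapping ROIs of the same compartment union; pixels under ROIs of
different compartments count in each. Cohort aggregation averages
per-slide ratios (mean ± sample sd, ddof = 1), matching per-slide
bookkeeping; a pooled mode (summing areas before dividing) is available
as an option.

## Evaluation protocol

Experts assign every pixel to lumen/stroma/epithelium. The consensus is
a per-pixel majority vote; hard labels admit no other exact "average",
and ties (possible with an even expert count) resolve by the fixed
priority epithelium > stroma > lumen so the vote is deterministic and
auditable. Scoring eliminates lumen-consensus pixels, then counts
TP/FP/FN/TN of the predicted epithelium mask; precision, recall and F1
follow the standard definitions, and specificity is TN/(TN+FP).
Predicted-lumen pixels with non-lumen consensus stay in the scoring
domain and count as FN or TN by their predicted E membership.
Multi-FOV benchmarking pools counts before forming ratios; expert
self-scoring supports leave-one-out (default) or full-consensus
references.

## Synthetic slides

The generator emulates the acquisition challenges on a 4×4 mosaic of
96×96 tiles (384² px, 8-bit by default):

* **Layout** — a mucosa region (left half) densely packed with crypts:
  epithelial rings (default thickness 8 px) around dark lumina on a
  jittered hexagonal lattice with stroma gaps of `min_band + 1..6` px;
  designated horizontal crypt pairs are pulled to *exactly* 5 px apart
  and their corridor pixels recorded for thin-band scoring. A stroma
  strip to the right carries tumor-bud clusters (1–10 round cells,
  radius 4 px) and erythrocyte-like artifact blobs; a bare-glass band
  (12.5% of width) forms the slide edge. One solid keratin-positive
  tumor nest (radius 65 px) is centered on a mucosa tile, creating at
  least one tile with neither lumen nor stroma.
* **Optics** — class means per channel (8-bit, pre-gradient): lumen
  5/3/5/3, stroma 160/42/40/15, epithelium 60/20/160/15
  (DAPI/GFP/TxRed/Cy5). Stroma is DAPI-bright (dense stromal nuclei)
  and mildly GFP-autofluorescent (collagen): this makes tissue roughly
  homogeneous in `VC_tissue` — as in stained sections, where every
  tissue class carries signal in some channel — while leaving stroma
  with a realistic noise tail in `VC_epi`. Artifact blobs are bright in
  TxRed (180) and brighter in GFP (190), so the virtual-channel
  subtraction cancels them. Nuclear holes (radius 1.8 px, DAPI-bright,
  TxRed ≈ 50) punch into epithelium; DAPI-bright nuclei dot the stroma.
* **Nonuniform staining** — a per-tile multiplicative gain ramping over
  [0.6, 1.4] along a random axis and direction with ±0.05 per-tile
  jitter, applied to all channels; Gaussian noise (sd 6) is added and
  values clipped to the bit depth. The gain range reflects the strong
  regional expression differences seen between tumor center and
  margins; at ±40%, squaring in the enhancement spreads the epithelial
  class ≈ 5-fold, which is what defeats single-global-threshold
  segmentation while remaining within AGS's adaptation corridor.
* **Ground truth** — every pixel is labeled lumen/stroma/epithelium/
  artifact exactly; artifact pixels are excluded from the geometric E/S
  accounting and annotated as stroma in derived expert labelings (the
  analysis protocol excludes artifact areas). Given a target E/S ratio
  the generator solves the ring thickness (TC) by bisection on
  rasterized counts, or the bud-cell count (IF2) with a top-up loop,
  to within ≈ 1–2%. Fixed seed ⇒ bit-identical output; infeasible
  packings raise an error.
* **Simulated experts** — each annotator is the truth with class
  boundaries displaced by a smooth random field of amplitude ≤ the
  jitter (signed-distance thresholding); zero jitter reproduces the
  truth exactly.

What the generator does **not** emulate: photorealistic texture,
JPEG-compression artifacts, autofocus/z-stack effects, folded-tissue
geometry beyond bright blobs, and within-tile staining gradients.
Passing tests on this family shows the algorithmic contracts hold under
the listed challenge structure, not that the calibration transfers to
acquired slides — on real data `c`, `p`, `α` and the corridors must be
re-calibrated per staining batch, as the protocol prescribes.

## Benchmark calibration (frozen)

`epstra.benchmark` fixes the family configuration: enhancement
c = 8/6/10/6, p = 2; branch 1 `α = 5000`, corridor `[0, 8000]`,
`clip_reference`, `min_fallback_fraction = 0.002`; branch 2
`α = 0.75·T_ref`, corridor `[1500, 6000]`, `clip_reference`,
`min_fallback_fraction = 0.15`; AGSm radius 2 on both branches. The
corridors were read off pilot virtual-channel histograms: `[0, 8000]`
spans glass/lumen plus the dark-tissue tail around the lumen|tissue
boundary, `[1500, 6000]` spans the stroma-tail/dark-epithelium gap.
The benchmark family is 24 FOVs (default generator, one sub-seed each);
high-ratio measurement slides use a denser, nest-free mucosa
(`DENSE_TC_PARAMS`: crypt radius 38 px, minimal lattice gaps, 80%
mucosa) because E/S = 2 — a tumor-center morphology of thick glands
with thin stroma — is geometrically unreachable in the default lattice.

## Numerical choices and degenerate inputs

* Threshold semantics: pixels with bin index ≤ cut are class-low
  ("≤ threshold → low"); the top histogram bin is closed.
* All-one-class slides (e.g. fully dark): the whole domain is class-low
  (no tissue), masks stay consistent, reference threshold is NaN.
* Empty branch-2 domain (no tissue) skips the branch; S and E are
  empty.
* Tiles wholly outside the restriction domain are skipped and recorded.
* Degenerate ROI polygons (zero area) warn and contribute no pixels.
* Expert vote with one expert is the identity; mismatched extents are
  an error, as is scoring with zero non-lumen pixels.

## Known limitations

* The guard/corridor logic assumes the calibrated corridor actually
  brackets the class boundary across the whole slide; staining
  variation far beyond the calibrated range degrades to
  reference-threshold behavior tile by tile (visible in the audit
  trail as degenerate fallbacks).
* Tie-low Otsu places in-gap thresholds at the bottom of the gap, so
  accepted thresholds on well-separated tiles sit near the low class's
  upper tail; the guard bounds must be chosen with that in mind.
* Area measurement counts overlapping compartments multiply by design;
  exclusive assignment would need a precedence rule the protocol does
  not define.
* The morphological-hierarchy comparison method from the wider
  literature is out of scope; evaluation reports list it as not
  implemented.
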