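# epstra

Epithelium–stroma segmentation and E/S ratio quantification for
multichannel immunofluorescence whole-slide images of colorectal cancer.

In colorectal tumors the balance between keratin-8-positive epithelium
(E) and the surrounding stroma (S) carries prognostic information: a
shrinking E/S ratio at the invasive front accompanies stromal expansion
and tumor budding. Quantifying it requires segmenting every field of
view (FOV) of a slide mosaic into **lumen**, **stroma** and
**epithelium** at full resolution — robustly against nonuniform
staining, keratin-negative nuclear holes, erythrocyte autofluorescence
and stroma bands as thin as 5 px. This package implements that pipeline
for slides acquired as tiled grayscale mosaics in four fluorescence
channels (DAPI, GFP/FITC, TxRed, Cy5), together with the baselines it is
compared against, a pixel-level expert-consensus evaluation protocol,
and a synthetic slide generator with exact ground truth so the whole
pipeline is testable without any acquired data.

## Method

Each channel *I* is enhanced by background subtraction and power
emphasis, `Ie = (max(I − c, 0))^p` with per-channel constants `c` and
`p > 1`, and combined into two virtual channels:

```
VC_tissue = Ie(DAPI) + Ie(GFP) + Ie(TxRed) + Ie(Cy5)
VC_epi    = Ie(TxRed) − Ie(GFP) − Ie(Cy5)      (clamped at 0)
```

The subtraction in `VC_epi` cancels structures bright in both TxRed and
GFP (erythrocytes, folded tissue) while keeping keratin-positive
epithelium.

Segmentation is **Adaptive Guided Segmentation (AGS)**: a slide-global
reference threshold `T_ref` is computed with Otsu's method on the
virtual-channel histogram; each mosaic tile is then Otsu-thresholded on
its own, and the tile threshold is accepted only inside the guard
interval `[T_ref − α, T_ref + α]`. Rejected tiles — typically tiles
containing a single intensity class, where unconstrained Otsu would
split that class in half — are re-thresholded on the pixel population
clipped to a calibrated corridor `[T_min, T_max]` that brackets the two
classes of interest. Two branches produce four mutually consistent
masks: lumen/tissue from `VC_tissue` over the whole slide, then
stroma/epithelium from `VC_epi` restricted to the tissue mask. Contours
are smoothed by one morphological closing and one opening with a small
disk (≤ 5 px, "AGSm"), which also fills the nuclear holes in the keratin
channel, and the partitions `L ⊎ T = slide`, `S ⊎ E = T` are repaired
exactly after smoothing.

Reference baselines: global Otsu (**GT**), independent per-tile Otsu
(**LT**), each optionally followed by morphological postprocessing
(**MP**, a closing that fills nuclear holes). E and S areas are measured
inside polygon regions of interest labeled by tumor compartment (NM,
Mu, AM, TC, IF1, IF2) and converted to mm² via the pixel size
(0.323 µm default); ratios aggregate to cohort means ± sd.

## Worked example

```
$ epstra simulate --out demo/slide --seed 7 --experts 3
wrote slide to demo/slide (counts: {'lumen': 28238, 'stroma': 89896,
                                    'epithelium': 28904, 'artifact': 418})

$ epstra segment --slide demo/slide --config demo/config.json --out demo/seg
EPSTRA: masks written to demo/seg

$ epstra measure --seg demo/seg --rois demo/slide/rois.geojson \
                 --out demo/measure.csv --slide-id demo
slide_id compartment roi_ids  e_area_px  s_area_px  e_area_mm2  s_area_mm2  es_ratio
    demo          TC       0      27441      35485    0.002863    0.003702  0.773313
    demo         IF2       1       1122      35088    0.000117    0.003661  0.031977

$ epstra evaluate --pred demo/seg --truth demo/slide/expert1.png \
                  --truth demo/slide/expert2.png --truth demo/slide/expert3.png \
                  --out demo/metrics.csv
    method    tp  fp  fn    tn  specificity  precision   recall       f1
prediction 28710  30 194 90284     0.999668   0.998956 0.993288 0.996114
   expert1 28894  30  80 90311     0.999668   0.998963 0.997239 0.998100
   expert2 28867  47  90 90321     0.999480   0.998374 0.996892 0.997633
   expert3 28793  23 188 90302     0.999745   0.999202 0.993513 0.996349
```

The measurement rows give epithelial and stromal pixel counts and areas
per ROI compartment and their ratio — here the crypt-dense tumor-center
ROI has E/S ≈ 0.77 while the invasive-front ROI, whose epithelium
consists only of small tumor-bud clusters, has E/S ≈ 0.03. The
evaluation table scores the predicted epithelium mask against the
majority-vote consensus of three simulated annotators (lumen pixels
eliminated before counting); the prediction's F1 of 0.996 sits in the
range of the individual annotators scored leave-one-out against each
other (0.996–0.998). `demo/config.json` holds the calibration used
throughout the package's benchmarks (`epstra.benchmark`); see
`docs/methods.md`.

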