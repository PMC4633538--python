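"""Frozen study configurations for the synthetic benchmark family.

The enhancement constants and AGS guard/clipping windows below were
calibrated once on pilot slides from the default generator, the same way
the protocol prescribes calibrating them per staining batch: the
background constants ``c`` sit just above the glass/lumen intensity, and
the per-branch corridors ``[T_min, T_max]`` bracket the virtual-channel
range where the branch's two classes meet (lumen|tissue for branch 1,
stroma|epithelium for branch 2; units are enhanced-intensity values of
the respective virtual channel).  They are the package's reference
configuration for 8-bit slides produced by :mod:`epstra.synth` with the
default optical model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ags import AgsParams, SegmentationResult, segment_slide
from .baselines import BaselineSpec, run_baseline
from .enhance import EnhancementParams
from .evaluate import ExpertLabeling, benchmark_methods
from .synth import GroundTruthMap, SynthParams, generate_slide
from .slide_io import MultiChannelSlide, RoiSet

#: background constants just above the glass/lumen level; emphasis p = 2
FAMILY_ENHANCEMENT = EnhancementParams(
    c={"DAPI": 8.0, "GFP": 6.0, "TxRed": 10.0, "Cy5": 6.0})

#: branch 1 (lumen vs tissue on VC_tissue): the corridor [0, 8000] spans
#: the glass/lumen mass and the dark-tissue tail around the lumen|tissue
#: boundary; tiles without lumen fall back and, with almost no corridor
#: pixels, inherit the reference threshold.
FAMILY_AGS_TISSUE = AgsParams(
    alpha=5000.0, t_min=0.0, t_max=8000.0, clip_reference=True,
    clamp_fallback=False, min_fallback_fraction=0.002, smoothing_radius=2)

#: branch 2 (stroma vs epithelium on VC_epi within tissue): the corridor
#: [1500, 6000] brackets the stroma-tail / dark-epithelium gap.
FAMILY_AGS_EPI = AgsParams(
    alpha_frac=0.75, t_min=1500.0, t_max=6000.0, clip_reference=True,
    clamp_fallback=False, min_fallback_fraction=0.15, smoothing_radius=2)

#: dense, nest-free mucosa used for high E/S ratio targets in the TC ROI
DENSE_TC_PARAMS = dict(
    mucosa_frac=0.8, glass_frac=0.08, crypt_radius=(38.0, 38.0),
    n_nests=0, lattice_gap_extra=0.0, n_thin_band_pairs=1, n_bud_clusters=2)


def segment_epstra(slide: MultiChannelSlide, n_workers: int = 1) -> SegmentationResult:
    """EPSTRA segmentation under the family calibration."""
    return segment_slide(slide, FAMILY_ENHANCEMENT, FAMILY_AGS_TISSUE,
                         FAMILY_AGS_EPI, n_workers=n_workers)


def segment_baseline(slide: MultiChannelSlide, spec: BaselineSpec) -> SegmentationResult:
    """Baseline segmentation under the family enhancement constants."""
    return run_baseline(slide, FAMILY_ENHANCEMENT, spec)


STANDARD_METHODS: dict[str, BaselineSpec | None] = {
    "EPSTRA": None,
    "GT": BaselineSpec("GT"),
    "GT+MP": BaselineSpec("GT", use_mp=True, mp_radius=3),
    "LT": BaselineSpec("LT"),
    "LT+MP": BaselineSpec("LT", use_mp=True, mp_radius=3),
}


def generate_benchmark_fovs(n_fovs: int = 24, seed: int = 0
                            ) -> list[tuple[MultiChannelSlide, GroundTruthMap, RoiSet]]:
    """The benchmark family: FOVs spanning the generator's challenge set
    (tile gradients, 5-px stroma bands, nuclear holes, tumor-bud clusters,
    artifact blobs, solid nests), one sub-seed per FOV."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_fovs):
        sub = int(rng.integers(0, 2**31 - 1))
        out.append(generate_slide(SynthParams(seed=sub)))
    return out


def run_benchmark(n_fovs: int = 24, seed: int = 0,
                  methods: dict[str, BaselineSpec | None] | None = None
                  ) -> pd.DataFrame:
    """Segment every benchmark FOV with every method and pool the
    epithelium metrics against the exact ground truth."""
    methods = methods if methods is not None else STANDARD_METHODS
    fovs = generate_benchmark_fovs(n_fovs, seed)
    truths: list[ExpertLabeling] = [t.to_expert() for _, t, _ in fovs]
    predictions: dict[str, list[SegmentationResult]] = {}
    for name, spec in methods.items():
        predictions[name] = [
            segment_epstra(slide) if spec is None else segment_baseline(slide, spec)
            for slide, _, _ in fovs
        ]
    return benchmark_methods(predictions, truths)


def generate_ratio_slide(target: float, compartment: str, seed: int,
                         max_tries: int = 8):
    """Generate a slide whose geometric E/S ratio inside the given ROI
    hits ``target``, retrying deterministically on infeasible packings."""
    from .synth import PackingError
    extra = DENSE_TC_PARAMS if compartment == "TC" else {}
    last: Exception | None = None
    for k in range(max_tries):
        try:
            params = SynthParams(seed=seed + 7919 * k, target_es_ratio=target,
                                 ratio_compartment=compartment, **extra)
            return generate_slide(params)
        except PackingError as exc:   # rare unlucky lattice draw
            last = exc
    raise last
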