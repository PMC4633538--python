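"""Reference thresholding methods: global Otsu (GT) and independent
per-tile Otsu (LT), each optionally followed by morphological
postprocessing (MP, a closing that fills keratin-negative nuclear holes).

These deliberately re-implement the threshold *application* directly
(rather than routing through the AGS guard machinery) so the degenerate
collapse of AGS onto GT/LT can be verified as a genuine equivalence:

* GT equals AGS with every tile forced to the reference threshold;
* LT equals AGS with an infinite guard interval.

Both baselines share the two-branch structure and partition repair of the
EPSTRA workflow, and the same histogram binning, so the comparison is
pixel-exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import closing, disk

from .ags import (BinGrid, SegmentationResult, ThresholdDecision,
                  _tile_slices, otsu_threshold)
from .enhance import EnhancementParams, build_vc_epi, build_vc_tissue
from .slide_io import MultiChannelSlide

MP_HARD_MAX = 10  # closing radii beyond this destroy thin stroma outright


@dataclass
class BaselineSpec:
    """Which baseline to run: method GT or LT, with or without MP."""

    method: str = "GT"
    use_mp: bool = False
    mp_radius: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("GT", "LT"):
            raise ValueError("method must be 'GT' or 'LT'")
        if self.use_mp:
            if self.mp_radius < 1:
                raise ValueError("mp_radius must be >= 1 when use_mp")
            if self.mp_radius > MP_HARD_MAX:
                raise ValueError(f"mp_radius above {MP_HARD_MAX} is not supported")
            if self.mp_radius > 5:
                warnings.warn("MP radius above 5 px sharply degrades contour "
                              "accuracy and thin-stroma recognition",
                              stacklevel=2)

    @property
    def name(self) -> str:
        return self.method + ("+MP" if self.use_mp else "")


def _baseline_branch(vc: np.ndarray, tile_shape: tuple[int, int], method: str,
                     domain: np.ndarray) -> tuple[np.ndarray, np.ndarray, list, float]:
    """One thresholding branch; returns (low, high, decisions, t_ref)."""
    low = np.zeros(vc.shape, dtype=bool)
    high = np.zeros(vc.shape, dtype=bool)
    decisions: list[ThresholdDecision] = []
    dom_values = vc[domain]
    grid = BinGrid.from_values(dom_values)
    binned = grid.index(vc)
    k_ref = otsu_threshold(np.bincount(binned[domain], minlength=grid.nbins)) \
        if dom_values.size else None
    if k_ref is None:
        low |= domain
        return low, high, decisions, math.nan
    t_ref = grid.upper_edge(k_ref)
    for idx, sl in _tile_slices(vc.shape, tile_shape):
        sel = domain[sl]
        dec = ThresholdDecision(idx)
        if not sel.any():
            dec.skipped = True
            decisions.append(dec)
            continue
        if method == "GT":
            k, dec.forced, dec.final_threshold = k_ref, True, t_ref
        else:  # LT: unconstrained per-tile Otsu
            k = otsu_threshold(np.bincount(binned[sl][sel], minlength=grid.nbins))
            if k is None:
                k, dec.degenerate, dec.final_threshold = k_ref, True, t_ref
            else:
                dec.raw_otsu = dec.final_threshold = grid.upper_edge(k)
                dec.accepted = True
        decisions.append(dec)
        low[sl] = sel & (binned[sl] <= k)
        high[sl] = sel & (binned[sl] > k)
    return low, high, decisions, t_ref


def run_baseline(slide: MultiChannelSlide,
                 enh_params: EnhancementParams | None = None,
                 spec: BaselineSpec | None = None) -> SegmentationResult:
    """Segment a slide with a baseline thresholding method.

    Same two-branch flow as EPSTRA (tissue/lumen on VC_tissue, then
    stroma/epithelium on VC_epi within the tissue mask), but with plain
    global or per-tile thresholds and, when requested, an MP closing of
    the high-class mask in place of AGSm smoothing.
    """
    enh_params = enh_params or EnhancementParams()
    spec = spec or BaselineSpec()
    se = disk(spec.mp_radius) if spec.use_mp else None

    vc_t = build_vc_tissue(slide, enh_params)
    _, high_t, dec_t, tref_t = _baseline_branch(
        vc_t, slide.tile_shape, spec.method, np.ones(vc_t.shape, dtype=bool))
    t_mask = closing(high_t, se).astype(bool) if se is not None else high_t
    l_mask = ~t_mask

    decisions = {"tissue": dec_t}
    e_mask = np.zeros(t_mask.shape, dtype=bool)
    tref_e = math.nan
    if t_mask.any():
        vc_e = build_vc_epi(slide, enh_params)
        _, high_e, dec_e, tref_e = _baseline_branch(
            vc_e, slide.tile_shape, spec.method, t_mask)
        e_mask = (closing(high_e, se).astype(bool) if se is not None else high_e) & t_mask
        decisions["epi"] = dec_e
    s_mask = t_mask & ~e_mask

    result = SegmentationResult(l_mask, t_mask, s_mask, e_mask,
                                t_ref_tissue=tref_t, t_ref_epi=tref_e,
                                decisions=decisions, method=spec.name)
    result.validate()
    return result
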