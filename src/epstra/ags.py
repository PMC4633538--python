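"""Adaptive Guided Segmentation (AGS) and the two-branch EPSTRA workflow.

AGS thresholds a virtual channel tile by tile.  A slide-global reference
threshold ``T_ref`` is first computed with Otsu's method on the histogram of
the entire (possibly mask-restricted) virtual slide.  Each tile is then
Otsu-thresholded on its own; the tile threshold is *accepted* only if it
lies inside the guard interval ``[T_ref - alpha, T_ref + alpha]``.  This
guards against the classic Otsu failure on single-class tiles (e.g. a tile
containing only stroma), where an unconstrained threshold would split one
class in two.  A rejected tile is re-thresholded on the clipped pixel
population inside ``[T_min, T_max]``, which removes the dark background
mass and bright outliers so that Otsu again sees the two classes of
interest.

Segmentation proceeds in two branches:

1. lumen vs tissue on ``VC_tissue`` over the whole slide, then
2. stroma vs epithelium on ``VC_epi`` restricted to the tissue mask,

each followed by contour smoothing (one morphological closing then one
opening with a small disk, "AGSm") and a partition repair that recomputes
each complement within its parent region, so that L and T exactly
partition the slide and S and E exactly partition T.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.morphology import closing, disk, opening

from .enhance import EnhancementParams, build_vc_epi, build_vc_tissue
from .slide_io import MultiChannelSlide

DEFAULT_NBINS = 256


def otsu_threshold(counts: Sequence[float],
                   centers: Sequence[float] | None = None) -> int | None:
    """Otsu's threshold on a histogram; returns the index of the last
    low-class bin, or ``None`` when the histogram is degenerate.

    The cut maximizes the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2`` over all cut positions with both classes
    non-empty; ties are broken toward the smallest threshold.  A histogram
    with all mass in a single bin has no two-class split and is flagged
    degenerate (``None``); the caller decides the fallback.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("histogram must be a 1-D array with >= 2 bins")
    if np.count_nonzero(counts) < 2:
        return None
    if centers is None:
        centers = np.arange(counts.size, dtype=np.float64)
    else:
        centers = np.asarray(centers, dtype=np.float64)
    w0 = np.cumsum(counts)[:-1]
    m0 = np.cumsum(counts * centers)[:-1]
    total, m_total = w0[-1] + counts[-1], m0[-1] + counts[-1] * centers[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros_like(w0)
    mu0 = np.divide(m0, w0, out=np.zeros_like(w0), where=valid)
    mu1 = np.divide(m_total - m0, w1, out=np.zeros_like(w0), where=valid)
    sigma_b[valid] = (w0 * w1)[valid] * (mu0 - mu1)[valid] ** 2
    return int(np.argmax(sigma_b))


@dataclass(frozen=True)
class BinGrid:
    """Uniform histogram binning shared by the global reference and every
    tile, so per-tile and slide-global thresholds are directly comparable."""

    lo: float
    hi: float
    nbins: int = DEFAULT_NBINS

    @classmethod
    def from_values(cls, values: np.ndarray, nbins: int = DEFAULT_NBINS) -> "BinGrid":
        if values.size == 0:
            return cls(0.0, 0.0, nbins)
        return cls(float(values.min()), float(values.max()), nbins)

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.nbins if self.hi > self.lo else 0.0

    def index(self, values: np.ndarray) -> np.ndarray:
        """Bin index per pixel; the top bin is closed (max value included)."""
        if self.hi <= self.lo:
            return np.zeros(np.shape(values), dtype=np.int64)
        idx = np.floor((np.asarray(values) - self.lo) / self.width).astype(np.int64)
        return np.clip(idx, 0, self.nbins - 1)

    def upper_edge(self, k: int) -> float:
        """Threshold value associated with cut index k (upper edge of the
        last low bin); pixels with value < this edge are class-low."""
        return self.lo + (k + 1) * self.width

    def cut_for_value(self, value: float) -> int:
        """Cut index whose boundary is nearest to ``value``."""
        if self.width == 0.0:
            return 0
        k = int(round((value - self.lo) / self.width)) - 1
        return min(max(k, 0), self.nbins - 1)


@dataclass
class AgsParams:
    """Tuning constants of one AGS branch.

    ``alpha`` is the guard-interval half width, ``t_min``/``t_max`` the
    clipping bounds used on fallback — all in the intensity units of the
    virtual channel being thresholded.  Any of the three left as ``None``
    is resolved relative to the reference threshold once it is known,
    as ``alpha_frac * T_ref`` etc.; the fraction defaults are scale-free
    (``alpha = 0.25 T_ref``, ``[t_min, t_max] = [0.5, 2] T_ref``).  Like
    the original protocol's constants they should be calibrated per
    staining batch by inspecting virtual-channel histograms (see docs).

    ``smoothing_radius`` is the disk radius of the AGSm closing/opening
    pass (0 disables smoothing, maximum 5).  ``clamp_fallback`` clamps a
    fallback threshold that is still outside the guard interval onto the
    nearer interval endpoint.  ``force_reference`` short-circuits every
    tile to ``T_ref`` (global thresholding through the AGS machinery).
    ``min_fallback_fraction`` is the smallest share of a tile's pixels the
    clipped population may have before the fallback is considered
    unsupported and ``T_ref`` is applied instead.

    ``clip_reference`` computes the slide-global reference threshold on
    the clipped population inside ``[t_min, t_max]`` as well (requires
    absolute ``t_min``/``t_max``).  On slides whose virtual channel has
    more than two intensity classes (e.g. a wide staining gradient), the
    unrestricted whole-slide Otsu can land inside the broad bright class;
    restricting it to the calibrated corridor of the two classes of
    interest keeps the reference meaningful.
    """

    alpha: float | None = None
    t_min: float | None = None
    t_max: float | None = None
    alpha_frac: float = 0.25
    t_min_frac: float = 0.5
    t_max_frac: float = 2.0
    smoothing_radius: int = 2
    clamp_fallback: bool = True
    force_reference: bool = False
    min_fallback_fraction: float = 0.005
    clip_reference: bool = False

    def __post_init__(self) -> None:
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if (self.t_min is not None and self.t_max is not None
                and not self.t_min < self.t_max):
            raise ValueError("t_min must be < t_max")
        if not 0 <= self.smoothing_radius <= 5:
            raise ValueError("smoothing_radius must be in [0, 5]")
        if self.clip_reference and (self.t_min is None or self.t_max is None):
            raise ValueError("clip_reference requires absolute t_min and t_max")

    def resolve(self, t_ref: float) -> "AgsParams":
        """Fill relative defaults from the reference threshold value."""
        scale = abs(t_ref)
        return replace(
            self,
            alpha=self.alpha if self.alpha is not None else self.alpha_frac * scale,
            t_min=self.t_min if self.t_min is not None else self.t_min_frac * t_ref,
            t_max=self.t_max if self.t_max is not None else self.t_max_frac * t_ref,
        )


@dataclass
class ThresholdDecision:
    """Audit record of the thresholding decision taken on one tile."""

    tile_index: tuple[int, int]
    raw_otsu: float = math.nan
    accepted: bool = False
    fallback_used: bool = False
    degenerate: bool = False
    skipped: bool = False
    forced: bool = False
    final_threshold: float = math.nan


@dataclass
class AgsResult:
    low_mask: np.ndarray
    high_mask: np.ndarray
    decisions: list[ThresholdDecision]
    t_ref: float
    bin_grid: BinGrid


def _tile_slices(extent: tuple[int, int],
                 tile_shape: tuple[int, int]) -> list[tuple[tuple[int, int], tuple[slice, slice]]]:
    rows, cols = extent
    tr, tc = tile_shape
    out = []
    for r in range(rows // tr):
        for c in range(cols // tc):
            out.append(((r, c), (slice(r * tr, (r + 1) * tr),
                                 slice(c * tc, (c + 1) * tc))))
    return out


def ags(vc: np.ndarray,
        tile_shape: tuple[int, int],
        params: AgsParams | None = None,
        restrict_to: np.ndarray | None = None,
        n_workers: int = 1) -> AgsResult:
    """Run Adaptive Guided Segmentation of one virtual channel.

    Returns low/high masks that partition the restriction domain (the
    whole slide when ``restrict_to`` is None); pixels outside the domain
    belong to neither mask.  One :class:`ThresholdDecision` is recorded
    per tile.
    """
    params = params or AgsParams()
    vc = np.asarray(vc, dtype=np.float64)
    domain = (np.ones(vc.shape, dtype=bool) if restrict_to is None
              else np.asarray(restrict_to, dtype=bool))
    low = np.zeros(vc.shape, dtype=bool)
    high = np.zeros(vc.shape, dtype=bool)
    tiles = _tile_slices(vc.shape, tile_shape)

    dom_values = vc[domain]
    grid = BinGrid.from_values(dom_values)
    binned = grid.index(vc)
    ref_domain = domain
    if params.clip_reference:
        ref_domain = domain & (vc >= params.t_min) & (vc <= params.t_max)
        if not ref_domain.any():
            ref_domain = domain
    k_ref = otsu_threshold(np.bincount(binned[ref_domain], minlength=grid.nbins)) \
        if dom_values.size else None
    if k_ref is None and params.clip_reference and dom_values.size:
        k_ref = otsu_threshold(np.bincount(binned[domain], minlength=grid.nbins))
    if k_ref is None:
        # single-class (or empty) slide: everything in the domain is low
        low |= domain
        decs = [ThresholdDecision(idx, degenerate=True, skipped=not domain[sl].any())
                for idx, sl in tiles]
        return AgsResult(low, high, decs, math.nan, grid)

    t_ref = grid.upper_edge(k_ref)
    p = params.resolve(t_ref)
    guard_lo, guard_hi = t_ref - p.alpha, t_ref + p.alpha

    def process(item: tuple[tuple[int, int], tuple[slice, slice]]) -> tuple:
        idx, sl = item
        sel = domain[sl]
        dec = ThresholdDecision(idx)
        if not sel.any():
            dec.skipped = True
            return idx, sl, None, dec
        tile_b = binned[sl]
        tile_v = vc[sl]
        if p.force_reference:
            dec.forced = True
            dec.final_threshold = t_ref
            return idx, sl, k_ref, dec
        k_i = otsu_threshold(np.bincount(tile_b[sel], minlength=grid.nbins))
        if k_i is None:
            dec.degenerate = True
            dec.final_threshold = t_ref
            return idx, sl, k_ref, dec
        dec.raw_otsu = grid.upper_edge(k_i)
        if guard_lo <= dec.raw_otsu <= guard_hi:
            dec.accepted = True
            dec.final_threshold = dec.raw_otsu
            return idx, sl, k_i, dec
        # fallback: re-threshold the population clipped to [t_min, t_max]
        dec.fallback_used = True
        clip_sel = sel & (tile_v >= p.t_min) & (tile_v <= p.t_max)
        if clip_sel.sum() < p.min_fallback_fraction * sel.sum():
            dec.fallback_used = False
            dec.degenerate = True
            dec.final_threshold = t_ref
            return idx, sl, k_ref, dec
        k_f = otsu_threshold(np.bincount(tile_b[clip_sel], minlength=grid.nbins))
        if k_f is None:
            dec.fallback_used = False
            dec.degenerate = True
            dec.final_threshold = t_ref
            return idx, sl, k_ref, dec
        t_f = grid.upper_edge(k_f)
        if p.clamp_fallback and not guard_lo <= t_f <= guard_hi and grid.width > 0:
            if t_f < guard_lo:   # smallest cut whose boundary is inside the guard
                k_f = math.ceil((guard_lo - grid.lo) / grid.width) - 1
            else:                # largest cut whose boundary is inside the guard
                k_f = math.floor((guard_hi - grid.lo) / grid.width) - 1
            k_f = min(max(k_f, 0), grid.nbins - 1)
            t_f = grid.upper_edge(k_f)
        dec.final_threshold = t_f
        return idx, sl, k_f, dec

    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(process, tiles))
    else:
        results = [process(t) for t in tiles]

    decisions = []
    for _, sl, k_final, dec in sorted(results, key=lambda r: r[0]):
        decisions.append(dec)
        if k_final is None:
            continue
        sel = domain[sl]
        low[sl] = sel & (binned[sl] <= k_final)
        high[sl] = sel & (binned[sl] > k_final)
    return AgsResult(low, high, decisions, t_ref, grid)


def agsm_smooth(mask: np.ndarray, radius: int = 2) -> np.ndarray:
    """AGSm contour smoothing: one closing then one opening with a disk.

    The closing fills small holes (e.g. keratin-negative nuclei inside
    epithelium), the opening removes isolated specks; the composite filter
    is idempotent.  Radius 0 returns the mask unchanged.
    """
    if not 0 <= radius <= 5:
        raise ValueError("smoothing radius must be in [0, 5]")
    mask = np.asarray(mask, dtype=bool)
    if radius == 0:
        return mask.copy()
    se = disk(radius)
    return opening(closing(mask, se), se).astype(bool)


@dataclass
class SegmentationResult:
    """Four mutually consistent binary masks plus the threshold audit trail.

    ``l_mask`` and ``t_mask`` partition the slide; ``s_mask`` and
    ``e_mask`` partition ``t_mask``.
    """

    l_mask: np.ndarray
    t_mask: np.ndarray
    s_mask: np.ndarray
    e_mask: np.ndarray
    t_ref_tissue: float = math.nan
    t_ref_epi: float = math.nan
    decisions: dict[str, list[ThresholdDecision]] = field(default_factory=dict)
    method: str = "EPSTRA"

    def validate(self) -> None:
        full = np.ones(self.l_mask.shape, dtype=bool)
        if not ((self.l_mask ^ self.t_mask) == full).all():
            raise AssertionError("L and T do not partition the slide")
        if (self.s_mask & self.e_mask).any():
            raise AssertionError("S and E overlap")
        if not ((self.s_mask | self.e_mask) == self.t_mask).all():
            raise AssertionError("S and E do not cover T")

    def decisions_frame(self) -> pd.DataFrame:
        rows = []
        for branch, decs in self.decisions.items():
            for d in decs:
                rows.append({
                    "branch": branch, "tile_row": d.tile_index[0],
                    "tile_col": d.tile_index[1], "raw_otsu": d.raw_otsu,
                    "accepted": d.accepted, "fallback_used": d.fallback_used,
                    "degenerate": d.degenerate, "skipped": d.skipped,
                    "forced": d.forced, "final_threshold": d.final_threshold,
                })
        return pd.DataFrame(rows)


def segment_slide(slide: MultiChannelSlide,
                  enh_params: EnhancementParams | None = None,
                  ags_tissue: AgsParams | None = None,
                  ags_epi: AgsParams | None = None,
                  n_workers: int = 1) -> SegmentationResult:
    """Full EPSTRA segmentation of one slide into L/T/S/E masks.

    Branch 1 applies AGS to the tissue virtual channel over the whole
    slide; branch 2 applies AGS to the epithelium virtual channel only
    within the (smoothed) tissue mask, whose reference threshold is
    likewise computed only over tissue pixels.  After AGSm smoothing the
    partition is repaired: L = slide minus T, S = T minus E.
    """
    enh_params = enh_params or EnhancementParams()
    ags_tissue = ags_tissue or AgsParams()
    ags_epi = ags_epi or AgsParams()

    vc_t = build_vc_tissue(slide, enh_params)
    res_t = ags(vc_t, slide.tile_shape, ags_tissue, n_workers=n_workers)
    t_mask = agsm_smooth(res_t.high_mask, ags_tissue.smoothing_radius)
    l_mask = ~t_mask

    decisions = {"tissue": res_t.decisions}
    e_mask = np.zeros(t_mask.shape, dtype=bool)
    t_ref_epi = math.nan
    if t_mask.any():
        vc_e = build_vc_epi(slide, enh_params)
        res_e = ags(vc_e, slide.tile_shape, ags_epi, restrict_to=t_mask,
                    n_workers=n_workers)
        e_mask = agsm_smooth(res_e.high_mask, ags_epi.smoothing_radius) & t_mask
        t_ref_epi = res_e.t_ref
        decisions["epi"] = res_e.decisions
    s_mask = t_mask & ~e_mask

    result = SegmentationResult(l_mask, t_mask, s_mask, e_mask,
                                t_ref_tissue=res_t.t_ref, t_ref_epi=t_ref_epi,
                                decisions=decisions, method="EPSTRA")
    result.validate()
    return result
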