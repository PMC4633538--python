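"""Synthetic multichannel slide generator with exact ground truth.

One generated field of view mimics a colorectal-cancer section scanned in
four fluorescence channels:

* a *mucosa* region densely packed with crypts — epithelial rings
  (keratin-bright in TxRed) around dark lumina — separated by stroma
  bands that can be as thin as 5 px;
* an *invasive-front strip* of stroma carrying small epithelial cell
  clusters (tumor buds, up to 10 cells) and erythrocyte-like artifact
  blobs that are bright in both TxRed and GFP;
* keratin-negative nuclear holes punched into the TxRed signal inside
  epithelium (DAPI-bright), and DAPI-bright nuclei in the stroma;
* a tile-to-tile multiplicative staining gradient and Gaussian noise.

Every pixel carries an exact ground-truth label (lumen, stroma,
epithelium, artifact), which makes all segmentation and measurement
modules testable without any acquired data.  With a fixed seed the
generator is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from shapely.geometry import Polygon

from .evaluate import EPITHELIUM, LUMEN, STROMA, ExpertLabeling
from .slide_io import (DEFAULT_PIXEL_SIZE_UM, MultiChannelSlide, Roi, RoiSet,
                       TiledChannelImage, rasterize_rois)

ARTIFACT = 3

#: per-structure channel means before the staining gradient (8-bit scale).
#: Stroma is cell- and collagen-rich: DAPI-bright (dense nuclei) with mild
#: GFP autofluorescence, but only weakly keratin(TxRed)-positive; the
#: erythrocyte-like artifact is bright in both TxRed and GFP.
CLASS_MEANS = {
    "lumen": {"DAPI": 5, "GFP": 3, "TxRed": 5, "Cy5": 3},
    "stroma": {"DAPI": 160, "GFP": 42, "TxRed": 40, "Cy5": 15},
    "epi": {"DAPI": 60, "GFP": 20, "TxRed": 160, "Cy5": 15},
    "hole": {"DAPI": 140, "GFP": 20, "TxRed": 50, "Cy5": 15},
    "stroma_nucleus": {"DAPI": 200, "GFP": 42, "TxRed": 40, "Cy5": 15},
    "artifact": {"DAPI": 20, "GFP": 190, "TxRed": 180, "Cy5": 15},
}


class PackingError(ValueError):
    """Crypts cannot be packed under the requested geometry constraints."""


@dataclass
class SynthParams:
    """Study conditions of one generated field of view.

    Geometry is in pixels.  ``gradient_range`` is the span of the
    multiplicative per-tile staining factor; ``(1.0, 1.0)`` disables the
    gradient.  ``n_crypts`` caps the number of crypts kept from the dense
    packing lattice (None keeps all).  ``target_es_ratio`` solves the
    epithelial ring thickness (compartment ``TC``) or the tumor-bud count
    (compartment ``IF2``) so the geometric E/S ratio inside that ROI hits
    the target.
    """

    grid_shape: tuple[int, int] = (4, 4)
    tile_shape: tuple[int, int] = (96, 96)
    mucosa_frac: float = 0.5            # x-fraction of the slide that is mucosa
    glass_frac: float = 0.125           # x-fraction of bare glass at the right edge
    bud_region_frac: float = 0.67       # y-fraction of the strip carrying buds
    n_crypts: int | None = None
    n_nests: int = 1                    # solid epithelial tumor nests (no lumen)
    nest_radius: float = 65.0
    crypt_radius: tuple[float, float] = (18.0, 22.0)
    ring_thickness: float = 8.0
    min_stroma_band: int = 5
    lattice_gap_extra: float = 4.0
    n_thin_band_pairs: int = 2
    n_bud_clusters: int = 5
    bud_cells_per_cluster: tuple[int, int] = (2, 10)
    bud_cell_radius: float = 4.0
    nuclear_hole_radius: float = 1.8
    nuclear_hole_rate: float = 0.004    # holes per epithelial pixel
    stroma_nucleus_radius: float = 2.0
    stroma_nucleus_rate: float = 0.003
    gradient_range: tuple[float, float] = (0.6, 1.4)
    gradient_jitter: float = 0.05
    artifact_blobs: int = 2
    artifact_radius: tuple[float, float] = (5.0, 9.0)
    noise_sd: float = 6.0
    bit_depth: int = 8
    target_es_ratio: float | None = None
    ratio_compartment: str = "TC"
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crypt_radius", "bud_cells_per_cluster", "artifact_radius",
                     "gradient_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be an increasing positive range")
        if self.min_stroma_band < 1 or self.ring_thickness <= 0:
            raise ValueError("geometric parameters must be positive")
        if self.ratio_compartment not in ("TC", "IF2"):
            raise ValueError("ratio_compartment must be 'TC' or 'IF2'")

    @property
    def extent(self) -> tuple[int, int]:
        return (self.grid_shape[0] * self.tile_shape[0],
                self.grid_shape[1] * self.tile_shape[1])


@dataclass
class GroundTruthMap:
    """Exact per-pixel labels and geometry bookkeeping of one FOV."""

    labels: np.ndarray                  # 0 lumen, 1 stroma, 2 epi, 3 artifact
    bands: list[dict[str, Any]] = field(default_factory=list)
    es_ratio: float = math.nan          # geometric ratio in the ratio ROI
    counts: dict[str, int] = field(default_factory=dict)

    def tally(self) -> dict[str, int]:
        return {name: int(np.count_nonzero(self.labels == lbl))
                for name, lbl in (("lumen", LUMEN), ("stroma", STROMA),
                                  ("epithelium", EPITHELIUM), ("artifact", ARTIFACT))}

    def to_expert(self, expert_id: str = "truth") -> ExpertLabeling:
        """Collapse to the three-label expert vocabulary (artifact counts
        as stroma: visually it is non-epithelial tissue)."""
        labels = self.labels.copy()
        labels[labels == ARTIFACT] = STROMA
        return ExpertLabeling(labels, expert_id)


# ---------------------------------------------------------------------------
# geometry helpers


def _disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.ceil(radius))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = yy**2 + xx**2 <= radius**2
    return yy[keep], xx[keep]


def _stamp(mask_or_labels: np.ndarray, cy: float, cx: float, radius: float,
           value: int | bool, where: np.ndarray | None = None) -> None:
    dy, dx = _disk_offsets(radius)
    yy = np.round(cy + dy).astype(int)
    xx = np.round(cx + dx).astype(int)
    rows, cols = mask_or_labels.shape
    keep = (yy >= 0) & (yy < rows) & (xx >= 0) & (xx < cols)
    yy, xx = yy[keep], xx[keep]
    if where is not None:
        ok = where[yy, xx]
        yy, xx = yy[ok], xx[ok]
    mask_or_labels[yy, xx] = value


def _crypt_lattice(params: SynthParams, rng: np.random.Generator,
                   mucosa_w: int) -> list[dict[str, float]]:
    """Hexagonal-ish packing of crypts in the mucosa region.

    Adjacent lattice neighbours are separated by a stroma gap drawn from
    ``[min_band + 1, min_band + 6]``; designated horizontal pairs get a
    gap of exactly ``min_band`` to create the thin-band challenge.
    """
    rows_px = params.extent[0]
    r_lo, r_hi = params.crypt_radius
    r0 = float(rng.uniform(r_lo, r_hi))
    band = params.min_stroma_band
    pitch = 2 * r0 + band + params.lattice_gap_extra
    # crypts may be clipped by the slide edges (glands continue beyond the
    # FOV) but must stay clear of the stroma strip on the right
    margin_right = r0 + 3
    xs = np.arange(6.0, mucosa_w - margin_right + 1e-9, pitch)
    ys = np.arange(6.0, rows_px - 4 + 1e-9, pitch * math.sqrt(3) / 2)
    if xs.size < 2 or ys.size < 1:
        raise PackingError("mucosa region too small for the requested crypts")
    crypts = []
    for i, y in enumerate(ys):
        shift = (pitch / 2) if i % 2 else 0.0
        for x in xs:
            cx = x + shift
            if cx > mucosa_w - margin_right:
                continue
            jy, jx = rng.uniform(-1.5, 1.5, size=2)
            crypts.append({"cy": y + jy, "cx": cx + jx, "r": r0})
    if params.n_crypts is not None:
        if params.n_crypts < 2:
            raise PackingError("need at least 2 crypts")
        crypts = crypts[:params.n_crypts]
    return crypts


def _mark_thin_pairs(crypts: list[dict], params: SynthParams,
                     rng: np.random.Generator,
                     forbidden: set[int] | None = None) -> list[tuple[int, int]]:
    """Pick horizontal neighbour pairs and pull them to exactly
    ``min_stroma_band`` apart; returns index pairs."""
    band = params.min_stroma_band
    pairs: list[tuple[int, int]] = []
    order = rng.permutation(len(crypts))
    used: set[int] = set(forbidden or ())
    for i in order:
        if len(pairs) >= params.n_thin_band_pairs:
            break
        if i in used:
            continue
        ci = crypts[i]
        for j, cj in enumerate(crypts):
            if j == i or j in used:
                continue
            if abs(cj["cy"] - ci["cy"]) < 3 and 0 < cj["cx"] - ci["cx"] < 3 * ci["r"]:
                # move the right-hand crypt so the surface gap is exactly band
                cj["cx"] = ci["cx"] + ci["r"] + cj["r"] + band
                cj["cy"] = ci["cy"]
                pairs.append((i, j))
                used.update((i, j))
                break
    if len(pairs) < params.n_thin_band_pairs:
        raise PackingError("could not place the requested thin-band pairs")
    return pairs


def _signed_outside(extent: tuple[int, int],
                    crypts: list[dict]) -> np.ndarray:
    """Per-pixel minimum over crypts of (distance to centre - outer radius):
    negative inside a crypt disk, positive outside all of them."""
    rows, cols = extent
    yy, xx = np.mgrid[0:rows, 0:cols]
    m = np.full(extent, np.inf)
    for c in crypts:
        d = np.hypot(yy - c["cy"], xx - c["cx"]) - c["r"]
        np.minimum(m, d, out=m)
    return m


def _ratio_for_thickness(m: np.ndarray, roi: np.ndarray, t: float,
                         nest: np.ndarray | None = None) -> float:
    epi = (m <= 0) & (m > -t) & roi
    lumen = (m <= -t) & roi & ~epi
    if nest is not None:
        epi = (epi | nest) & roi
        lumen &= ~nest
    stroma = roi.sum() - epi.sum() - lumen.sum()
    return epi.sum() / stroma if stroma else math.inf


# ---------------------------------------------------------------------------
# main generator


def generate_slide(params: SynthParams | None = None,
                   seed: int | None = None
                   ) -> tuple[MultiChannelSlide, GroundTruthMap, RoiSet]:
    """Generate one synthetic FOV: slide channels, ground truth, ROIs.

    The returned ROI set contains a tumor-center-like region (``TC``,
    the crypt-packed mucosa) and an invasive-front-like region (``IF2``,
    the bud-carrying stroma strip).
    """
    params = params or SynthParams()
    if seed is not None:
        params = SynthParams(**{**params.__dict__, "seed": seed})
    rng = np.random.default_rng(params.seed)
    rows, cols = params.extent
    mucosa_w = int(round(params.mucosa_frac * cols))
    glass_x = cols - int(round(params.glass_frac * cols))
    bud_h = int(round(params.bud_region_frac * rows))
    if not mucosa_w < glass_x <= cols:
        raise ValueError("mucosa_frac and glass_frac leave no stroma strip")

    # ROIs first: the same rasterized masks serve ratio solving and truth
    rois = RoiSet([
        Roi(Polygon([(1, 1), (mucosa_w - 1, 1), (mucosa_w - 1, rows - 1),
                     (1, rows - 1)]), "TC", 0),
        Roi(Polygon([(mucosa_w + 1, 1), (glass_x - 1, 1), (glass_x - 1, bud_h - 1),
                     (mucosa_w + 1, bud_h - 1)]), "IF2", 1),
    ])
    roi_masks = rasterize_rois(rois, (rows, cols))
    tc_roi, strip = roi_masks["TC"], roi_masks["IF2"]

    crypts = _crypt_lattice(params, rng, mucosa_w)

    # solid tumor nests: keratin-positive areas with neither lumen nor
    # stroma, each centered on a mucosa tile so at least one tile is
    # single-class ("areas without lumen or stroma")
    tr_px, tc_px = params.tile_shape
    nest_mask = np.zeros((rows, cols), dtype=bool)
    yy0, xx0 = np.mgrid[0:rows, 0:cols]
    nest_cols = [c for c in range(params.grid_shape[1])
                 if (c + 0.5) * tc_px + params.nest_radius / 2 < mucosa_w]
    for k in range(params.n_nests):
        if not nest_cols:
            raise PackingError("no mucosa tile can host a tumor nest")
        r_t = int(rng.integers(params.grid_shape[0]))
        c_t = nest_cols[int(rng.integers(len(nest_cols)))]
        cy, cx = (r_t + 0.5) * tr_px, (c_t + 0.5) * tc_px
        nest_mask |= np.hypot(yy0 - cy, xx0 - cx) <= params.nest_radius
        crypts = [c for c in crypts
                  if math.hypot(c["cy"] - cy, c["cx"] - cx)
                  > params.nest_radius + c["r"] + 3]
    nest_mask[:, mucosa_w:] = False
    if len(crypts) < 2 * params.n_thin_band_pairs:
        raise PackingError("nests leave too few crypts for thin-band pairs")

    # keep thin-band corridors clear of the nests
    near_nest = {i for i, c in enumerate(crypts)
                 if nest_mask.any() and np.hypot(
                     yy0[nest_mask] - c["cy"], xx0[nest_mask] - c["cx"]
                 ).min() < c["r"] + 2 * params.min_stroma_band + 6}
    thin_pairs = _mark_thin_pairs(crypts, params, rng, forbidden=near_nest)
    m = _signed_outside((rows, cols), crypts)

    # epithelial ring thickness: fixed, or solved for a target E/S ratio
    thickness = params.ring_thickness
    if params.target_es_ratio is not None and params.ratio_compartment == "TC":
        lo, hi = 1.0, min(c["r"] for c in crypts) - 4.0
        if not _ratio_for_thickness(m, tc_roi, lo, nest_mask) \
                <= params.target_es_ratio \
                <= _ratio_for_thickness(m, tc_roi, hi, nest_mask):
            raise PackingError("target E/S ratio out of reachable range")
        for _ in range(60):  # bisection on the rasterized ratio (monotone in t)
            mid = 0.5 * (lo + hi)
            if _ratio_for_thickness(m, tc_roi, mid, nest_mask) \
                    < params.target_es_ratio:
                lo = mid
            else:
                hi = mid
        thickness = 0.5 * (lo + hi)
    thickness = min(thickness, min(c["r"] for c in crypts) - 4.0)

    labels = np.full((rows, cols), STROMA, dtype=np.int64)
    labels[(m <= 0) & (m > -thickness)] = EPITHELIUM
    labels[m <= -thickness] = LUMEN
    labels[nest_mask] = EPITHELIUM
    labels[:, glass_x:] = LUMEN        # bare glass beyond the tissue edge

    # thin stroma bands: corridor between the designated crypt pairs
    bands = []
    yy, xx = np.mgrid[0:rows, 0:cols]
    for i, j in thin_pairs:
        ci, cj = crypts[i], crypts[j]
        di = np.hypot(yy - ci["cy"], xx - ci["cx"]) - ci["r"]
        dj = np.hypot(yy - cj["cy"], xx - cj["cx"]) - cj["r"]
        corridor = (di > 0) & (dj > 0) & (di <= params.min_stroma_band) \
            & (dj <= params.min_stroma_band)
        bands.append({"mask": corridor, "axis": 0,
                      "crypts": (i, j), "width": params.min_stroma_band})

    # tumor buds in the strip; cell count optionally solved for E/S target
    cell_area = len(_disk_offsets(params.bud_cell_radius)[0])
    if params.target_es_ratio is not None and params.ratio_compartment == "IF2":
        roi_area = int(strip.sum())
        n_cells = int(round(params.target_es_ratio * roi_area
                            / (cell_area * (1.0 + params.target_es_ratio))))
        max_cells = params.bud_cells_per_cluster[1]
        n_clusters = math.ceil(n_cells / max_cells)
    else:
        n_clusters = params.n_bud_clusters
        n_cells = None
    bud_mask = np.zeros((rows, cols), dtype=bool)
    placed_cells = 0
    cluster_centers: list[tuple[float, float]] = []
    lo_c, hi_c = params.bud_cells_per_cluster
    r_cell = params.bud_cell_radius
    for k in range(n_clusters):
        if n_cells is not None:
            remaining = n_cells - placed_cells
            if remaining <= 0:
                break
            size = min(hi_c, remaining)
        else:
            size = int(rng.integers(lo_c, hi_c + 1))
        for _ in range(400):
            cy = float(rng.uniform(3 * r_cell, bud_h - 3 * r_cell))
            cx = float(rng.uniform(mucosa_w + 3 * r_cell, glass_x - 3 * r_cell))
            if all(np.hypot(cy - py, cx - px) > 8 * r_cell
                   for py, px in cluster_centers):
                break
        else:
            raise PackingError("could not place tumor-bud clusters")
        cluster_centers.append((cy, cx))
        cells = [(cy, cx)]
        _stamp(bud_mask, cy, cx, r_cell, True, where=strip)
        for _ in range(size - 1):
            base = cells[int(rng.integers(len(cells)))]
            ang = rng.uniform(0, 2 * math.pi)
            ny = base[0] + 1.8 * r_cell * math.sin(ang)
            nx = base[1] + 1.8 * r_cell * math.cos(ang)
            ny = min(max(ny, r_cell + 1), bud_h - r_cell - 1)
            nx = min(max(nx, mucosa_w + r_cell + 1), glass_x - r_cell - 1)
            cells.append((ny, nx))
            _stamp(bud_mask, ny, nx, r_cell, True, where=strip)
        placed_cells += size
    labels[bud_mask & (labels == STROMA)] = EPITHELIUM

    # overlapping cells undershoot the disk-area estimate: top up with
    # single cells until the geometric ratio reaches the target
    if n_cells is not None:
        def _strip_ratio() -> float:
            e = np.count_nonzero((labels == EPITHELIUM) & strip)
            s = np.count_nonzero((labels == STROMA) & strip)
            return e / s if s else math.inf

        for _ in range(200):
            if _strip_ratio() >= params.target_es_ratio:
                break
            cy = float(rng.uniform(3 * r_cell, bud_h - 3 * r_cell))
            cx = float(rng.uniform(mucosa_w + 2 * r_cell, glass_x - 2 * r_cell))
            single = np.zeros((rows, cols), dtype=bool)
            _stamp(single, cy, cx, r_cell, True, where=strip)
            labels[single & (labels == STROMA)] = EPITHELIUM

    # artifact blobs (erythrocyte-like), kept clear of epithelium
    art_lo, art_hi = params.artifact_radius
    for _ in range(params.artifact_blobs):
        r_art = float(rng.uniform(art_lo, art_hi))
        for _ in range(400):
            cy = float(rng.uniform(r_art + 2, bud_h - r_art - 2))
            cx = float(rng.uniform(mucosa_w + r_art + 2, glass_x - r_art - 2))
            dy, dx = _disk_offsets(r_art + 3)
            ys = np.clip(np.round(cy + dy).astype(int), 0, rows - 1)
            xs = np.clip(np.round(cx + dx).astype(int), 0, cols - 1)
            if not (labels[ys, xs] == EPITHELIUM).any():
                _stamp(labels, cy, cx, r_art, ARTIFACT)
                break
        else:
            raise PackingError("could not place artifact blobs")

    # nuclear holes (epithelium) and stroma nuclei: channel overlays only
    hole_mask = np.zeros((rows, cols), dtype=bool)
    epi_idx = np.flatnonzero(labels == EPITHELIUM)
    n_holes = int(round(params.nuclear_hole_rate * epi_idx.size))
    if n_holes and epi_idx.size:
        centers = rng.choice(epi_idx, size=n_holes, replace=False)
        for flat in centers:
            _stamp(hole_mask, flat // cols, flat % cols,
                   params.nuclear_hole_radius, True,
                   where=labels == EPITHELIUM)
    nuc_mask = np.zeros((rows, cols), dtype=bool)
    str_idx = np.flatnonzero(labels == STROMA)
    n_nuc = int(round(params.stroma_nucleus_rate * str_idx.size))
    if n_nuc and str_idx.size:
        centers = rng.choice(str_idx, size=n_nuc, replace=False)
        for flat in centers:
            _stamp(nuc_mask, flat // cols, flat % cols,
                   params.stroma_nucleus_radius, True,
                   where=labels == STROMA)

    # channel synthesis: class means -> overlays -> tile gain -> noise
    structure = np.full((rows, cols), "stroma", dtype=object)
    structure[labels == LUMEN] = "lumen"
    structure[labels == EPITHELIUM] = "epi"
    structure[labels == ARTIFACT] = "artifact"
    structure[hole_mask] = "hole"
    structure[nuc_mask] = "stroma_nucleus"

    g_lo, g_hi = params.gradient_range
    gr, gc = params.grid_shape
    axis = int(rng.integers(2))
    ascending = bool(rng.integers(2))
    n_steps = params.grid_shape[axis]
    frac = (np.arange(n_steps) / max(n_steps - 1, 1))
    if not ascending:
        frac = frac[::-1]
    base_gain = g_lo + (g_hi - g_lo) * frac
    gain_tiles = np.empty((gr, gc))
    for r in range(gr):
        for c in range(gc):
            g = base_gain[r if axis == 0 else c]
            g += rng.uniform(-params.gradient_jitter, params.gradient_jitter)
            gain_tiles[r, c] = min(max(g, g_lo), g_hi)
    tr, tc = params.tile_shape
    gain = np.kron(gain_tiles, np.ones((tr, tc)))

    maxval = 2 ** params.bit_depth - 1
    channels = {}
    for ch in ("DAPI", "GFP", "TxRed", "Cy5"):
        base = np.zeros((rows, cols))
        for name, means in CLASS_MEANS.items():
            base[structure == name] = means[ch]
        img = base * gain
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
        img = np.clip(np.round(img), 0, maxval)
        dtype = np.uint8 if params.bit_depth == 8 else np.uint16
        channels[ch] = TiledChannelImage.from_stitched(
            ch, img.astype(dtype), params.tile_shape, params.bit_depth,
            params.pixel_size_um)
    slide = MultiChannelSlide(channels)

    ratio_mask = tc_roi if params.ratio_compartment == "TC" else strip
    e_cnt = int(np.count_nonzero((labels == EPITHELIUM) & ratio_mask))
    s_cnt = int(np.count_nonzero((labels == STROMA) & ratio_mask))
    truth = GroundTruthMap(labels, bands,
                           es_ratio=e_cnt / s_cnt if s_cnt else math.nan)
    truth.counts = truth.tally()
    return slide, truth, rois


def band_detection_fraction(s_mask: np.ndarray, band: dict[str, Any]) -> float:
    """Fraction of a thin stroma band's length on which the stroma mask
    detects it (a band row counts as detected when at least one of its
    corridor pixels is stroma)."""
    rows = np.unique(np.nonzero(band["mask"])[0])
    hit = sum(bool((s_mask[r] & band["mask"][r]).any()) for r in rows)
    return hit / len(rows) if len(rows) else math.nan


def generate_expert_labelings(truth: GroundTruthMap, n_experts: int = 3,
                              boundary_jitter_px: float = 2.0,
                              seed: int = 0) -> list[ExpertLabeling]:
    """Emulate inter-observer variability in manual mark-up.

    Each expert is the ground truth with its class boundaries displaced
    by an expert-specific smooth random field of amplitude at most
    ``boundary_jitter_px`` (signed-distance thresholding); zero jitter
    reproduces the truth exactly.  Artifact pixels are annotated as
    stroma (experts see non-epithelial tissue there).
    """
    if n_experts < 1:
        raise ValueError("need at least one expert")
    base = truth.to_expert().labels
    rng = np.random.default_rng(seed)
    out = []
    for e in range(n_experts):
        labels = np.full(base.shape, STROMA, dtype=np.int64)
        new_masks = {}
        for lbl in (LUMEN, EPITHELIUM):
            mask = base == lbl
            if boundary_jitter_px > 0:
                sdf = distance_transform_edt(mask) - distance_transform_edt(~mask)
                fld = gaussian_filter(rng.standard_normal(mask.shape), sigma=6.0)
                peak = np.abs(fld).max()
                if peak > 0:
                    fld *= boundary_jitter_px / peak
                new_masks[lbl] = (sdf + fld) > 0
            else:
                rng.standard_normal(2)  # keep the stream aligned across jitters
                new_masks[lbl] = mask
        labels[new_masks[EPITHELIUM]] = EPITHELIUM
        labels[new_masks[LUMEN]] = LUMEN  # lumen wins where displaced sets overlap
        out.append(ExpertLabeling(labels, expert_id=f"expert{e + 1}"))
    return out
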