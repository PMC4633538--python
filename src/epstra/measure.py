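"""Compartment-scoped area measurement and E/S ratio computation.

Within each ROI compartment (NM, Mu, AM, TC, IF1, IF2) the epithelial and
stromal areas are the pixel counts of the E and S masks intersected with
the union of that compartment's rasterized polygons; lumen and
out-of-tissue pixels contribute to neither.  Areas convert to mm^2 via
``count * (pixel_size_um / 1000)**2`` and the E/S ratio is their quotient,
undefined (None, flagged) when the stromal area is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ags import SegmentationResult
from .slide_io import DEFAULT_PIXEL_SIZE_UM, RoiSet, rasterize_rois


@dataclass
class CompartmentMeasurement:
    compartment: str
    roi_ids: list[int]
    e_area_px: int
    s_area_px: int
    e_area_mm2: float
    s_area_mm2: float
    es_ratio: float | None


@dataclass
class SlideReport:
    """Per-compartment E/S measurements for one slide."""

    slide_id: str
    rows: list[CompartmentMeasurement] = field(default_factory=list)
    params_fingerprint: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "slide_id": self.slide_id, "compartment": m.compartment,
            "roi_ids": ";".join(map(str, m.roi_ids)),
            "e_area_px": m.e_area_px, "s_area_px": m.s_area_px,
            "e_area_mm2": m.e_area_mm2, "s_area_mm2": m.s_area_mm2,
            "es_ratio": np.nan if m.es_ratio is None else m.es_ratio,
        } for m in self.rows])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def ratio(self, compartment: str) -> float | None:
        for m in self.rows:
            if m.compartment == compartment:
                return m.es_ratio
        raise KeyError(compartment)


def measure_compartments(seg: SegmentationResult, rois: RoiSet,
                         pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                         slide_id: str = "slide") -> SlideReport:
    """Measure E and S areas and their ratio per ROI compartment.

    Overlapping ROIs of the same compartment union; pixels covered by
    ROIs of different compartments are counted in each (no exclusivity).
    """
    extent = seg.e_mask.shape
    masks = rasterize_rois(rois, extent)
    px_to_mm2 = (pixel_size_um / 1000.0) ** 2
    report = SlideReport(slide_id)
    for compartment in rois.compartments():
        if compartment not in masks:
            continue
        roi_mask = masks[compartment]
        e_px = int(np.count_nonzero(seg.e_mask & roi_mask))
        s_px = int(np.count_nonzero(seg.s_mask & roi_mask))
        ratio = e_px / s_px if s_px > 0 else None
        report.rows.append(CompartmentMeasurement(
            compartment=compartment,
            roi_ids=[r.id for r in rois if r.compartment == compartment],
            e_area_px=e_px, s_area_px=s_px,
            e_area_mm2=e_px * px_to_mm2, s_area_mm2=s_px * px_to_mm2,
            es_ratio=ratio))
    return report


def aggregate_reports(reports: list[SlideReport],
                      grouping: dict[str, str],
                      mode: str = "per_slide") -> pd.DataFrame:
    """Summarize E/S ratios per cohort x compartment.

    ``mode='per_slide'`` (default) averages each slide's ratio and reports
    mean +/- sample standard deviation; ``mode='pooled'`` sums areas
    across slides before dividing.  Slides missing from ``grouping`` are
    skipped with a warning; so are empty cohort/compartment cells.
    """
    if mode not in ("per_slide", "pooled"):
        raise ValueError("mode must be 'per_slide' or 'pooled'")
    frames = []
    for rep in reports:
        frame = rep.to_frame()
        if rep.slide_id not in grouping:
            import warnings
            warnings.warn(f"slide {rep.slide_id!r} has no cohort, skipped",
                          stacklevel=2)
            continue
        frame["cohort"] = grouping[rep.slide_id]
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["cohort", "compartment", "mean_es_ratio",
                                     "sd_es_ratio", "n_slides"])
    data = pd.concat(frames, ignore_index=True)
    out = []
    for (cohort, compartment), grp in data.groupby(["cohort", "compartment"],
                                                   sort=True):
        ratios = grp["es_ratio"].dropna()
        if ratios.empty:
            import warnings
            warnings.warn(f"no defined ratios for {cohort}/{compartment}",
                          stacklevel=2)
            continue
        if mode == "pooled":
            e, s = grp["e_area_px"].sum(), grp["s_area_px"].sum()
            mean = e / s if s > 0 else np.nan
            sd = np.nan
        else:
            mean = float(ratios.mean())
            sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else np.nan
        out.append({"cohort": cohort, "compartment": compartment,
                    "mean_es_ratio": mean, "sd_es_ratio": sd,
                    "n_slides": int(len(grp))})
    return pd.DataFrame(out)
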