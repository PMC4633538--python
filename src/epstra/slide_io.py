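"""Data model and I/O for tiled multichannel fluorescence slides.

A slide is acquired as a rectangular mosaic of equally sized monochrome
tiles, one image per fluorescence channel (DAPI, GFP, TxRed, Cy5).  Tiles
are addressed by (row, col) on the mosaic grid; the global pixel coordinate
of offset (i, j) inside tile (r, c) is (r*tile_rows + i, c*tile_cols + j).
Coordinates are 0-based, row-major, half-open; polygon vertices live in
continuous pixel coordinates with pixel centers at integer + 0.5.

On disk a slide is a directory of per-tile grayscale images (PNG or TIFF,
8- or 16-bit) plus a JSON manifest describing the grid shape, tile shape
and the per-channel filename pattern.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon

CHANNELS = ("DAPI", "GFP", "TxRed", "Cy5")
COMPARTMENTS = ("NM", "Mu", "AM", "TC", "IF1", "IF2")

#: Physical pixel edge length of the acquisition setup, micrometers.
DEFAULT_PIXEL_SIZE_UM = 0.323


class SlideFormatError(ValueError):
    """Raised when tiles or manifest violate the slide data model."""


@dataclass
class TiledChannelImage:
    """One fluorescence channel as a grid of equally sized tiles.

    Parameters
    ----------
    channel_name : str
        One of ``DAPI``, ``GFP``, ``TxRed``, ``Cy5``.
    tiles : ndarray
        Integer array of shape ``(grid_rows, grid_cols, tile_rows, tile_cols)``.
    bit_depth : int
        8 or 16.
    pixel_size_um : float
        Physical edge length of one pixel, micrometers.
    """

    channel_name: str
    tiles: np.ndarray
    bit_depth: int = 8
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.channel_name not in CHANNELS:
            raise SlideFormatError(f"unknown channel {self.channel_name!r}")
        if self.tiles.ndim != 4:
            raise SlideFormatError("tiles must be a 4-D (gr, gc, tr, tc) array")
        if self.bit_depth not in (8, 16):
            raise SlideFormatError("bit_depth must be 8 or 16")
        if self.pixel_size_um <= 0:
            raise SlideFormatError("pixel_size_um must be positive")
        if self.tiles.min() < 0:
            raise SlideFormatError("intensities must be non-negative")
        if self.tiles.max() > 2**self.bit_depth - 1:
            raise SlideFormatError("intensity exceeds bit depth")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.tiles.shape[:2]

    @property
    def tile_shape(self) -> tuple[int, int]:
        return self.tiles.shape[2:]

    @property
    def extent(self) -> tuple[int, int]:
        """Slide extent in pixels, (rows, cols)."""
        gr, gc, tr, tc = self.tiles.shape
        return gr * tr, gc * tc

    def stitch(self) -> np.ndarray:
        """Assemble the tile grid into one slide-extent array."""
        gr, gc, tr, tc = self.tiles.shape
        return self.tiles.transpose(0, 2, 1, 3).reshape(gr * tr, gc * tc)

    @staticmethod
    def from_stitched(
        channel_name: str,
        image: np.ndarray,
        tile_shape: tuple[int, int],
        bit_depth: int = 8,
        pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    ) -> "TiledChannelImage":
        """Cut a full-extent image back into its tile grid (inverse of stitch)."""
        rows, cols = image.shape
        tr, tc = tile_shape
        if rows % tr or cols % tc:
            raise SlideFormatError("image extent is not a multiple of tile_shape")
        tiles = image.reshape(rows // tr, tr, cols // tc, tc).transpose(0, 2, 1, 3)
        return TiledChannelImage(channel_name, np.ascontiguousarray(tiles),
                                 bit_depth, pixel_size_um)


@dataclass
class MultiChannelSlide:
    """All fluorescence channels of one slide, sharing a common tile grid."""

    channels: dict[str, TiledChannelImage]

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise SlideFormatError(f"missing channels: {missing}")
        ref = next(iter(self.channels.values()))
        for ch in self.channels.values():
            if ch.tiles.shape != ref.tiles.shape or ch.bit_depth != ref.bit_depth:
                raise SlideFormatError("channels disagree on grid/tile shape or bit depth")

    def __getitem__(self, name: str) -> TiledChannelImage:
        return self.channels[name]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).grid_shape

    @property
    def tile_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).tile_shape

    @property
    def extent(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).extent

    @property
    def pixel_size_um(self) -> float:
        return next(iter(self.channels.values())).pixel_size_um

    @property
    def bit_depth(self) -> int:
        return next(iter(self.channels.values())).bit_depth


@dataclass
class Roi:
    """A labeled polygon region in global pixel coordinates."""

    polygon: Polygon
    compartment: str
    id: int

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise SlideFormatError(f"unknown compartment {self.compartment!r}")
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if len(self.polygon.exterior.coords) - 1 < 3:
            raise SlideFormatError("polygon needs at least 3 vertices")
        if not self.polygon.is_simple:
            raise SlideFormatError("polygon must be simple (non-self-intersecting)")


@dataclass
class RoiSet:
    """Collection of compartment-labeled ROI polygons for one slide."""

    rois: list[Roi] = field(default_factory=list)

    def __iter__(self) -> Iterator[Roi]:
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def compartments(self) -> list[str]:
        seen: list[str] = []
        for roi in self.rois:
            if roi.compartment not in seen:
                seen.append(roi.compartment)
        return seen


# ---------------------------------------------------------------------------
# slide reading / writing


def write_slide(slide: MultiChannelSlide, path: str | Path) -> Path:
    """Write a slide as per-tile PNGs plus a JSON grid manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    gr, gc = slide.grid_shape
    pattern = "{channel}_r{row:02d}_c{col:02d}.png"
    dtype = np.uint8 if slide.bit_depth == 8 else np.uint16
    for name, ch in slide.channels.items():
        for r in range(gr):
            for c in range(gc):
                fname = pattern.format(channel=name, row=r, col=c)
                iio.imwrite(path / fname, ch.tiles[r, c].astype(dtype))
    manifest = {
        "grid_shape": list(slide.grid_shape),
        "tile_shape": list(slide.tile_shape),
        "bit_depth": slide.bit_depth,
        "pixel_size_um": slide.pixel_size_um,
        "channels": {name: pattern.replace("{channel}", name)
                     for name in slide.channels},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path / "manifest.json"


def read_slide(path: str | Path) -> MultiChannelSlide:
    """Read a slide from a tile directory (or its manifest file).

    The manifest is a JSON sidecar with keys ``grid_shape``, ``tile_shape``,
    ``bit_depth``, ``pixel_size_um`` and ``channels`` (channel name ->
    per-tile filename pattern with ``{row}``/``{col}`` fields).
    """
    path = Path(path)
    manifest_path = path if path.is_file() else path / "manifest.json"
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    gr, gc = manifest["grid_shape"]
    tr, tc = manifest["tile_shape"]
    bit_depth = int(manifest.get("bit_depth", 8))
    pixel_size = float(manifest.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM))
    channels: dict[str, TiledChannelImage] = {}
    for name, pattern in manifest["channels"].items():
        if name not in CHANNELS:
            raise SlideFormatError(f"unknown channel {name!r} in manifest")
        tiles = np.zeros((gr, gc, tr, tc), dtype=np.uint16)
        for r in range(gr):
            for c in range(gc):
                tile_path = root / pattern.format(row=r, col=c)
                if not tile_path.exists():
                    raise SlideFormatError(f"missing tile file {tile_path}")
                tile = np.asarray(iio.imread(tile_path))
                if tile.ndim != 2:
                    raise SlideFormatError(f"tile {tile_path} is not single-channel")
                if tile.shape != (tr, tc):
                    raise SlideFormatError(
                        f"tile {tile_path} has shape {tile.shape}, expected {(tr, tc)}")
                tiles[r, c] = tile
        channels[name] = TiledChannelImage(name, tiles, bit_depth, pixel_size)
    return MultiChannelSlide(channels)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (0/255), lossless."""
    mask = np.asarray(mask)
    iio.imwrite(Path(path), (mask.astype(bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask PNG back to a boolean array (any nonzero pixel is set)."""
    return np.asarray(iio.imread(Path(path))) > 0


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write a small-integer label image as an 8-bit PNG."""
    iio.imwrite(Path(path), np.asarray(labels, dtype=np.uint8))


def read_label_map(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)), dtype=np.int64)


# ---------------------------------------------------------------------------
# ROI polygons


def write_rois(rois: RoiSet, path: str | Path) -> None:
    """Write ROIs as a GeoJSON FeatureCollection with a `compartment` property."""
    features = []
    for roi in rois:
        features.append({
            "type": "Feature",
            "properties": {"compartment": roi.compartment, "id": roi.id},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[list(xy) for xy in roi.polygon.exterior.coords]],
            },
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=2))


def read_rois(path: str | Path) -> RoiSet:
    data = json.loads(Path(path).read_text())
    rois = []
    for feat in data["features"]:
        ring = feat["geometry"]["coordinates"][0]
        rois.append(Roi(Polygon(ring), feat["properties"]["compartment"],
                        int(feat["properties"].get("id", len(rois)))))
    return RoiSet(rois)


def rasterize_rois(rois: RoiSet, extent: tuple[int, int]) -> dict[str, np.ndarray]:
    """Rasterize ROI polygons to one boolean mask per compartment.

    A pixel (i, j) belongs to a polygon iff its center (j + 0.5, i + 0.5) —
    x = column, y = row — lies strictly inside the polygon (even-odd rule;
    for simple polygons this equals shapely interior containment).
    Overlapping ROIs of the same compartment union together; polygons are
    clipped to the slide extent implicitly by only testing in-extent centers.
    """
    rows, cols = extent
    out: dict[str, np.ndarray] = {}
    for roi in rois:
        if roi.polygon.area == 0:
            warnings.warn(f"ROI {roi.id} has zero area, contributes no pixels",
                          stacklevel=2)
            continue
        minx, miny, maxx, maxy = roi.polygon.bounds
        j0, j1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)), cols)
        i0, i1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)), rows)
        if j0 >= j1 or i0 >= i1:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        inside = contains_xy(roi.polygon, jj + 0.5, ii + 0.5)
        mask = out.setdefault(roi.compartment, np.zeros(extent, dtype=bool))
        mask[i0:i1, j0:j1] |= inside
    return out
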