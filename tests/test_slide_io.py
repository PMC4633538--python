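"""Slide/mask/ROI I-O and polygon rasterization."""

import json

import numpy as np
import pytest
from shapely.geometry import Polygon

from epstra.slide_io import (MultiChannelSlide, Roi, RoiSet, SlideFormatError,
                             TiledChannelImage, rasterize_rois, read_mask,
                             read_rois, read_slide, write_mask, write_rois,
                             write_slide)

from conftest import make_slide


def point_in_polygon(px, py, vertices):
    """Even-odd ray casting, written independently of shapely."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def test_stitch_geometry_and_round_trip():
    rng = np.random.default_rng(0)
    image = rng.integers(0, 255, size=(128, 128)).astype(np.uint8)
    ch = TiledChannelImage.from_stitched("DAPI", image, (64, 64))
    assert ch.grid_shape == (2, 2) and ch.extent == (128, 128)
    assert (ch.stitch() == image).all()
    # global coordinate of tile (r, c) offset (i, j)
    assert ch.tiles[1, 0, 3, 5] == image[64 + 3, 5]
    # unstitching a stitched slide recovers every tile bit-exactly
    again = TiledChannelImage.from_stitched("DAPI", ch.stitch(), (64, 64))
    assert (again.tiles == ch.tiles).all()


def test_slide_round_trip_and_manifest_errors(tmp_path):
    rng = np.random.default_rng(1)
    slide = make_slide({n: rng.integers(0, 255, size=(32, 32))
                        for n in ("DAPI", "GFP", "TxRed", "Cy5")},
                       tile_shape=(16, 16))
    manifest = write_slide(slide, tmp_path / "slide")
    back = read_slide(manifest)
    for name in slide.channels:
        assert (back[name].tiles == slide[name].tiles).all()

    # missing tile file -> format error
    (tmp_path / "slide" / "DAPI_r00_c00.png").unlink()
    with pytest.raises(SlideFormatError, match="missing tile"):
        read_slide(manifest)

    # unknown channel name -> format error
    data = json.loads(manifest.read_text())
    data["channels"] = {"FancyStain": "DAPI_r{row:02d}_c{col:02d}.png"}
    bad = tmp_path / "slide" / "bad_manifest.json"
    bad.write_text(json.dumps(data))
    with pytest.raises(SlideFormatError, match="unknown channel"):
        read_slide(bad)


def test_inconsistent_tile_shape_rejected(tmp_path):
    import imageio.v3 as iio
    slide = make_slide({"DAPI": np.zeros((32, 32), dtype=np.uint8)},
                       tile_shape=(16, 16))
    manifest = write_slide(slide, tmp_path / "s")
    iio.imwrite(tmp_path / "s" / "DAPI_r00_c01.png",
                np.zeros((8, 8), dtype=np.uint8))
    with pytest.raises(SlideFormatError, match="shape"):
        read_slide(manifest)


@pytest.mark.parametrize("pattern", ["checkerboard", "empty", "random"])
def test_mask_round_trip_bit_exact(tmp_path, pattern):
    if pattern == "checkerboard":
        mask = np.indices((33, 41)).sum(axis=0) % 2 == 0
    elif pattern == "empty":
        mask = np.zeros((20, 20), dtype=bool)
    else:
        mask = np.random.default_rng(5).random((64, 64)) > 0.5
    write_mask(mask, tmp_path / "m.png")
    assert (read_mask(tmp_path / "m.png") == mask).all()


def test_rasterize_square_triangle_and_additivity():
    square = Roi(Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]), "TC", 0)
    masks = rasterize_rois(RoiSet([square]), (20, 20))
    assert masks["TC"].sum() == 100

    tri_pts = [(0, 0), (0, 4), (4, 0)]
    tri = Roi(Polygon(tri_pts), "NM", 1)
    mask = rasterize_rois(RoiSet([tri]), (10, 10))["NM"]
    expected = sum(point_in_polygon(j + 0.5, i + 0.5, tri_pts)
                   for i in range(10) for j in range(10))
    assert mask.sum() == expected

    # two disjoint squares of the same compartment: areas add
    s2 = Roi(Polygon([(12, 12), (16, 12), (16, 16), (12, 16)]), "TC", 2)
    both = rasterize_rois(RoiSet([square, s2]), (20, 20))
    assert both["TC"].sum() == 100 + 16


def test_rasterization_invariant_to_vertex_reversal():
    pts = [(1.3, 2.2), (9.7, 1.1), (8.2, 9.5), (2.5, 7.7)]
    fwd = rasterize_rois(RoiSet([Roi(Polygon(pts), "Mu", 0)]), (12, 12))["Mu"]
    rev = rasterize_rois(RoiSet([Roi(Polygon(pts[::-1]), "Mu", 0)]), (12, 12))["Mu"]
    assert (fwd == rev).all()


def test_degenerate_polygon_warns_and_contributes_nothing():
    degenerate = Roi(Polygon([(1, 1), (1, 1), (1, 1)]), "TC", 0)
    with pytest.warns(UserWarning, match="zero area"):
        masks = rasterize_rois(RoiSet([degenerate]), (8, 8))
    assert "TC" not in masks or masks["TC"].sum() == 0


def test_roi_geojson_round_trip(tmp_path):
    rois = RoiSet([Roi(Polygon([(0, 0), (5, 0), (5, 5), (0, 5)]), "IF2", 7)])
    write_rois(rois, tmp_path / "rois.geojson")
    back = read_rois(tmp_path / "rois.geojson")
    assert back.rois[0].compartment == "IF2" and back.rois[0].id == 7
    assert back.rois[0].polygon.equals(rois.rois[0].polygon)


def test_domain_type_invariants():
    with pytest.raises(SlideFormatError):
        TiledChannelImage("Nope", np.zeros((1, 1, 4, 4), dtype=np.uint8))
    with pytest.raises(SlideFormatError):
        TiledChannelImage("DAPI", np.zeros((1, 1, 4, 4), dtype=np.uint8),
                          pixel_size_um=0.0)
    with pytest.raises(SlideFormatError, match="missing channels"):
        MultiChannelSlide({"DAPI": TiledChannelImage(
            "DAPI", np.zeros((1, 1, 4, 4), dtype=np.uint8))})
    with pytest.raises(SlideFormatError):
        Roi(Polygon([(0, 0), (4, 4), (4, 0), (0, 4)]), "TC", 0)  # bow-tie
    with pytest.raises(SlideFormatError):
        Roi(Polygon([(0, 0), (4, 0), (4, 4), (0, 4)]), "XX", 0)
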