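"""AGS thresholding, guard/fallback logic, and AGSm smoothing."""

import math

import numpy as np
import pytest

from epstra.ags import AgsParams, ags, agsm_smooth


def two_class_tile(rng, lo, hi, shape=(32, 32), frac_hi=0.5):
    vals = np.where(rng.random(shape) < frac_hi, float(hi), float(lo))
    return vals + rng.normal(0, 1.0, shape)


def test_identical_tiles_all_accepted_and_match_global():
    rng = np.random.default_rng(0)
    tile = two_class_tile(rng, 100, 1000)
    vc = np.tile(tile, (2, 2))
    res = ags(vc, (32, 32), AgsParams())
    assert all(d.accepted for d in res.decisions)
    assert all(d.raw_otsu == pytest.approx(res.t_ref) for d in res.decisions)
    # identical to plain global thresholding
    assert ((vc > res.t_ref) == res.high_mask).all()


def test_guard_property_on_accepted_tiles():
    rng = np.random.default_rng(1)
    tiles = [[two_class_tile(rng, 100 * g, 1000 * g) for g in (0.8, 1.0)],
             [two_class_tile(rng, 100 * g, 1000 * g) for g in (1.2, 1.0)]]
    vc = np.block(tiles)
    params = AgsParams(alpha_frac=0.4)
    res = ags(vc, (32, 32), params)
    p = params.resolve(res.t_ref)
    for d in res.decisions:
        if d.accepted:
            assert res.t_ref - p.alpha <= d.final_threshold <= res.t_ref + p.alpha
            assert d.final_threshold == d.raw_otsu


def test_fallback_on_rejected_dark_tile():
    """A tile whose raw Otsu falls below the guard re-thresholds on the
    clipped population; the final threshold lies inside [t_min, t_max]."""
    rng = np.random.default_rng(2)
    bright = two_class_tile(rng, 100, 1000)
    dark = two_class_tile(rng, 50, 500)       # raw Otsu ~ 275, below guard
    vc = np.block([[bright, dark]])
    params = AgsParams(alpha=100.0, t_min=40.0, t_max=800.0)
    res = ags(vc, (32, 32), params)
    d_dark = res.decisions[1]
    assert not d_dark.accepted and d_dark.fallback_used
    assert params.t_min <= d_dark.final_threshold <= params.t_max
    # and it separates the dark tile's classes
    assert 60 < d_dark.final_threshold < 490


def test_fallback_clamped_into_guard_when_requested():
    rng = np.random.default_rng(3)
    bright = two_class_tile(rng, 100, 1000)
    dark = two_class_tile(rng, 50, 500)
    vc = np.block([[bright, dark]])
    params = AgsParams(alpha=100.0, t_min=40.0, t_max=800.0, clamp_fallback=True)
    res = ags(vc, (32, 32), params)
    d_dark = res.decisions[1]
    assert d_dark.fallback_used
    assert res.t_ref - 100 <= d_dark.final_threshold <= res.t_ref + 100


def test_single_class_tile_degenerate_fallback_avoids_spurious_split():
    """The known LT failure mode: a single-class tile gets split by
    unconstrained Otsu, while the AGS fallback (no clipped pixels ->
    reference) keeps it whole."""
    rng = np.random.default_rng(4)
    mixed = two_class_tile(rng, 400, 1000)
    dark_only = 150.0 + rng.normal(0, 10, (32, 32))   # single dark class
    vc = np.block([[mixed, dark_only]])
    guarded = AgsParams(alpha=150.0, t_min=500.0, t_max=2000.0)
    res = ags(vc, (32, 32), guarded)
    assert res.t_ref - 150 > 200        # precondition: guard rejects ~150 cuts
    d = res.decisions[1]
    assert not d.accepted and d.degenerate
    # the whole single-class tile lands in the low class (stroma recall 1)
    assert res.low_mask[:, 32:].all()
    # whereas with an infinite guard (the LT behavior) it is split
    lt = ags(vc, (32, 32), AgsParams(alpha=math.inf))
    assert lt.high_mask[:, 32:].any() and lt.low_mask[:, 32:].any()


def test_restriction_domain_semantics():
    rng = np.random.default_rng(5)
    vc = np.block([[two_class_tile(rng, 100, 1000),
                    two_class_tile(rng, 100, 1000)]])
    restrict = np.zeros_like(vc, dtype=bool)
    restrict[:, :32] = True
    res = ags(vc, (32, 32), AgsParams(), restrict_to=restrict)
    assert not res.low_mask[:, 32:].any() and not res.high_mask[:, 32:].any()
    assert ((res.low_mask | res.high_mask) == restrict).all()
    assert not (res.low_mask & res.high_mask).any()
    assert res.decisions[1].skipped


def test_degenerate_whole_slide_is_all_low():
    vc = np.zeros((64, 64))
    res = ags(vc, (32, 32), AgsParams())
    assert res.low_mask.all() and not res.high_mask.any()
    assert math.isnan(res.t_ref)


def test_clip_reference_moves_t_ref_into_corridor():
    rng = np.random.default_rng(6)
    # three intensity classes: background 0, mid 500, bright broad 5000-20000
    vals = np.concatenate([np.zeros(3000), np.full(3000, 500.0),
                           rng.uniform(5000, 20000, 3000)])
    vc = rng.permutation(vals).reshape(75, 120)
    plain = ags(vc, (75, 120), AgsParams())
    clipped = ags(vc, (75, 120), AgsParams(t_min=0.0, t_max=2000.0,
                                           clip_reference=True))
    assert plain.t_ref > 2000.0          # lands inside the broad bright class
    assert 0 < clipped.t_ref <= 2000.0   # corridor keeps it at the class gap
    with pytest.raises(ValueError):
        AgsParams(clip_reference=True)   # needs absolute bounds


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        AgsParams(alpha=-1.0)
    with pytest.raises(ValueError):
        AgsParams(t_min=10.0, t_max=10.0)
    with pytest.raises(ValueError):
        AgsParams(smoothing_radius=6)


# ---------------------------------------------------------------------------
# AGSm smoothing


def test_smoothing_fills_holes_and_removes_specks():
    mask = np.zeros((40, 40), dtype=bool)
    mask[8:32, 8:32] = True
    mask[19, 19] = False                   # 1-px hole
    mask[2, 2] = True                      # isolated speck
    out = agsm_smooth(mask, radius=1)
    assert out[19, 19]
    assert not out[2, 2]


def test_smoothing_preserves_large_rectangle_interior():
    mask = np.zeros((60, 60), dtype=bool)
    mask[10:50, 10:50] = True              # side 40 >= 3 * radius
    out = agsm_smooth(mask, radius=3)
    # interior untouched; any change confined to within radius of the border
    assert (out[13:47, 13:47] == mask[13:47, 13:47]).all()
    changed = np.argwhere(out != mask)
    if changed.size:
        from scipy.ndimage import distance_transform_edt
        border_dist = distance_transform_edt(mask) + distance_transform_edt(~mask)
        assert border_dist[out != mask].max() <= 3 + 1


def test_smoothing_matches_reference_morphology():
    from scipy import ndimage
    from skimage.morphology import disk
    rng = np.random.default_rng(8)
    mask = np.zeros((64, 64), dtype=bool)
    mask[12:52, 12:52] = rng.random((40, 40)) > 0.4   # 12-px empty border
    se = disk(2)
    expected = ndimage.binary_opening(
        ndimage.binary_closing(mask, structure=se), structure=se)
    assert (agsm_smooth(mask, 2) == expected).all()


def test_smoothing_idempotent_and_radius_bounds():
    rng = np.random.default_rng(9)
    mask = rng.random((50, 50)) > 0.45
    once = agsm_smooth(mask, 2)
    assert (agsm_smooth(once, 2) == once).all()
    assert (agsm_smooth(mask, 0) == mask).all()
    with pytest.raises(ValueError):
        agsm_smooth(mask, 6)
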