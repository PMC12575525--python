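"""Prompt derivation and overlay: containment, minimality, exact footprints."""

import itertools

import numpy as np
import pytest

from dzseg.errors import DerivationError
from dzseg.prompts import (PromptGeometry, PromptStyle, derive_bbox,
                           derive_point, derive_scribble, overlay,
                           prompt_footprint)
from dzseg.synthetic import SceneSpec, generate_scene


def _style_1to1(image_side: int = 8, **kw):
    """Style whose pixel sizes apply unscaled to a given image side."""
    return PromptStyle(reference_size=image_side, **kw)


# -- points -----------------------------------------------------------------

def test_point_on_singleton_zone_is_forced():
    mask = np.zeros((8, 8), np.uint8)
    mask[3, 5] = 1
    assert derive_point(mask, seed=0).point == (3, 5)


def test_point_membership_and_determinism():
    mask = np.zeros((6, 6), np.uint8)
    mask[1, 1] = mask[2, 2] = 1
    for seed in range(50):
        p = derive_point(mask, seed)
        assert p.point in {(1, 1), (2, 2)}
        assert derive_point(mask, seed).point == p.point


def test_point_is_uniform_over_two_pixel_zone():
    mask = np.zeros((4, 4), np.uint8)
    mask[0, 0] = mask[3, 3] = 1
    hits = sum(derive_point(mask, seed).point == (0, 0) for seed in range(10_000))
    assert abs(hits / 10_000 - 0.5) <= 0.02


def test_point_requires_nonempty_zone():
    with pytest.raises(DerivationError):
        derive_point(np.zeros((4, 4), np.uint8), seed=0)


# -- bounding boxes ----------------------------------------------------------

def test_bbox_matches_brute_force_min_max():
    mask = np.zeros((8, 8), np.uint8)
    mask[2:5, 1:7] = 1
    assert derive_bbox(mask).rect == (2, 1, 4, 6)


def test_bbox_full_extent_and_degenerate():
    assert derive_bbox(np.ones((5, 7), np.uint8)).rect == (0, 0, 4, 6)
    single = np.zeros((8, 8), np.uint8)
    single[3, 5] = 1
    assert derive_bbox(single).rect == (3, 5, 3, 5)


def test_bbox_containment_and_minimality_exhaustive_4x4():
    """Every mask on a 4x4 grid with <= 3 foreground pixels."""
    cells = list(itertools.product(range(4), repeat=2))
    for k in (1, 2, 3):
        for combo in itertools.combinations(cells, k):
            mask = np.zeros((4, 4), np.uint8)
            for r, c in combo:
                mask[r, c] = 1
            r0, c0, r1, c1 = derive_bbox(mask).rect
            # containment
            assert all(r0 <= r <= r1 and c0 <= c <= c1 for r, c in combo)
            # minimality: each side touches at least one zone pixel
            assert any(r == r0 for r, _ in combo)
            assert any(r == r1 for r, _ in combo)
            assert any(c == c0 for _, c in combo)
            assert any(c == c1 for _, c in combo)


# -- scribbles ---------------------------------------------------------------

def test_long_scribble_spans_a_thin_strip():
    mask = np.zeros((5, 10), np.uint8)
    mask[2, :] = 1  # 1-px strip: its skeleton is the strip itself
    poly = derive_scribble(mask, "long_scribble", seed=0).polyline
    assert all(r == 2 for r, _ in poly)
    assert len({c for _, c in poly}) >= 8


def test_short_scribble_is_central_subpath_of_long():
    mask = np.zeros((5, 10), np.uint8)
    mask[2, :] = 1
    long = derive_scribble(mask, "long_scribble", seed=0).polyline
    short = derive_scribble(mask, "short_scribble", seed=0).polyline
    assert set(short) < set(long)


def test_scribble_vertices_stay_inside_zone(disk_mask):
    for kind in ("long_scribble", "short_scribble"):
        poly = derive_scribble(disk_mask, kind, seed=1).polyline
        assert all(disk_mask[r, c] == 1 for r, c in poly)


def test_scribble_containment_on_synthetic_blobs():
    for seed in range(20):
        mask = generate_scene(SceneSpec(seed=seed)).mask
        poly = derive_scribble(mask, "long_scribble", seed=seed).polyline
        assert all(mask[r, c] == 1 for r, c in poly)


def test_scribble_needs_skeletonizable_zone():
    mask = np.zeros((6, 6), np.uint8)
    mask[2, 2] = 1  # skeleton is a single pixel: no trajectory
    with pytest.raises(DerivationError):
        derive_scribble(mask, "long_scribble", seed=0)


def test_jittered_scribble_snaps_back_into_zone(disk_mask):
    poly = derive_scribble(disk_mask, "long_scribble", seed=3, jitter=2.0).polyline
    assert all(disk_mask[r, c] == 1 for r, c in poly)


# -- overlay -----------------------------------------------------------------

def test_overlay_none_is_identity():
    img = np.arange(8 * 8 * 3, dtype=np.uint8).reshape(8, 8, 3)
    out = overlay(img, PromptGeometry(kind="none"))
    assert np.array_equal(out, img)


def test_point_footprint_is_euclidean_disk():
    img = np.zeros((8, 8, 3), np.uint8)
    style = _style_1to1(point_radius=1, color_per_kind={"point": (0, 255, 0)})
    out = overlay(img, PromptGeometry(kind="point", point=(3, 3)), style)
    expected = {(r, c) for r in range(8) for c in range(8)
                if np.hypot(r - 3, c - 3) <= 1}
    assert expected == {(3, 3), (2, 3), (4, 3), (3, 2), (3, 4)}
    green = {tuple(p) for p in np.argwhere((out == (0, 255, 0)).all(axis=2))}
    assert green == expected


def test_bbox_outline_equals_perimeter_enumeration():
    img = np.zeros((8, 8, 3), np.uint8)
    rect = (2, 1, 4, 6)
    style = _style_1to1(stroke_thickness=1)
    out = overlay(img, PromptGeometry(kind="bbox", rect=rect), style)
    r0, c0, r1, c1 = rect
    perimeter = {(r, c) for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)
                 if r in (r0, r1) or c in (c0, c1)}
    red = {tuple(p) for p in np.argwhere((out == (255, 0, 0)).all(axis=2))}
    assert red == perimeter


@pytest.mark.parametrize("kind", ["point", "long_scribble", "bbox"])
def test_overlay_changes_only_the_footprint(kind, disk_mask):
    rng = np.random.default_rng(0)
    img = rng.integers(0, 255, size=(32, 32, 3), dtype=np.uint8)
    if kind == "point":
        prompt = derive_point(disk_mask, seed=2)
    elif kind == "bbox":
        from dzseg.prompts import derive_bbox
        prompt = derive_bbox(disk_mask)
    else:
        prompt = derive_scribble(disk_mask, kind, seed=2)
    style = PromptStyle()
    out = overlay(img, prompt, style)
    foot = prompt_footprint(img.shape[:2], prompt, style)
    assert np.array_equal(out[~foot], img[~foot])
    assert (out[foot] == style.color_per_kind[kind]).all()


def test_out_of_bounds_geometry_rejected():
    img = np.zeros((8, 8, 3), np.uint8)
    with pytest.raises(ValueError):
        overlay(img, PromptGeometry(kind="point", point=(9, 3)), _style_1to1())


def test_geometry_field_population_enforced():
    with pytest.raises(ValueError):
        PromptGeometry(kind="point")                      # missing field
    with pytest.raises(ValueError):
        PromptGeometry(kind="point", point=(1, 1), rect=(0, 0, 1, 1))
    with pytest.raises(ValueError):
        PromptGeometry(kind="bbox", rect=(3, 3, 1, 1))    # inverted bounds


def test_geometry_json_round_trip(disk_mask):
    for prompt in (derive_point(disk_mask, 0), derive_bbox(disk_mask),
                   derive_scribble(disk_mask, "short_scribble", 0),
                   PromptGeometry(kind="none")):
        again = PromptGeometry.from_dict(prompt.to_dict())
        assert again.to_dict() == prompt.to_dict()
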