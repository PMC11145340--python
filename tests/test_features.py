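"""Morphometric features against brute-force oracles and closed forms."""

import numpy as np
import pytest

from nucmil.features import (
    FEATURE_NAMES,
    DegenerateGLCMError,
    EmptyRegionError,
    NucleusRegion,
    boundary_counts,
    compute_glcm,
    compute_moments,
    featurize_nucleus,
    geometric_features,
    hull_area,
    texture_features,
)
from nucmil.synthetic import ClassParams, default_class_params, sample_nucleus_regions

from conftest import random_blob_mask


def brute_moments(mask):
    """Double-loop moment oracle; x = column, y = row."""
    m = {k: 0.0 for k in [(0, 0), (1, 0), (0, 1), (1, 1), (2, 0), (0, 2)]}
    for yy in range(mask.shape[0]):
        for xx in range(mask.shape[1]):
            if mask[yy, xx]:
                for (p, q) in m:
                    m[(p, q)] += xx**p * yy**q
    return m


def disk_mask(r, pad=2):
    n = 2 * (r + pad) + 1
    yy, xx = np.indices((n, n)) - (r + pad)
    return xx * xx + yy * yy <= r * r


# ---------------------------------------------------------------- moments

def test_moments_of_uniform_square_are_symmetric():
    mom = compute_moments(np.ones((3, 3), dtype=bool))
    assert mom.raw[(0, 0)] == 9
    assert mom.xbar == 1 and mom.ybar == 1
    assert mom.mu11 == pytest.approx(0.0)


def test_moments_match_brute_force_oracle(rng):
    for _ in range(100):
        mask = random_blob_mask(rng, size=int(rng.integers(5, 33)))
        if not mask.any():
            continue
        mom = compute_moments(mask)
        oracle = brute_moments(mask)
        for key, val in oracle.items():
            assert mom.raw[key] == val  # exact integer sums


def test_single_pixel_has_zero_normalized_moments():
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 3] = True
    mom = compute_moments(mask)
    assert mom.mu20 == 0 and mom.mu02 == 0 and mom.mu11 == 0


def test_empty_mask_raises():
    with pytest.raises(EmptyRegionError):
        compute_moments(np.zeros((4, 4), dtype=bool))


# --------------------------------------------------------------- geometry

def test_axis_aligned_rectangle_geometry():
    mask = np.zeros((20, 40), dtype=bool)
    mask[5:15, 5:35]  # noqa: B018 - shape note: 10 rows x 30 cols
    mask[5:15, 5:35] = True
    geo = geometric_features(mask)
    assert geo.area == 300
    assert geo.theta == pytest.approx(0.0, abs=1e-12)
    assert geo.major / geo.minor == pytest.approx(3.0, rel=0.05)


def test_digital_disk_is_round():
    geo = geometric_features(disk_mask(15))
    assert geo.ecc < 0.1
    assert geo.ell > 0.95
    assert geo.dia == pytest.approx(30.0, rel=0.02)


def test_equivalent_diameter_closed_form():
    mask = np.zeros((12, 12), dtype=bool)
    mask[1:11, 1:11] = True  # area 100
    geo = geometric_features(mask)
    assert geo.dia == pytest.approx(11.2838, abs=1e-3)


def test_ecc_ell_identity_on_random_regions(rng):
    for _ in range(30):
        mask = random_blob_mask(rng, size=20)
        geo = geometric_features(mask)
        assert geo.ecc == pytest.approx(np.sqrt(1.0 - geo.ell**2), abs=1e-12)


def test_rotating_90_degrees_swaps_directional_counts():
    regions, _ = sample_nucleus_regions(
        ClassParams(aspect_mean=2.0, aspect_sd=0.0), 1, np.random.default_rng(5)
    )
    mask = regions[0].binary_mask
    geo = geometric_features(mask)
    rot = geometric_features(np.rot90(mask))
    assert (geo.nv, geo.nh) == (rot.nh, rot.nv)
    assert (geo.nd1, geo.nd2) == (rot.nd2, rot.nd1)
    # the half-angle arctan estimate has period pi/2, so the folded
    # orientation is numerically unchanged under a quarter turn
    assert rot.theta == pytest.approx(geo.theta, abs=1e-9)


def test_dilating_a_disk_grows_all_size_features():
    feats = [geometric_features(disk_mask(r)) for r in (6, 9, 12)]
    for small, big in zip(feats, feats[1:]):
        assert big.area > small.area
        assert big.dia > small.dia
        assert big.per > small.per
        assert big.area_hull > small.area_hull


def test_ellipse_axes_recover_generator_truth():
    params = ClassParams(aspect_mean=1.8, aspect_sd=0.0, noise_sigma=0.0)
    regions, truth = sample_nucleus_regions(params, 20, np.random.default_rng(9))
    ratios_major = [
        geometric_features(r.binary_mask).major / (2 * t["a"])
        for r, t in zip(regions, truth)
    ]
    ratios_minor = [
        geometric_features(r.binary_mask).minor / (2 * t["b"])
        for r, t in zip(regions, truth)
    ]
    assert abs(np.mean(ratios_major) - 1.0) < 0.05
    assert abs(np.mean(ratios_minor) - 1.0) < 0.05


# ------------------------------------------------------------------- hull

def test_hull_of_four_corner_pixels_by_shoelace():
    mask = np.zeros((11, 11), dtype=bool)
    mask[[0, 0, 10, 10], [0, 10, 0, 10]] = True
    area, perim, poly = hull_area(mask)
    assert area == pytest.approx(100.0)
    assert perim == pytest.approx(40.0)


def test_hull_area_close_to_area_for_convex_shape():
    mask = disk_mask(15)
    area, _, _ = hull_area(mask)
    assert abs(area - mask.sum()) / mask.sum() < 0.03


def test_hull_area_exceeds_area_for_concave_shape():
    mask = np.zeros((20, 20), dtype=bool)
    mask[2:18, 2:6] = True
    mask[2:6, 2:18] = True
    mask[14:18, 2:18] = True  # C shape
    area, _, _ = hull_area(mask)
    assert area > mask.sum()


# --------------------------------------------------------- boundary counts

def brute_boundary_counts(mask):
    fg = np.argwhere(mask)
    fgset = {tuple(p) for p in fg}
    contour = set()
    for (y, x) in fgset:
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (y + dy, x + dx) not in fgset:
                contour.add((y, x))
                break
    counts = {"nh": 0, "nv": 0, "nd1": 0, "nd2": 0}
    for (y, x) in contour:
        if (y, x + 1) in contour:
            counts["nh"] += 1
        if (y + 1, x) in contour:
            counts["nv"] += 1
        if (y - 1, x + 1) in contour:
            counts["nd1"] += 1
        if (y + 1, x + 1) in contour:
            counts["nd2"] += 1
    return counts


def test_horizontal_line_boundary_counts():
    mask = np.zeros((3, 7), dtype=bool)
    mask[1, 1:6] = True
    nv, nh, nd1, nd2, per, ph = boundary_counts(mask)
    assert (nv, nh, nd1, nd2) == (0, 4, 0, 0)
    assert per == 4.0 and ph == per


def test_single_pixel_boundary_counts_are_zero():
    mask = np.zeros((3, 3), dtype=bool)
    mask[1, 1] = True
    assert boundary_counts(mask)[:5] == (0, 0, 0, 0, 0.0)


@pytest.mark.parametrize("shape", ["square", "blob"])
def test_boundary_counts_match_enumeration_oracle(shape, rng):
    if shape == "square":
        mask = np.zeros((12, 12), dtype=bool)
        mask[1:11, 1:11] = True
        masks = [mask]
    else:
        masks = [random_blob_mask(rng, 16) for _ in range(25)]
    for mask in masks:
        if not mask.any():
            continue
        nv, nh, nd1, nd2, per, _ = boundary_counts(mask)
        oracle = brute_boundary_counts(mask)
        assert (nv, nh, nd1, nd2) == (
            oracle["nv"], oracle["nh"], oracle["nd1"], oracle["nd2"]
        )
        assert per == oracle["nv"] + oracle["nh"] + 2 * (oracle["nd1"] + oracle["nd2"])


def test_diagonal_weight_switch():
    mask = disk_mask(6)
    *_, per2, _ = boundary_counts(mask, diagonal_weight=2.0)
    *_, per_s, _ = boundary_counts(mask, diagonal_weight=np.sqrt(2.0))
    assert per_s < per2


# ------------------------------------------------------------------- GLCM

def region_from_patch(patch, mask=None, levels=8):
    patch = np.asarray(patch)
    mask = np.ones_like(patch, dtype=bool) if mask is None else mask
    return NucleusRegion(binary_mask=mask, gray_patch=patch, gray_levels=levels)


def brute_glcm(patch, mask, levels, dx, dy):
    g = np.zeros((levels, levels))
    h, w = patch.shape
    for y in range(h):
        for x in range(w):
            x2, y2 = x + dx, y + dy
            if 0 <= x2 < w and 0 <= y2 < h and mask[y, x] and mask[y2, x2]:
                g[patch[y, x], patch[y2, x2]] += 1
    return g


def test_constant_patch_glcm_single_cell():
    region = region_from_patch(np.full((4, 4), 5))
    counts, p = compute_glcm(region, (1, 0))
    assert counts[5, 5] == 12 and counts.sum() == 12
    assert (p**2).sum() == pytest.approx(1.0)  # ASM of the normalized matrix


def test_checkerboard_entropy_one_bit():
    patch = np.indices((4, 4)).sum(axis=0) % 2
    region = region_from_patch(patch, levels=2)
    _, p = compute_glcm(region, (1, 0))
    assert p[0, 1] == pytest.approx(0.5) and p[1, 0] == pytest.approx(0.5)
    nz = p[p > 0]
    assert -(nz * np.log2(nz)).sum() == pytest.approx(1.0)


def test_glcm_mass_equals_pair_enumeration(rng):
    for _ in range(100):
        size = int(rng.integers(3, 12))
        patch = rng.integers(0, 8, size=(size, size))
        mask = rng.random((size, size)) < 0.7
        if not mask.any():
            continue
        region_ok = True
        for (dx, dy) in ((1, 0), (1, 1), (0, 1), (-1, 1)):
            oracle = brute_glcm(patch, mask, 8, dx, dy)
            try:
                counts, p = compute_glcm(region_from_patch(patch, mask), (dx, dy))
            except DegenerateGLCMError:
                assert oracle.sum() == 0
                region_ok = False
                continue
            assert np.array_equal(counts, oracle)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
        del region_ok


def test_single_pixel_glcm_degenerate():
    mask = np.zeros((3, 3), dtype=bool)
    mask[1, 1] = True
    with pytest.raises(DegenerateGLCMError):
        compute_glcm(region_from_patch(np.zeros((3, 3), dtype=int), mask), (1, 0))


# ---------------------------------------------------------------- texture

def test_constant_patch_texture_closed_forms():
    region = region_from_patch(np.full((6, 6), 2))
    tex = texture_features(region)
    assert tex.con == 0 and tex.diss == 0
    assert tex.hom == pytest.approx(1.0)
    assert tex.ent == pytest.approx(0.0)
    assert tex.asm == pytest.approx(1.0)


def test_uniform_glcm_has_zero_dispersion():
    from nucmil.features import _glcm_stats

    p = np.full((8, 8), 1.0 / 64.0)
    assert _glcm_stats(p)["dsip"] == pytest.approx(0.0, abs=1e-15)


def test_noisy_nuclei_are_entropic_and_inhomogeneous():
    params = default_class_params()
    rng0, rng1 = np.random.default_rng(11), np.random.default_rng(11)
    smooth, _ = sample_nucleus_regions(params[0], 120, rng0)
    noisy, _ = sample_nucleus_regions(params[1], 120, rng1)
    stats = {}
    for name, regions in (("smooth", smooth), ("noisy", noisy)):
        vecs = np.array([featurize_nucleus(r) for r in regions])
        stats[name] = dict(zip(FEATURE_NAMES, vecs.mean(axis=0)))
    assert stats["noisy"]["ent"] / stats["smooth"]["ent"] > 1.0
    assert stats["noisy"]["hom"] / stats["smooth"]["hom"] < 1.0
    assert stats["noisy"]["asm"] / stats["smooth"]["asm"] < 1.0
    assert stats["noisy"]["area"] / stats["smooth"]["area"] > 1.0


def test_featurize_returns_16_finite_values(positive_slide):
    from nucmil.features import regions_from_mask

    tile = positive_slide.tiles[0]
    regions = regions_from_mask(tile.image, tile.instance_mask)
    assert regions, "fixture tile should contain nuclei"
    vec = featurize_nucleus(regions[0])
    assert vec.shape == (16,)
    assert np.all(np.isfinite(vec))
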