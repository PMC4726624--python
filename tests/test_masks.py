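import dataclasses

import numpy as np
import pytest

from shgquant.image import MosaicImage
from shgquant.masks import (MaskPipelineConfig, NoTissueError,
                            analyze_particles, detect_excluded_regions,
                            detect_sample_area, fraction_threshold,
                            max_filter, mean_filter, overlay_channels,
                            percentile_autothreshold, segment)
from shgquant.phantom import generate_phantom

# --- independent brute-force oracles -------------------------------------


def brute_disc(radius):
    r = int(radius)
    return [(dr, dc) for dr in range(-r, r + 1) for dc in range(-r, r + 1)
            if dr * dr + dc * dc <= r * r]


def brute_rank_filter(raster, radius, op):
    h, w = raster.shape
    offsets = brute_disc(radius)
    out = np.empty((h, w), dtype=np.float64)
    for i in range(h):
        for j in range(w):
            vals = [raster[min(max(i + dr, 0), h - 1),
                           min(max(j + dc, 0), w - 1)]
                    for dr, dc in offsets]
            out[i, j] = op(vals)
    return out


def brute_percentile(raster, p=0.5):
    flat = np.asarray(raster).ravel()
    best_t, best_score = None, np.inf
    for t in np.unique(flat):
        score = abs(int((flat <= t).sum()) - p * flat.size)
        if score < best_score:
            best_t, best_score = t, score
    return float(best_t)


def brute_label(mask, connectivity=8):
    """Flood-fill connected components, independent of skimage."""
    h, w = mask.shape
    if connectivity == 8:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1),
                 (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                stack = [(i, j)]
                labels[i, j] = current
                while stack:
                    y, x = stack.pop()
                    for dy, dx in neigh:
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                                and labels[ny, nx] == 0):
                            labels[ny, nx] = current
                            stack.append((ny, nx))
    return labels, current


def brute_roundness(coords):
    """4*area/(pi*major^2) from the eigen-decomposition of the coordinate
    covariance (equivalent-ellipse convention)."""
    pts = np.asarray(coords, dtype=np.float64)
    n = len(pts)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / n
    lam = np.linalg.eigvalsh(cov)[-1]
    major = 4.0 * np.sqrt(lam)
    if major <= 0:
        return 1.0
    return min(1.0, 4.0 * n / (np.pi * major**2))


# --- overlay ---------------------------------------------------------------


def test_overlay_examples():
    a = np.array([[1, 5], [0, 2]], np.uint8)
    b = np.array([[3, 0], [4, 2]], np.uint8)
    img = MosaicImage(shg=a, cars=b, pixel_size_um=1.0, bit_depth=8)
    np.testing.assert_array_equal(overlay_channels(img),
                                  [[3, 5], [4, 2]])
    same = MosaicImage(shg=a, cars=a, pixel_size_um=1.0, bit_depth=8)
    np.testing.assert_array_equal(overlay_channels(same), a)
    zero = MosaicImage(shg=np.zeros_like(b), cars=b, pixel_size_um=1.0,
                       bit_depth=8)
    np.testing.assert_array_equal(overlay_channels(zero), b)


# --- percentile auto-threshold --------------------------------------------


def test_percentile_balanced_and_skewed():
    half = np.array([0] * 50 + [10] * 50)
    assert percentile_autothreshold(half) == 0
    skew = np.array([0] * 25 + [10] * 75)
    assert percentile_autothreshold(skew) == 0
    # constant raster thresholds to the constant => empty foreground
    const = np.full(64, 7)
    t = percentile_autothreshold(const)
    assert t == 7 and not (const > t).any()


def test_percentile_matches_bruteforce(rng):
    for _ in range(25):
        raster = rng.integers(0, 40, (rng.integers(2, 20),
                                      rng.integers(2, 20))).astype(np.uint8)
        assert percentile_autothreshold(raster) == brute_percentile(raster)


def test_percentile_foreground_rank_invariant(rng):
    raster = rng.integers(0, 50, (24, 24)).astype(np.uint8)
    fg = raster > percentile_autothreshold(raster)
    transformed = (raster.astype(np.float64) * 2.5 + 3.0) ** 1.3
    fg2 = transformed > percentile_autothreshold(transformed)
    np.testing.assert_array_equal(fg, fg2)


# --- rank filters ----------------------------------------------------------


def test_filters_preserve_constants():
    const = np.full((9, 11), 42.0)
    for r in (1, 3):
        np.testing.assert_allclose(mean_filter(const, r), const, atol=1e-9)
        np.testing.assert_array_equal(max_filter(const, r), const)


def test_max_filter_cross_kernel_example():
    raster = np.array([[0, 0], [0, 9]], np.float64)
    np.testing.assert_array_equal(max_filter(raster, 1),
                                  [[0, 9], [9, 9]])


def test_mean_filter_cross_kernel_example():
    raster = np.zeros((3, 3))
    raster[1, 1] = 9.0
    out = mean_filter(raster, 1)
    assert out[1, 1] == pytest.approx(9 / 5)  # 5-pixel cross kernel


@pytest.mark.parametrize("radius", [1, 2, 4, 5])
def test_filters_match_bruteforce(rng, radius):
    raster = rng.integers(0, 256, (17, 23)).astype(np.float64)
    got_mean = mean_filter(raster, radius)
    want_mean = brute_rank_filter(raster, radius, np.mean)
    np.testing.assert_allclose(got_mean, want_mean, rtol=1e-9, atol=1e-9)
    got_max = max_filter(raster, radius)
    want_max = brute_rank_filter(raster, radius, np.max)
    np.testing.assert_array_equal(got_max, want_max)


def test_filters_reject_nonpositive_radius():
    raster = np.zeros((4, 4))
    with pytest.raises(ValueError):
        mean_filter(raster, 0)
    with pytest.raises(ValueError):
        max_filter(raster, 0)


# --- fraction threshold ----------------------------------------------------


def test_fraction_threshold_eight_bit_levels(rng):
    raster = rng.integers(0, 256, (32, 32)).astype(np.uint8)
    # 9.8% of 255 = 24.99 -> integer pixels >= 25 are foreground
    np.testing.assert_array_equal(fraction_threshold(raster, 0.098),
                                  raster >= 25)
    # 1.17% of 255 = 2.98 -> integer pixels >= 3 are foreground
    np.testing.assert_array_equal(fraction_threshold(raster, 0.0117),
                                  raster >= 3)
    assert not fraction_threshold(np.zeros((4, 4), np.uint8), 0.5).any()
    with pytest.raises(ValueError):
        fraction_threshold(raster, 1.5)


def test_fraction_threshold_float_uses_observed_max():
    raster = np.array([0.0, 5.0, 100.0])
    np.testing.assert_array_equal(fraction_threshold(raster, 0.0499),
                                  [False, True, True])


# --- particle analysis -----------------------------------------------------


def test_disc_particle_roundness():
    yy, xx = np.mgrid[-15:16, -15:16]
    disc = (yy**2 + xx**2) <= 10**2
    parts = analyze_particles(disc, pixel_size_um=2.0)
    assert len(parts) == 1
    p = parts[0]
    assert 0.95 <= p.roundness <= 1.0
    assert p.area_um2 == pytest.approx(disc.sum() * 4.0)
    assert not p.touches_border


def test_ellipse_particle_roundness_is_axis_ratio():
    yy, xx = np.mgrid[-25:26, -25:26]
    ellipse = (xx / 20.0)**2 + (yy / 10.0)**2 <= 1.0
    (p,) = analyze_particles(ellipse, pixel_size_um=1.0)
    assert p.roundness == pytest.approx(0.5, abs=0.03)  # b/a


def test_diagonal_pixels_connectivity():
    mask = np.zeros((4, 4), bool)
    mask[1, 1] = mask[2, 2] = True
    assert len(analyze_particles(mask, 1.0, connectivity=8)) == 1
    assert len(analyze_particles(mask, 1.0, connectivity=4)) == 2


def test_particles_match_bruteforce(rng):
    for _ in range(10):
        mask = rng.random((20, 20)) > 0.7
        parts = analyze_particles(mask, pixel_size_um=1.0)
        labels, n = brute_label(mask, 8)
        assert len(parts) == n
        areas_got = sorted(p.area_um2 for p in parts)
        areas_want = sorted(np.bincount(labels.ravel())[1:].tolist())
        assert areas_got == [float(a) for a in areas_want]
        # roundness via the independent covariance formula, matched by area+centroid
        by_key = {(round(p.centroid[0], 6), round(p.centroid[1], 6)): p.roundness
                  for p in parts}
        for lab in range(1, n + 1):
            coords = np.argwhere(labels == lab)
            key = (round(coords[:, 0].mean(), 6), round(coords[:, 1].mean(), 6))
            assert by_key[key] == pytest.approx(brute_roundness(coords),
                                                rel=1e-9, abs=1e-9)


def test_empty_mask_gives_no_particles():
    assert analyze_particles(np.zeros((5, 5), bool), 1.0) == []


# --- sample-area detection -------------------------------------------------


def test_sample_mask_recovers_phantom_tissue(phantom_stage1):
    img, gt = phantom_stage1
    sample = detect_sample_area(img)
    tissue = gt.tissue_mask
    recall = (sample.pixels & tissue).sum() / tissue.sum()
    assert recall >= 0.95


def test_sample_detection_saturated_frame(rng):
    cars = rng.integers(100, 300, (256, 256)).astype(np.uint16)
    img = MosaicImage(shg=np.zeros((256, 256), np.uint16), cars=cars,
                      pixel_size_um=4.0)
    mask = detect_sample_area(img)
    assert mask.pixels.mean() >= 0.99


def test_constant_frame_raises_no_tissue():
    flat = np.full((128, 128), 5, np.uint16)
    img = MosaicImage(shg=flat, cars=flat.copy(), pixel_size_um=4.0)
    with pytest.raises(NoTissueError):
        detect_sample_area(img)


# --- excluded-region detection ---------------------------------------------


def test_excluded_regions_cover_portal_and_capsule(phantom_stage1):
    img, gt = phantom_stage1
    seg = segment(img)
    truth = gt.portal_mask | gt.capsule_mask
    coverage = (seg.excluded.pixels & truth).sum() / truth.sum()
    assert coverage >= 0.95  # bright collagen structures are removed
    # and the exclusion stays a modest part of the specimen
    assert seg.excluded.area_px < 0.6 * seg.sample.area_px


def test_all_zero_shg_gives_empty_exclusion():
    shg = np.zeros((64, 64), np.uint16)
    cars = np.full((64, 64), 50, np.uint16)
    cars[:8] = 1  # some background so the sample mask is not the frame
    img = MosaicImage(shg=shg, cars=cars, pixel_size_um=8.0)
    sample = detect_sample_area(img)
    excluded, parts = detect_excluded_regions(img, sample)
    assert not excluded.pixels.any()
    assert parts == []


def test_mask_triple_is_consistent(phantom_stage1):
    img, _ = phantom_stage1
    seg = segment(img)
    assert not (seg.excluded.pixels & ~seg.sample.pixels).any()  # excluded <= sample
    np.testing.assert_array_equal(
        seg.parenchyma.pixels, seg.sample.pixels & ~seg.excluded.pixels)
    assert seg.parenchyma.area_px + seg.excluded.area_px == seg.sample.area_px


def test_size_filter_is_antimonotone(phantom_stage1):
    img, _ = phantom_stage1
    sample = detect_sample_area(img)
    small = MaskPipelineConfig(min_particle_area_um2=500.0)
    large = MaskPipelineConfig(min_particle_area_um2=50000.0)
    ex_small, _ = detect_excluded_regions(img, sample, small)
    ex_large, _ = detect_excluded_regions(img, sample, large)
    assert not (ex_large.pixels & ~ex_small.pixels).any()


def test_pipeline_is_deterministic(phantom_stage1):
    img, _ = phantom_stage1
    a = segment(img)
    b = segment(img)
    np.testing.assert_array_equal(a.sample.pixels, b.sample.pixels)
    np.testing.assert_array_equal(a.excluded.pixels, b.excluded.pixels)


def test_config_yaml_roundtrip(tmp_path):
    cfg = MaskPipelineConfig(min_roundness=0.3, portal_mean_scope="frame")
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert MaskPipelineConfig.from_yaml(path) == cfg
    with pytest.raises(ValueError):
        MaskPipelineConfig(border_threshold_fraction=1.2)
    with pytest.raises(ValueError):
        MaskPipelineConfig(connectivity=6)
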