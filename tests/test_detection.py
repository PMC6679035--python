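"""Preprocessing, thresholding, mode dispatch and quantification filters."""

import numpy as np
import pandas as pd
import pytest

from temsize.detection import (
    DetectionParams,
    analyze_micrograph,
    apply_quantification_filters,
    denoise,
    flatten_background,
    preprocess,
    segment,
    threshold_particles,
)
from temsize.imaging import Micrograph, QuantificationLimits
from temsize.scene_sim import SceneSpec, place_particles, render, sample_population, simulate_scene


def _disk_mask(shape, center, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r**2


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        DetectionParams(mode="fancy")
    with pytest.raises(ValueError):
        DetectionParams(smoothing_factor=-1)
    with pytest.raises(ValueError):
        DetectionParams(convexity_threshold=0.0)
    with pytest.raises(ValueError):
        DetectionParams(border_policy="keep")


def test_denoise_identity_at_zero():
    rng = np.random.default_rng(0)
    img = rng.random((64, 64))
    np.testing.assert_array_equal(denoise(img, 0.0), img)
    assert not np.array_equal(denoise(img, 2.0), img)


def test_linear_gradient_background_is_flattened():
    n = 256
    yy, xx = np.mgrid[:n, :n] / n
    img = 0.7 + 0.2 * xx  # pure ramp, no particles, no noise
    corrected = flatten_background(img, background_scale_px=n // 4)
    interior = corrected[32:-32, 32:-32]
    assert np.ptp(interior) < 1e-6


def test_preprocess_leaves_small_background_residual(disk_scene):
    spec, mg, _ = disk_scene
    corrected = preprocess(mg, smoothing_factor=1.0)
    contrast = spec.background_level * (1 - spec.particle_transmittance)
    # background (majority of pixels) sits near zero after flattening
    assert abs(np.median(corrected)) < 0.01 * contrast


def test_threshold_blank_image_empty_mask():
    assert not threshold_particles(np.full((64, 64), 0.5), 0.1).any()
    rng = np.random.default_rng(1)
    noisy = rng.normal(0.0, 0.01, (128, 128))
    assert not threshold_particles(noisy, min_otb=0.15).any()


def test_threshold_recovers_disks_and_respects_min_otb(disk_scene):
    spec, mg, truth = disk_scene
    corrected = preprocess(mg, 1.0)
    mask = threshold_particles(corrected, min_otb=0.2)
    from temsize.scene_sim import _rasterize, sample_population, place_particles

    truth_mask = mg.data < spec.background_level * 0.6
    jac = (mask & truth_mask).sum() / (mask | truth_mask).sum()
    assert jac >= 0.9
    # a veto above the particle contrast suppresses everything
    assert not threshold_particles(corrected, min_otb=0.9).any()


def test_min_otb_monotonicity(disk_scene):
    _, mg, _ = disk_scene
    corrected = preprocess(mg, 1.0)
    counts = []
    for otb in [0.05, 0.15, 0.3, 0.45, 0.6, 0.8]:
        mask = threshold_particles(corrected, otb)
        lab = segment(mask, corrected, DetectionParams(min_otb=otb), pixel_size_nm=1.0)
        counts.append(lab.n_particles)
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_default_mode_counts_disjoint_disks(disk_records, disk_scene):
    retained, log, truth = disk_records
    assert log["n_retained"] == len(truth) == 25
    med_true = truth.min_feret_nm.median()
    assert retained.min_feret_nm.median() == pytest.approx(med_true, rel=0.02)


def test_default_mode_splits_slightly_overlapping_pair():
    spec = SceneSpec(
        shape_class="sphere", size_law={"family": "constant", "value": 30.0},
        particle_count=2, cluster_mean=2.0, overlap_frac=0.05,
        fov_nm=128.0, n_pixels=256, seed=6,
    )
    mg, truth = simulate_scene(spec)
    assert truth.cluster_id.nunique() == 1
    corrected = preprocess(mg, 0.5)
    mask = threshold_particles(corrected, 0.15)
    lab = segment(mask, corrected, DetectionParams(mode="default"), pixel_size_nm=spec.pixel_size_nm)
    assert lab.n_particles == 2


def test_single_particle_mode_keeps_only_free_particles():
    spec = SceneSpec(
        shape_class="sphere", size_law={"family": "constant", "value": 20.0},
        particle_count=15, cluster_mean=1.0, overlap_frac=0.0,
        fov_nm=400.0, n_pixels=512, seed=8,
    )
    # one 10-particle aggregate + 5 isolated disks
    shapes = sample_population(spec)
    agg = place_particles(shapes[:10], cluster_mean=10.0, overlap_frac=0.3,
                          fov_nm=200.0, seed=1, edge_margin_nm=5.0)
    free = place_particles(shapes[10:], cluster_mean=1.0, overlap_frac=0.0,
                           fov_nm=180.0, seed=2, edge_margin_nm=5.0)
    layout = agg + [p.translated(210.0, 210.0) for p in free]
    mg, truth = render(layout, spec)
    corrected = preprocess(mg, 0.5)
    mask = threshold_particles(corrected, 0.15)
    lab = segment(mask, corrected, DetectionParams(mode="single_particle"),
                  pixel_size_nm=spec.pixel_size_nm)
    assert lab.n_particles == 5


def test_irregular_watershed_does_not_shred_rods():
    spec = SceneSpec(
        shape_class="rod", size_law={"family": "constant", "value": 16.0},
        particle_count=8, cluster_mean=2.0, overlap_frac=0.05,
        aspect_range=(3.0, 3.0), fov_nm=500.0, n_pixels=640, seed=10,
    )
    mg, truth = simulate_scene(spec)
    retained, log = analyze_micrograph(mg, DetectionParams(mode="irregular_watershed"))
    assert log["n_retained"] == len(truth)
    assert retained.min_feret_nm.median() == pytest.approx(16.0, rel=0.10)


def test_segmentation_determinism(disk_scene):
    _, mg, _ = disk_scene
    params = DetectionParams(mode="default")
    a, _ = analyze_micrograph(mg, params)
    b, _ = analyze_micrograph(mg, params)
    pd.testing.assert_frame_equal(a, b)


def test_quantification_filter_boundary_rules():
    # min-Feret px-equivalents {4, 6, 60, 244, 246} at lloq=6, uloq=245
    limits = QuantificationLimits(lod_nm=0.6, lloq_nm=6.0, uloq_nm=245.0, fov_nm=2450.0)
    rec = pd.DataFrame(
        {
            "min_feret_nm": [4.0, 6.0, 60.0, 244.0, 246.0],
            "flags": [""] * 5,
        }
    )
    kept, log = apply_quantification_filters(rec, limits)
    assert sorted(kept.min_feret_nm) == [6.0, 60.0, 244.0]  # lloq inclusive
    assert log["n_below_lloq"] == 1 and log["n_above_uloq"] == 1
    # all-inside is the identity
    inside = pd.DataFrame({"min_feret_nm": [10.0, 20.0], "flags": ["", ""]})
    kept2, log2 = apply_quantification_filters(inside, limits)
    assert len(kept2) == 2 and log2["n_retained"] == 2


def test_border_particles_excluded():
    spec = SceneSpec(
        shape_class="sphere", size_law={"family": "constant", "value": 30.0},
        particle_count=1, fov_nm=360.0, n_pixels=512, seed=3,
    )
    shapes = sample_population(spec)
    # straddle the left edge: center at x=0
    layout = [shapes[0].translated(-shapes[0].center[0], 180.0 - shapes[0].center[1])]
    mg, _ = render(layout, spec)
    retained, log = analyze_micrograph(mg, DetectionParams(border_policy="exclude_touching"))
    assert log["n_retained"] == 0 and log["n_border"] == 1
    retained2, _ = analyze_micrograph(mg, DetectionParams(border_policy="include"))
    assert len(retained2) == 1


def test_setting_robustness_small_parameter_changes(disk_scene):
    """+-10% changes of smoothing and min-OTB move the median < 2%."""
    _, mg, _ = disk_scene
    base, _ = analyze_micrograph(mg, DetectionParams(smoothing_factor=1.0, min_otb=0.15))
    med0 = base.min_feret_nm.median()
    for sf, otb in [(0.9, 0.15), (1.1, 0.15), (1.0, 0.135), (1.0, 0.165)]:
        alt, _ = analyze_micrograph(mg, DetectionParams(smoothing_factor=sf, min_otb=otb))
        assert alt.min_feret_nm.median() == pytest.approx(med0, rel=0.02)
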