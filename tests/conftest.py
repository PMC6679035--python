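import numpy as np
import pytest

from temsize.detection import DetectionParams, analyze_micrograph
from temsize.scene_sim import SceneSpec, simulate_scene


def _width_at(pts, theta):
    proj = pts @ np.array([np.cos(theta), np.sin(theta)])
    return proj.max() - proj.min()


def brute_force_min_feret(outline, step_deg=0.01, refine=True):
    """Directional-sweep oracle: min over a fine angle grid of the
    projection width, optionally sharpened by a ternary search around
    the best grid direction (the width function is V-shaped at its
    minimum, so the grid alone is only step-accurate)."""
    pts = np.asarray(outline, dtype=float)
    theta = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    normals = np.column_stack([np.cos(theta), np.sin(theta)])
    proj = pts @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    k = int(np.argmin(widths))
    best = float(widths[k])
    if not refine:
        return best
    lo, hi = theta[k] - np.deg2rad(step_deg), theta[k] + np.deg2rad(step_deg)
    for _ in range(120):
        m1 = lo + (hi - lo) / 3.0
        m2 = hi - (hi - lo) / 3.0
        if _width_at(pts, m1) <= _width_at(pts, m2):
            hi = m2
        else:
            lo = m1
    return float(min(best, _width_at(pts, (lo + hi) / 2.0)))


def brute_force_max_feret(outline):
    pts = np.asarray(outline, dtype=float)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    return float(d.max())


def random_convex_polygon(rng, n_max=12, radius=10.0):
    """Convex hull of random points: a random convex test polygon."""
    from temsize.measurands import convex_hull_vertices

    n = rng.integers(4, n_max + 1)
    pts = rng.uniform(-radius, radius, size=(n + 4, 2))
    return convex_hull_vertices(pts)


@pytest.fixture(scope="session")
def disk_scene():
    """Small noisy scene of disjoint constant-size disks + ground truth."""
    spec = SceneSpec(
        shape_class="sphere",
        size_law={"family": "constant", "value": 20.0},
        particle_count=25,
        cluster_mean=1.0,
        overlap_frac=0.0,
        fov_nm=360.0,
        n_pixels=512,
        poisson_dose=2000.0,
        read_noise=0.01,
        background_gradient=0.1,
        seed=31,
    )
    mg, truth = simulate_scene(spec)
    return spec, mg, truth


@pytest.fixture(scope="session")
def disk_records(disk_scene):
    _, mg, truth = disk_scene
    retained, log = analyze_micrograph(mg, DetectionParams(mode="default"))
    return retained, log, truth
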