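"""Synthetic calibrated micrographs with per-particle ground truth.

Real validation imagery cannot ship with a toolkit, so every downstream
stage is exercised on simulated bright-field scenes of the four
material classes the segmentation modes target:

``sphere``
    stable colloids of non-aggregated near-spherical particles
    (silica-like);
``ellipsoid``
    aggregated/agglomerated materials with spherical or ellipsoidal
    touching or slightly overlapping constituent particles
    (pigment-grade titania-like);
``rod``
    agglomerates of irregular elongated constituent particles modelled
    as stadium shapes (gold-nanorod-like);
``irregular``
    highly overlapping aggregates of perturbed star-convex particles
    (ceria-like).

Every particle is generated as a polygon in nm (origin at the top-left
pixel corner, x right, y down, pixel centers at half-integers); the
stored minimal/maximal Feret diameters are computed from that exact
polygon, so the truth table is an oracle for the measurand chain, not a
re-measurement.  Images follow the bright-field convention (particles
darker than the background) with an optional low-order background
gradient, Poisson shot noise and Gaussian read noise — a minimal CCD
model, not a physical electron-optical one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import Polygon

from .imaging import Micrograph
from .measurands import min_feret, max_feret, polygon_area, ecd

__all__ = [
    "SceneSpec",
    "GroundTruthParticle",
    "PlacementError",
    "sample_population",
    "place_particles",
    "render",
    "simulate_scene",
    "scene_spec_for_class",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = [
    "particle_id",
    "cluster_id",
    "center_x_nm",
    "center_y_nm",
    "min_feret_nm",
    "max_feret_nm",
    "ecd_nm",
    "outline_wkt",
]


class PlacementError(RuntimeError):
    """Raised when particles cannot be placed within the overlap budget."""


@dataclass
class SceneSpec:
    """Full description of one synthetic scene; deterministic given ``seed``."""

    shape_class: str = "sphere"
    size_law: dict = field(default_factory=lambda: {"family": "lognormal", "median": 20.0, "gsd": 1.15})
    particle_count: int = 100
    cluster_mean: float = 1.0
    overlap_frac: float = 0.0
    fov_nm: float = 1230.0
    n_pixels: int = 2048
    aspect_range: tuple[float, float] = (1.0, 1.0)
    background_level: float = 0.78
    particle_transmittance: float = 0.30
    background_gradient: float = 0.0
    poisson_dose: float = 0.0
    read_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.particle_count < 1:
            raise ValueError("particle_count must be >= 1")
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap fraction must be in [0, 1)")
        if self.fov_nm <= 0:
            raise ValueError("fov_nm must be positive")
        if self.n_pixels < 64:
            raise ValueError("n_pixels must be >= 64")
        if self.shape_class not in {"sphere", "ellipsoid", "rod", "irregular"}:
            raise ValueError(f"unknown shape_class {self.shape_class!r}")

    @property
    def pixel_size_nm(self) -> float:
        return self.fov_nm / self.n_pixels

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruthParticle:
    """One simulated constituent particle; outline and sizes in nm."""

    particle_id: int
    outline: np.ndarray
    min_feret_nm: float
    max_feret_nm: float
    ecd_nm: float
    cluster_id: int = -1

    @property
    def center(self) -> np.ndarray:
        return self.outline.mean(axis=0)

    def translated(self, dx: float, dy: float) -> "GroundTruthParticle":
        return GroundTruthParticle(
            particle_id=self.particle_id,
            outline=self.outline + np.array([dx, dy]),
            min_feret_nm=self.min_feret_nm,
            max_feret_nm=self.max_feret_nm,
            ecd_nm=self.ecd_nm,
            cluster_id=self.cluster_id,
        )


# ---------------------------------------------------------------------------
# shape generation

_N_VERT = 96  # vertices per outline; polygonisation error ~(pi/96)^2/2 < 6e-4


def _unit_outline(shape_class: str, aspect: float, rng: np.random.Generator) -> np.ndarray:
    """A closed outline of roughly unit size, centered at the origin."""
    t = np.linspace(0.0, 2.0 * np.pi, _N_VERT, endpoint=False)
    if shape_class == "sphere":
        return np.column_stack([np.cos(t), np.sin(t)])
    if shape_class == "ellipsoid":
        return np.column_stack([aspect * np.cos(t), np.sin(t)])
    if shape_class == "rod":
        # stadium of width 2 and total length 2*aspect (unit semicircle caps)
        half = aspect - 1.0
        a = np.linspace(-np.pi / 2, np.pi / 2, _N_VERT // 2)
        right = np.column_stack([half + np.cos(a), np.sin(a)])
        left = np.column_stack([-half - np.cos(a), -np.sin(a)])
        return np.vstack([right, left])
    if shape_class == "irregular":
        # star-convex radial perturbation with a few low-order modes
        r = np.ones_like(t)
        for k in range(2, 7):
            r += rng.uniform(0.0, 0.12) * np.cos(k * t + rng.uniform(0, 2 * np.pi))
        r = np.clip(r, 0.3, None)
        return np.column_stack([r * np.cos(t), r * np.sin(t)])
    raise ValueError(shape_class)


def _draw_sizes(size_law: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    family = size_law.get("family", "constant")
    if family == "constant":
        return np.full(n, float(size_law["value"]))
    if family == "lognormal":
        median, gsd = float(size_law["median"]), float(size_law["gsd"])
        if median <= 0 or gsd < 1.0:
            raise ValueError("lognormal law needs median > 0 and gsd >= 1")
        return rng.lognormal(np.log(median), np.log(gsd), size=n)
    if family == "normal":
        mean, sd = float(size_law["mean"]), float(size_law["sd"])
        if mean <= 0 or sd < 0:
            raise ValueError("normal law needs mean > 0 and sd >= 0")
        vals = rng.normal(mean, sd, size=n)
        return np.clip(vals, mean * 0.05, None)
    raise ValueError(f"unknown size law family {family!r}")


def sample_population(spec: SceneSpec) -> list[GroundTruthParticle]:
    """Draw ``particle_count`` shapes (unplaced, centered at the origin).

    The size law governs the *minimal Feret diameter*: each outline is
    scaled so its exact caliper width equals the drawn size, then
    randomly rotated.  Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    sizes = _draw_sizes(spec.size_law, spec.particle_count, rng)
    lo, hi = spec.aspect_range
    aspects = rng.uniform(lo, hi, size=spec.particle_count)
    angles = rng.uniform(0.0, np.pi, size=spec.particle_count)
    particles = []
    for i in range(spec.particle_count):
        out = _unit_outline(spec.shape_class, max(1.0, aspects[i]), rng)
        out = out * (sizes[i] / min_feret(out))
        c, s = np.cos(angles[i]), np.sin(angles[i])
        out = out @ np.array([[c, -s], [s, c]]).T
        particles.append(
            GroundTruthParticle(
                particle_id=i,
                outline=out,
                min_feret_nm=min_feret(out),
                max_feret_nm=max_feret(out),
                ecd_nm=ecd(polygon_area(out)),
            )
        )
    return particles


# ---------------------------------------------------------------------------
# placement

def _overlap_fraction(a: Polygon, b: Polygon) -> float:
    inter = a.intersection(b).area
    if inter == 0.0:
        return 0.0
    return inter / min(a.area, b.area)


def _attach_member(
    members: list[GroundTruthParticle],
    polys: list[Polygon],
    new: GroundTruthParticle,
    overlap_frac: float,
    rng: np.random.Generator,
    max_tries: int = 40,
) -> GroundTruthParticle | None:
    """Place ``new`` touching/overlapping one existing cluster member."""
    new_poly0 = Polygon(new.outline)
    for _ in range(max_tries):
        k = rng.integers(len(members))
        anchor = polys[k]
        theta = rng.uniform(0.0, 2.0 * np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        c0 = np.asarray(anchor.centroid.coords[0])
        target = overlap_frac * rng.uniform(0.3, 0.9) if overlap_frac > 0 else 0.0
        d_hi = (members[k].max_feret_nm + new.max_feret_nm) / 1.6
        d_lo = 0.0

        def frac_at(d):
            shifted = shapely.affinity.translate(
                new_poly0, *(c0 + d * u - np.asarray(new_poly0.centroid.coords[0]))
            )
            return _overlap_fraction(anchor, shifted), shifted

        d_cap = 20.0 * d_hi
        f_hi, _ = frac_at(d_hi)
        while f_hi > max(target, 1e-6) and d_hi < d_cap:
            d_hi *= 1.4
            f_hi, _ = frac_at(d_hi)
        # bisect to the target overlap (touching when target == 0)
        for _ in range(45):
            mid = (d_lo + d_hi) / 2.0
            f_mid, shifted = frac_at(mid)
            if f_mid > target:
                d_lo = mid
            else:
                d_hi = mid
        f_final, shifted = frac_at(d_hi if target == 0 else (d_lo + d_hi) / 2.0)
        if target == 0:
            # nudge inward so rasterised masks actually touch
            f_final, shifted = frac_at(max(d_hi - 1e-3 * new.min_feret_nm, 0.0))
        if f_final > overlap_frac + 1e-9 and overlap_frac > 0:
            continue
        # respect the overlap budget against every member, not just the anchor
        ok = True
        for j, p in enumerate(polys):
            if j == k:
                continue
            if _overlap_fraction(p, shifted) > max(overlap_frac, 1e-9):
                ok = False
                break
        if not ok:
            continue
        dxy = np.asarray(shifted.centroid.coords[0]) - np.asarray(
            new_poly0.centroid.coords[0]
        )
        return new.translated(*dxy)
    return None


def place_particles(
    shapes: Sequence[GroundTruthParticle],
    cluster_mean: float,
    overlap_frac: float,
    fov_nm: float,
    seed: int,
    *,
    min_gap_nm: float = 1.0,
    edge_margin_nm: float = 1.0,
    max_cluster_tries: int = 60,
) -> list[GroundTruthParticle]:
    """Lay shapes out in the field of view in clusters.

    Cluster sizes are 1 + Poisson(cluster_mean - 1); members of a
    cluster touch or overlap by at most ``overlap_frac`` of the smaller
    particle's area, distinct clusters (and all particles when
    ``cluster_mean == 1``) stay disjoint with a gap of at least
    ``min_gap_nm``.  Raises :class:`PlacementError` when the field of
    view is too crowded after bounded retries.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    shapes = list(shapes)
    # partition into clusters
    clusters: list[list[GroundTruthParticle]] = []
    i = 0
    while i < len(shapes):
        size = 1 + (rng.poisson(cluster_mean - 1.0) if cluster_mean > 1 else 0)
        clusters.append(shapes[i : i + size])
        i += size

    placed: list[GroundTruthParticle] = []
    placed_polys: list[Polygon] = []
    for cid, members0 in enumerate(clusters):
        # build the cluster in a local frame first
        local = [members0[0].translated(0.0, 0.0)]
        local_polys = [Polygon(local[0].outline)]
        for m in members0[1:]:
            att = _attach_member(local, local_polys, m, overlap_frac, rng)
            if att is None:
                raise PlacementError(
                    f"could not attach particle {m.particle_id} within the "
                    f"overlap budget {overlap_frac}"
                )
            local.append(att)
            local_polys.append(Polygon(att.outline))
        pts = np.vstack([m.outline for m in local])
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        span = hi - lo
        room = fov_nm - 2 * edge_margin_nm - span
        if np.any(room < 0):
            raise PlacementError(
                f"cluster of extent {span} nm does not fit in a {fov_nm} nm field"
            )
        ok = False
        for _ in range(max_cluster_tries):
            origin = edge_margin_nm + rng.uniform(0.0, 1.0, size=2) * room
            shift = origin - lo
            cand = [Polygon(m.outline + shift) for m in local]
            conflict = False
            for cp in cand:
                grown = cp.buffer(min_gap_nm / 2.0, quad_segs=2)
                for pp in placed_polys:
                    if grown.intersects(pp):
                        conflict = True
                        break
                if conflict:
                    break
            if not conflict:
                for m, cp in zip(local, cand):
                    mm = m.translated(*shift)
                    mm.cluster_id = cid
                    placed.append(mm)
                    placed_polys.append(cp.buffer(min_gap_nm / 2.0, quad_segs=2))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place cluster {cid} after {max_cluster_tries} tries; "
                "field of view too crowded"
            )
    return placed


# ---------------------------------------------------------------------------
# rendering

def _rasterize(particles, spec: SceneSpec) -> np.ndarray:
    """Boolean particle mask: pixel centers (half-integer nm) inside outlines."""
    n, px = spec.n_pixels, spec.pixel_size_nm
    mask = np.zeros((n, n), dtype=bool)
    for p in particles:
        poly = Polygon(p.outline)
        lo_x, lo_y, hi_x, hi_y = poly.bounds
        c0 = max(0, int(np.floor(lo_x / px)) - 1)
        c1 = min(n, int(np.ceil(hi_x / px)) + 1)
        r0 = max(0, int(np.floor(lo_y / px)) - 1)
        r1 = min(n, int(np.ceil(hi_y / px)) + 1)
        if c1 <= c0 or r1 <= r0:
            continue
        xs = (np.arange(c0, c1) + 0.5) * px
        ys = (np.arange(r0, r1) + 0.5) * px
        xg, yg = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(poly, xg.ravel(), yg.ravel()).reshape(xg.shape)
        mask[r0:r1, c0:c1] |= inside
    return mask


def render(
    particles: Sequence[GroundTruthParticle], spec: SceneSpec
) -> tuple[Micrograph, pd.DataFrame]:
    """Render a placed layout into a bright-field micrograph + truth table.

    Intensities are in [0, 1]; particles multiply the background by the
    particle transmittance (overlapping particles do not darken twice).
    Shot noise (``poisson_dose`` counts at full scale) and Gaussian read
    noise are applied after rasterisation; both are skipped when zero.
    """
    n = spec.n_pixels
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    yy, xx = np.meshgrid(np.linspace(0, 1, n), np.linspace(0, 1, n), indexing="ij")
    background = np.full((n, n), spec.background_level)
    if spec.background_gradient > 0:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        plane = np.cos(theta) * (xx - 0.5) + np.sin(theta) * (yy - 0.5)
        background *= 1.0 + spec.background_gradient * plane
    image = background.copy()
    if particles:
        mask = _rasterize(particles, spec)
        image[mask] = background[mask] * spec.particle_transmittance
    if spec.poisson_dose > 0:
        image = rng.poisson(np.clip(image, 0, None) * spec.poisson_dose) / spec.poisson_dose
    if spec.read_noise > 0:
        image = image + rng.normal(0.0, spec.read_noise, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    rows = [
        {
            "particle_id": p.particle_id,
            "cluster_id": p.cluster_id,
            "center_x_nm": p.center[0],
            "center_y_nm": p.center[1],
            "min_feret_nm": p.min_feret_nm,
            "max_feret_nm": p.max_feret_nm,
            "ecd_nm": p.ecd_nm,
            "outline_wkt": Polygon(p.outline).wkt,
        }
        for p in particles
    ]
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    mg = Micrograph(data=image, pixel_size_nm=spec.pixel_size_nm, meta=spec.to_dict())
    return mg, truth


def simulate_scene(spec: SceneSpec) -> tuple[Micrograph, pd.DataFrame]:
    """Sample, place and render a full scene from one spec (one seed)."""
    shapes = sample_population(spec)
    placed = place_particles(
        shapes,
        spec.cluster_mean,
        spec.overlap_frac,
        spec.fov_nm,
        spec.seed,
        min_gap_nm=3.0 * spec.pixel_size_nm,
        edge_margin_nm=2.0 * spec.pixel_size_nm,
    )
    return render(placed, spec)


_CLASS_PRESETS = {
    # the four material classes the four analysis modes target
    "sphere": dict(cluster_mean=1.0, overlap_frac=0.0, aspect_range=(1.0, 1.0)),
    "ellipsoid": dict(cluster_mean=3.0, overlap_frac=0.10, aspect_range=(1.2, 1.8)),
    "rod": dict(cluster_mean=3.0, overlap_frac=0.08, aspect_range=(2.5, 3.5)),
    "irregular": dict(cluster_mean=6.0, overlap_frac=0.35, aspect_range=(1.0, 1.3)),
}


def scene_spec_for_class(shape_class: str, **overrides) -> SceneSpec:
    """A SceneSpec with morphology presets for one of the four classes."""
    if shape_class not in _CLASS_PRESETS:
        raise ValueError(f"unknown shape_class {shape_class!r}")
    kw = dict(_CLASS_PRESETS[shape_class])
    kw["shape_class"] = shape_class
    kw.update(overrides)
    return SceneSpec(**kw)
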