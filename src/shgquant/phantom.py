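"""Synthetic two-channel biopsy phantoms with ground-truth masks.

A phantom emulates a ~4 x 4 mm stitched mosaic of a native liver section:

* a smooth tissue blob covering about half the frame;
* a bright SHG capsule band along the specimen border;
* bright, roundish SHG portal areas (100-400 um across) inside the tissue;
* weak, wavy parenchymal collagen fibrils 20-200 um long, drawn one pixel
  wide with a partial-volume amplitude (real fibrils are ~1 um across,
  i.e. sub-pixel at mosaic pitch), whose density scales with fibrosis
  stage;
* a moderate, textured hepatocyte CARS signal with bright lipid droplets
  whose density scales with steatosis grade;
* nonnegative (gamma) detector noise everywhere.

Everything is reproducible from the seed, and the generator returns the
true masks so the segmentation and quantification pipeline can be scored
against a known answer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import MosaicImage

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "generate_cohort",
    "STAGE_FIBRIL_DENSITY",
    "GRADE_DROPLET_DENSITY",
]

# fibrils per mm^2 of parenchyma by fibrosis stage; chosen so the stage-0
# parenchymal raw mean sits roughly 8-fold above the background mean and
# stage 1 roughly doubles stage 0 (see docs/methods.md)
STAGE_FIBRIL_DENSITY = {0: 320.0, 1: 650.0, 2: 1100.0, 3: 1700.0, 4: 2500.0}

# lipid droplets per mm^2 of tissue by steatosis grade
GRADE_DROPLET_DENSITY = {0: 2.0, 1: 15.0, 2: 35.0, 3: 60.0}


@dataclass
class PhantomSpec:
    """Generative parameters of one phantom biopsy."""

    stage: int = 1
    steatosis_grade: int = 1
    frame_px: tuple[int, int] = (2048, 2048)
    pixel_size_um: float = 2.0
    bit_depth: int = 16
    fibril_density: float | None = None  # per mm^2; None -> stage default
    fibril_length_range_um: tuple[float, float] = (20.0, 200.0)
    fibril_intensity: float = 400.0  # amplitude of a 1-um fibril core
    fibril_width_um: float = 1.0
    fibril_curvature: float = 0.3  # heading diffusion per step (rad)
    portal_count: int | None = None  # None -> 4 + 2*stage
    portal_intensity: float = 4000.0
    portal_diameter_range_um: tuple[float, float] = (100.0, 400.0)
    capsule_thickness_um: float = 60.0
    capsule_intensity: float = 4000.0
    hepatocyte_intensity: float = 30.0
    droplet_density: float | None = None  # per mm^2; None -> grade default
    droplet_radius_range_um: tuple[float, float] = (8.0, 40.0)
    droplet_intensity: float = 250.0
    tissue_fraction: float = 0.5
    noise_mean: float = 2.0
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.stage not in range(5):
            raise ValueError(f"stage must be 0..4, got {self.stage}")
        if self.steatosis_grade not in range(4):
            raise ValueError(f"steatosis_grade must be 0..3, got {self.steatosis_grade}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        lo, hi = self.fibril_length_range_um
        if not (0 < lo <= hi):
            raise ValueError("fibril_length_range_um must satisfy 0 < min <= max")
        for name in ("fibril_intensity", "portal_intensity", "capsule_intensity",
                     "hepatocyte_intensity", "droplet_intensity",
                     "capsule_thickness_um", "noise_mean", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.2 <= self.tissue_fraction <= 0.8:
            raise ValueError("tissue_fraction must lie in [0.2, 0.8]")

    @property
    def fibril_density_resolved(self) -> float:
        if self.fibril_density is not None:
            return float(self.fibril_density)
        return STAGE_FIBRIL_DENSITY[self.stage]

    @property
    def droplet_density_resolved(self) -> float:
        if self.droplet_density is not None:
            return float(self.droplet_density)
        return GRADE_DROPLET_DENSITY[self.steatosis_grade]

    @property
    def portal_count_resolved(self) -> int:
        if self.portal_count is not None:
            return int(self.portal_count)
        return 4 + 2 * self.stage


@dataclass
class GroundTruth:
    """True masks and area fractions paired with a generated phantom."""

    tissue_mask: np.ndarray
    portal_mask: np.ndarray
    capsule_mask: np.ndarray
    fibril_mask: np.ndarray
    droplet_mask: np.ndarray
    true_fibril_area_fraction: float  # fibril px / parenchyma px
    true_droplet_area_fraction: float  # droplet px / tissue px

    @property
    def parenchyma_mask(self) -> np.ndarray:
        return self.tissue_mask & ~self.portal_mask & ~self.capsule_mask


def _tissue_blob(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.frame_px
    cy = h / 2 + rng.uniform(-0.03, 0.03) * h
    cx = w / 2 + rng.uniform(-0.03, 0.03) * w
    r0 = np.sqrt(spec.tissue_fraction * h * w / np.pi)
    n_modes = 4
    amps = rng.normal(0.0, 0.035, n_modes)
    amps = np.clip(amps, -0.08, 0.08)
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    boundary = r0 * (1.0 + sum(a * np.cos((k + 2) * theta + p)
                               for k, (a, p) in enumerate(zip(amps, phases))))
    return dy**2 + dx**2 <= boundary**2


def _rasterize_ellipse(mask: np.ndarray, cy: float, cx: float, a_px: float,
                       b_px: float, angle: float) -> None:
    h, w = mask.shape
    r = int(np.ceil(max(a_px, b_px))) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    mask[y0:y1, x0:x1] |= (u / a_px)**2 + (v / b_px)**2 <= 1.0


def _draw_portals(spec: PhantomSpec, tissue: np.ndarray, dist_in: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    h, w = tissue.shape
    portal = np.zeros_like(tissue)
    d_lo, d_hi = spec.portal_diameter_range_um
    centers = []
    n = spec.portal_count_resolved
    if n == 0:
        return portal, np.empty((0, 2))
    for _ in range(n):
        d = rng.uniform(d_lo, d_hi)
        a_um = d / 2
        b_um = a_um * rng.uniform(0.65, 1.0)
        angle = rng.uniform(0, np.pi)
        margin = spec.capsule_thickness_um + a_um + 20.0
        candidates = np.flatnonzero(dist_in.ravel() >= margin)
        if candidates.size == 0:  # tissue too small for this portal: shrink
            candidates = np.flatnonzero(
                dist_in.ravel() >= spec.capsule_thickness_um + 10.0)
            if candidates.size == 0:
                continue
            a_um = b_um = 50.0
        flat = int(rng.choice(candidates))
        cy, cx = divmod(flat, w)
        _rasterize_ellipse(portal, cy, cx, a_um / spec.pixel_size_um,
                           b_um / spec.pixel_size_um, angle)
        centers.append((cy, cx))
    portal &= tissue
    return portal, np.asarray(centers, dtype=float)


def _draw_fibrils(spec: PhantomSpec, parenchyma: np.ndarray,
                  portal_centers: np.ndarray, rng: np.random.Generator,
                  shg: np.ndarray) -> np.ndarray:
    """Wavy random-walk polylines, one pixel wide, clipped to the parenchyma."""
    h, w = parenchyma.shape
    px = spec.pixel_size_um
    area_mm2 = parenchyma.sum() * px**2 / 1e6
    n_fib = int(rng.poisson(spec.fibril_density_resolved * area_mm2))
    fibril = np.zeros((h, w), dtype=bool)
    if n_fib == 0 or not parenchyma.any():
        return fibril
    lo, hi = spec.fibril_length_range_um
    lengths = rng.uniform(lo, hi, n_fib)
    n_steps = np.maximum(1, np.rint(lengths / px).astype(int))
    max_steps = int(n_steps.max())

    candidates = np.flatnonzero(parenchyma.ravel())
    starts = rng.choice(candidates, n_fib)
    r0, c0 = np.divmod(starts, w)

    theta0 = rng.uniform(0, 2 * np.pi, n_fib)
    # a fraction of fibrils head toward another portal area (septal bridging)
    if len(portal_centers) >= 2:
        bridging = rng.random(n_fib) < 0.15
        idx = rng.integers(0, len(portal_centers), bridging.sum())
        tgt = portal_centers[idx]
        theta0[bridging] = np.arctan2(tgt[:, 0] - r0[bridging],
                                      tgt[:, 1] - c0[bridging])
    dtheta = rng.normal(0.0, spec.fibril_curvature, (n_fib, max_steps))
    theta = theta0[:, None] + np.cumsum(dtheta, axis=1)
    rows = np.rint(r0[:, None] + np.cumsum(np.sin(theta), axis=1)).astype(int)
    cols = np.rint(c0[:, None] + np.cumsum(np.cos(theta), axis=1)).astype(int)
    rows = np.concatenate([r0[:, None], rows], axis=1)
    cols = np.concatenate([c0[:, None], cols], axis=1)
    step_idx = np.arange(max_steps + 1)[None, :]
    valid = step_idx <= n_steps[:, None]
    valid &= (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    rr, cc = rows[valid], cols[valid]
    fid = np.broadcast_to(np.arange(n_fib)[:, None], rows.shape)[valid]
    inside = parenchyma[rr, cc]
    rr, cc, fid = rr[inside], cc[inside], fid[inside]
    # de-duplicate revisited pixels within a fibril so intensities add once
    key = fid.astype(np.int64) * (h * w) + rr.astype(np.int64) * w + cc
    uniq = np.unique(key)
    fid_u, rem = np.divmod(uniq, h * w)
    rr_u, cc_u = np.divmod(rem, w)
    amp = spec.fibril_intensity * min(1.0, spec.fibril_width_um / px)
    per_fibril = amp * rng.uniform(0.6, 1.4, n_fib)
    np.add.at(shg, (rr_u, cc_u), per_fibril[fid_u])
    fibril[rr_u, cc_u] = True
    return fibril


def _draw_droplets(spec: PhantomSpec, tissue: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    h, w = tissue.shape
    px = spec.pixel_size_um
    area_mm2 = tissue.sum() * px**2 / 1e6
    n = int(rng.poisson(spec.droplet_density_resolved * area_mm2))
    droplet = np.zeros_like(tissue)
    if n == 0 or not tissue.any():
        return droplet
    candidates = np.flatnonzero(tissue.ravel())
    centers = rng.choice(candidates, n)
    radii = rng.uniform(*spec.droplet_radius_range_um, n) / px
    for flat, r in zip(centers, radii):
        cy, cx = divmod(int(flat), w)
        _rasterize_ellipse(droplet, cy, cx, max(r, 0.6), max(r, 0.6), 0.0)
    droplet &= tissue
    return droplet


def _check_densities(spec: PhantomSpec) -> None:
    mean_len = sum(spec.fibril_length_range_um) / 2
    # nominal (pre-overlap) physical coverage, independent of pixel pitch
    fib_frac = spec.fibril_density_resolved * mean_len * spec.fibril_width_um / 1e6
    r_lo, r_hi = spec.droplet_radius_range_um
    mean_r2 = (r_lo**2 + r_lo * r_hi + r_hi**2) / 3
    drop_frac = spec.droplet_density_resolved * np.pi * mean_r2 / 1e6
    if fib_frac > 0.8 or drop_frac > 0.9:
        raise ValueError(
            f"densities overflow the tissue area (nominal fibril coverage "
            f"{fib_frac:.2f}, droplet coverage {drop_frac:.2f})")


def generate_phantom(spec: PhantomSpec) -> tuple[MosaicImage, GroundTruth]:
    """Generate one phantom mosaic and its ground truth, reproducibly."""
    _check_densities(spec)
    rng = np.random.default_rng(spec.seed)
    h, w = spec.frame_px
    px = spec.pixel_size_um

    tissue = _tissue_blob(spec, rng)
    dist_in = ndimage.distance_transform_edt(tissue, sampling=px)
    capsule = tissue & (dist_in <= spec.capsule_thickness_um) \
        if spec.capsule_thickness_um > 0 else np.zeros_like(tissue)
    portal, portal_centers = _draw_portals(spec, tissue, dist_in, rng)
    portal &= ~capsule
    parenchyma = tissue & ~capsule & ~portal

    shg = np.zeros((h, w), dtype=np.float64)
    fibril = _draw_fibrils(spec, parenchyma, portal_centers, rng, shg)
    shg[portal] += spec.portal_intensity
    shg[capsule] += spec.capsule_intensity * rng.uniform(0.8, 1.0)

    droplet = _draw_droplets(spec, tissue, rng)
    cars = np.zeros((h, w), dtype=np.float64)
    if spec.hepatocyte_intensity > 0:
        sigma_px = max(1.0, 150.0 / px)
        g = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma_px)
        sd = g.std()
        texture = 1.0 + 0.3 * (g / sd if sd > 0 else g)
        texture = np.clip(texture, 0.3, 2.0)
        cars[tissue] = spec.hepatocyte_intensity * texture[tissue]
    cars[droplet] += spec.droplet_intensity

    if spec.noise_mean > 0:
        if spec.noise_sd > 0:
            k = (spec.noise_mean / spec.noise_sd) ** 2
            theta = spec.noise_sd**2 / spec.noise_mean
            shg += rng.gamma(k, theta, (h, w))
            cars += rng.gamma(k, theta, (h, w))
        else:
            shg += spec.noise_mean
            cars += spec.noise_mean

    if spec.bit_depth in (8, 16):
        top = 2**spec.bit_depth - 1
        shg = np.clip(np.rint(shg), 0, top)
        cars = np.clip(np.rint(cars), 0, top)
        dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
        shg, cars = shg.astype(dtype), cars.astype(dtype)
    else:
        shg, cars = shg.astype(np.float32), cars.astype(np.float32)

    img = MosaicImage(shg=shg, cars=cars, pixel_size_um=px,
                      bit_depth=spec.bit_depth)
    n_par = parenchyma.sum()
    n_tis = tissue.sum()
    gt = GroundTruth(
        tissue_mask=tissue, portal_mask=portal, capsule_mask=capsule,
        fibril_mask=fibril, droplet_mask=droplet,
        true_fibril_area_fraction=float(fibril.sum() / n_par) if n_par else 0.0,
        true_droplet_area_fraction=float(droplet.sum() / n_tis) if n_tis else 0.0,
    )
    return img, gt


def generate_cohort(n_per_stage: int, base_spec: PhantomSpec | None = None,
                    seed: int = 0, stages: tuple[int, ...] = (0, 1, 2, 3, 4)
                    ) -> list[tuple[PhantomSpec, MosaicImage, GroundTruth]]:
    """A deterministic cohort with ``n_per_stage`` phantoms per stage.

    Per-sample seeds derive from the master seed; steatosis grades are
    drawn uniformly from 0-3 with the same master stream, so the cohort
    carries both a fibrosis and a fat gradient.
    """
    if n_per_stage < 1:
        raise ValueError("n_per_stage must be >= 1")
    base = base_spec or PhantomSpec()
    ss = np.random.SeedSequence(seed)
    n_total = n_per_stage * len(stages)
    sample_seeds = [int(s) for s in (ss.generate_state(n_total) >> 1)]
    grade_rng = np.random.default_rng(ss.spawn(1)[0])
    grades = grade_rng.integers(0, 4, n_total)
    cohort = []
    i = 0
    for stage in stages:
        for _ in range(n_per_stage):
            spec = dataclasses.replace(base, stage=int(stage),
                                       steatosis_grade=int(grades[i]),
                                       seed=sample_seeds[i])
            img, gt = generate_phantom(spec)
            cohort.append((spec, img, gt))
            i += 1
    return cohort
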