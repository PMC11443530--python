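"""Synthetic fluorescence-microscopy scenes with exact ground truth.

Emulates cells expressing a phase-separation kinase-activity reporter:
diffuse cytosolic fluorescence plus bright, near-spherical condensates
that nucleate, grow, coalesce and dissolve under a kinase-activity
trace ``a(t)``, with all reporter-derived intensity optionally
modulated by a Ca²⁺ trace ``c(t)`` (dual-reporter mode). The generator
returns both pixel data and the droplet schedule that produced it, so
detection and time-series estimators can be validated against exact
truth.

Model summary
-------------
* Nucleation is a Poisson process with per-frame intensity
  ``nucleation_rate * a(t) * dt`` per cell, at uniform positions inside
  the cell, suppressed inside a depletion zone around existing
  condensates (local monomer depletion).
* Alive condensates grow linearly in diameter at ``growth_rate * a(t)``
  and merge when their discs overlap (volume-conserving diameter).
* When activity falls, non-persistent condensates dissolve with
  per-frame hazard ``1 - exp(-dissolve_rate * (1 - a(t)) * dt)``;
  persistent ones never do (the "memory" population).
* Rendering conserves reporter flux per cell before noise: condensate
  brightness (proportional to d³ at a fixed enrichment over the
  cytosol) is drawn from the diffuse pool, so the cytosol dims as
  condensates accumulate material. Poisson then Gaussian read noise is
  applied last.

All randomness derives from ``SceneConfig.rng_seed``; identical config
and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .core import ImageStack

# ---------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------


class CellGeometry(BaseModel):
    """Elliptical cell footprint: center and semi-axes in µm."""

    center_um: tuple[float, float]  # (y, x)
    radii_um: tuple[float, float]  # (ry, rx)
    z_radius_um: float = 2.5  # semi-axis along z for volumetric scenes

    @model_validator(mode="after")
    def _positive(self):
        if min(self.radii_um) <= 0 or self.z_radius_um <= 0:
            raise ValueError("cell radii must be positive")
        return self


class NoiseConfig(BaseModel):
    """Poisson shot noise (gain 0 disables), Gaussian read noise, and a
    constant camera offset added before the Poisson step."""

    poisson_gain: float = Field(default=1.0, ge=0)
    read_sigma: float = Field(default=2.0, ge=0)
    offset: float = Field(default=20.0, ge=0)


class SceneConfig(BaseModel):
    """Geometry, optics, expression and noise for one synthetic scene."""

    image_shape: tuple[int, int] = (64, 64)  # (ny, nx)
    n_z: int = Field(default=1, ge=1)
    pixel_size_um: float = Field(default=0.2, gt=0)
    z_step_um: float = Field(default=0.3, gt=0)
    frame_interval_s: float = Field(default=5.0, gt=0)
    cells: list[CellGeometry] = Field(
        default_factory=lambda: [
            CellGeometry(center_um=(6.4, 6.4), radii_um=(4.5, 3.5))
        ]
    )
    expression_levels: list[float] = Field(default_factory=lambda: [50.0])
    psf_sigma_um: float = Field(default=0.2, ge=0)
    psf_sigma_z_um: float = Field(default=0.4, ge=0)
    enrichment: float = Field(default=10.0, gt=1)
    section_depth_um: float = Field(default=1.0, gt=0)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _consistent(self):
        if len(self.cells) != len(self.expression_levels):
            raise ValueError("one expression level per cell required")
        ny, nx = self.image_shape
        for cell in self.cells:
            cy, cx = cell.center_um
            ry, rx = cell.radii_um
            if (
                cy - ry < 0
                or cx - rx < 0
                or cy + ry > ny * self.pixel_size_um
                or cx + rx > nx * self.pixel_size_um
            ):
                raise ValueError("cell mask extends beyond image bounds")
        return self


def cell_mask(config: SceneConfig, cell_index: int) -> np.ndarray:
    """Boolean pixel mask of one cell's elliptical footprint."""
    ny, nx = config.image_shape
    cell = config.cells[cell_index]
    px = config.pixel_size_um
    yy, xx = np.mgrid[0:ny, 0:nx]
    y_um = (yy + 0.5) * px
    x_um = (xx + 0.5) * px
    cy, cx = cell.center_um
    ry, rx = cell.radii_um
    mask = ((y_um - cy) / ry) ** 2 + ((x_um - cx) / rx) ** 2 <= 1.0
    if not mask.any():
        raise ValueError(f"cell {cell_index} has an empty pixel mask")
    return mask


# ---------------------------------------------------------------------
# Activity protocol
# ---------------------------------------------------------------------


@dataclass
class ActivityProtocol:
    """Per-frame kinase activity a(t) in [0, 1] and Ca²⁺ level c(t)
    relative to a baseline of 1, plus labelled stimulus windows
    (half-open frame ranges)."""

    kinase_activity: np.ndarray
    ca_level: np.ndarray
    windows: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kinase_activity = np.asarray(self.kinase_activity, dtype=float)
        self.ca_level = np.asarray(self.ca_level, dtype=float)
        if self.kinase_activity.shape != self.ca_level.shape:
            raise ValueError("activity and Ca traces must have equal length")
        for name, tr in (
            ("kinase_activity", self.kinase_activity),
            ("ca_level", self.ca_level),
        ):
            if not np.isfinite(tr).all() or (tr < 0).any():
                raise ValueError(f"{name} must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.kinase_activity)

    @classmethod
    def step(
        cls,
        n_frames: int,
        stim_start: int,
        stim_end: int,
        ca_window: tuple[int, int] | None = None,
        ca_amplitude: float = 3.0,
    ) -> "ActivityProtocol":
        """Square-pulse protocol: activity 1 in [stim_start, stim_end),
        0 elsewhere (washout after the pulse); optional Ca²⁺ elevation
        window at the given amplitude."""
        a = np.zeros(n_frames)
        a[stim_start:stim_end] = 1.0
        c = np.ones(n_frames)
        windows = [(stim_start, stim_end, "stimulation"), (stim_end, n_frames, "washout")]
        if ca_window is not None:
            c0, c1 = ca_window
            c[c0:c1] = ca_amplitude
            windows.append((c0, c1, "ca-elevation"))
        return cls(a, c, windows)


# ---------------------------------------------------------------------
# Droplet schedule (ground truth)
# ---------------------------------------------------------------------


@dataclass
class Droplet:
    """Ground-truth record of one condensate over the movie.

    Per-frame arrays are NaN outside the droplet's lifespan; ``death``
    is None while the droplet persists to the end.
    """

    id: int
    cell_id: int
    birth: int
    persistent: bool
    diameter_um: np.ndarray  # (n_frames,)
    y_um: np.ndarray
    x_um: np.ndarray
    death: int | None = None
    merged_into: int | None = None

    def alive_at(self, t: int) -> bool:
        return not math.isnan(self.diameter_um[t])


@dataclass
class DropletSchedule:
    """All droplets of a scene plus the frame count; exact ground truth."""

    droplets: list[Droplet]
    n_frames: int

    def counts_per_frame(self) -> np.ndarray:
        out = np.zeros(self.n_frames, dtype=int)
        for d in self.droplets:
            out += ~np.isnan(d.diameter_um)
        return out

    def alive(self, t: int, cell_id: int | None = None) -> list[Droplet]:
        return [
            d
            for d in self.droplets
            if d.alive_at(t) and (cell_id is None or d.cell_id == cell_id)
        ]

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per droplet per alive frame."""
        rows = []
        for d in self.droplets:
            for t in range(self.n_frames):
                if d.alive_at(t):
                    rows.append(
                        {
                            "droplet_id": d.id,
                            "cell": d.cell_id,
                            "frame": t,
                            "y_um": float(d.y_um[t]),
                            "x_um": float(d.x_um[t]),
                            "diameter_um": float(d.diameter_um[t]),
                            "persistent": d.persistent,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "droplet_id", "cell", "frame", "y_um", "x_um",
                "diameter_um", "persistent",
            ],
        )


def _sample_position(
    rng: np.random.Generator,
    cell: CellGeometry,
    margin_um: float,
) -> tuple[float, float]:
    """Uniform position inside the cell ellipse shrunk by ``margin_um``."""
    ry = max(cell.radii_um[0] - margin_um, 0.05)
    rx = max(cell.radii_um[1] - margin_um, 0.05)
    r = math.sqrt(rng.random())
    theta = rng.random() * 2 * math.pi
    return (
        cell.center_um[0] + ry * r * math.sin(theta),
        cell.center_um[1] + rx * r * math.cos(theta),
    )


def simulate_droplet_kinetics(
    protocol: ActivityProtocol,
    config: SceneConfig,
    nucleation_rate_per_min: float = 4.0,
    growth_rate_um_per_min: float = 0.25,
    dissolve_rate_per_min: float = 3.0,
    persistent_fraction: float = 0.0,
    initial_diameter_um: float = 0.8,
    exclusion_margin_um: float = 0.6,
    coalesce: bool = True,
) -> DropletSchedule:
    """Simulate condensate birth/growth/merge/death under an activity trace.

    Per frame (interval dt minutes), in order: alive droplets grow by
    ``growth_rate * a(t) * dt`` in diameter; overlapping droplets in the
    same cell merge (volume-conserving diameter, volume-weighted
    center); non-persistent droplets dissolve with hazard
    ``1 - exp(-dissolve_rate * (1 - a(t)) * dt)``; new droplets nucleate
    as Poisson(``nucleation_rate * a(t) * dt``) per cell at uniform
    positions outside the depletion zones of existing droplets. Each
    nucleus is persistent with probability ``persistent_fraction``.

    Deterministic given ``config.rng_seed``.
    """
    for v in (nucleation_rate_per_min, growth_rate_um_per_min, dissolve_rate_per_min):
        if v < 0:
            raise ValueError("rates must be non-negative")
    if not 0 <= persistent_fraction <= 1:
        raise ValueError("persistent_fraction must be in [0, 1]")
    # validate placeability up-front
    for i in range(len(config.cells)):
        cell_mask(config, i)

    rng = np.random.default_rng([config.rng_seed, 1])
    n_frames = protocol.n_frames
    dt_min = config.frame_interval_s / 60.0
    droplets: list[Droplet] = []
    alive: list[Droplet] = []
    next_id = 0

    for t in range(n_frames):
        a = float(protocol.kinase_activity[t])

        # 1. growth
        if t > 0:
            for d in alive:
                d.diameter_um[t] = d.diameter_um[t - 1] + growth_rate_um_per_min * a * dt_min
                d.y_um[t] = d.y_um[t - 1]
                d.x_um[t] = d.x_um[t - 1]

        # 2. coalescence: merge overlapping discs, smaller into larger
        if coalesce:
            merged = True
            while merged:
                merged = False
                alive_sorted = sorted(
                    alive, key=lambda d: (-d.diameter_um[t], d.id)
                )
                for i_big in range(len(alive_sorted)):
                    big = alive_sorted[i_big]
                    for small in alive_sorted[i_big + 1 :]:
                        if small.cell_id != big.cell_id:
                            continue
                        dist = math.hypot(
                            big.y_um[t] - small.y_um[t],
                            big.x_um[t] - small.x_um[t],
                        )
                        if dist < (big.diameter_um[t] + small.diameter_um[t]) / 2.0:
                            v1 = big.diameter_um[t] ** 3
                            v2 = small.diameter_um[t] ** 3
                            big.diameter_um[t] = (v1 + v2) ** (1.0 / 3.0)
                            big.y_um[t] = (v1 * big.y_um[t] + v2 * small.y_um[t]) / (v1 + v2)
                            big.x_um[t] = (v1 * big.x_um[t] + v2 * small.x_um[t]) / (v1 + v2)
                            big.persistent = big.persistent or small.persistent
                            small.diameter_um[t] = np.nan
                            small.y_um[t] = np.nan
                            small.x_um[t] = np.nan
                            small.death = t
                            small.merged_into = big.id
                            alive.remove(small)
                            merged = True
                            break
                    if merged:
                        break

        # 3. dissolution
        hazard = dissolve_rate_per_min * (1.0 - a) * dt_min
        if hazard > 0:
            p_die = 1.0 - math.exp(-hazard)
            for d in list(alive):
                if not d.persistent and rng.random() < p_die:
                    d.diameter_um[t] = np.nan
                    d.y_um[t] = np.nan
                    d.x_um[t] = np.nan
                    d.death = t
                    alive.remove(d)

        # 4. nucleation
        lam = nucleation_rate_per_min * a * dt_min
        for ci, cell in enumerate(config.cells):
            n_new = rng.poisson(lam) if lam > 0 else 0
            for _ in range(n_new):
                placed = None
                for _attempt in range(30):
                    y, x = _sample_position(rng, cell, initial_diameter_um / 2 + 0.2)
                    ok = True
                    for d in alive:
                        if d.cell_id != ci:
                            continue
                        min_dist = (
                            (d.diameter_um[t] + initial_diameter_um) / 2.0
                            + exclusion_margin_um
                        )
                        if math.hypot(d.y_um[t] - y, d.x_um[t] - x) < min_dist:
                            ok = False
                            break
                    if ok:
                        placed = (y, x)
                        break
                if placed is None:
                    continue  # cell too crowded; nucleation suppressed
                diam = np.full(n_frames, np.nan)
                ys = np.full(n_frames, np.nan)
                xs = np.full(n_frames, np.nan)
                diam[t] = initial_diameter_um
                ys[t], xs[t] = placed
                new = Droplet(
                    id=next_id,
                    cell_id=ci,
                    birth=t,
                    persistent=bool(rng.random() < persistent_fraction),
                    diameter_um=diam,
                    y_um=ys,
                    x_um=xs,
                )
                next_id += 1
                droplets.append(new)
                alive.append(new)

    return DropletSchedule(droplets=droplets, n_frames=n_frames)


# ---------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------


def _add_gaussian_2d(
    img: np.ndarray, y_px: float, x_px: float, sigma_px: float, integral: float
) -> None:
    """Add a discretely normalized Gaussian blob (in-place).

    Normalized over its in-image window so the blob contributes exactly
    ``integral`` counts — conservation before noise is exact.
    """
    ny, nx = img.shape
    half = max(int(math.ceil(5 * sigma_px)), 2)
    y0, y1 = int(math.floor(y_px)) - half, int(math.floor(y_px)) + half + 1
    x0, x1 = int(math.floor(x_px)) - half, int(math.floor(x_px)) + half + 1
    y0, y1 = max(y0, 0), min(y1, ny)
    x0, x1 = max(x0, 0), min(x1, nx)
    if y0 >= y1 or x0 >= x1:
        raise ValueError("droplet center outside the image")
    yy = np.arange(y0, y1) + 0.5
    xx = np.arange(x0, x1) + 0.5
    gy = np.exp(-0.5 * ((yy - y_px) / sigma_px) ** 2)
    gx = np.exp(-0.5 * ((xx - x_px) / sigma_px) ** 2)
    kernel = np.outer(gy, gx)
    img[y0:y1, x0:x1] += kernel * (integral / kernel.sum())


def _droplet_brightness(
    diameter_um: float, expression: float, config: SceneConfig
) -> float:
    """Integrated blob counts for one condensate: enrichment x expression
    x condensate volume, in pixel-count units (an optical-section depth
    converts the volumetric concentration to 2D counts)."""
    vol = math.pi / 6.0 * diameter_um**3
    return (
        expression
        * config.enrichment
        * vol
        / (config.pixel_size_um**2 * config.section_depth_um)
    )


def _apply_noise(img: np.ndarray, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    noise = config.noise
    out = img
    if noise.poisson_gain > 0:
        out = rng.poisson(out * noise.poisson_gain) / noise.poisson_gain
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


@dataclass
class MovieRender:
    """Rendered movie plus ground-truth tables."""

    stack: ImageStack
    droplet_table: pd.DataFrame  # per droplet per frame
    count_table: pd.DataFrame  # per frame: truth count, a(t), c(t)


def render_movie(
    schedule: DropletSchedule,
    protocol: ActivityProtocol,
    config: SceneConfig,
    gcamp_mode: bool = False,
) -> MovieRender:
    """Render a time-lapse movie from a droplet schedule.

    Each frame is the camera offset plus, per cell, a diffuse cytosolic
    pool and Gaussian condensate blobs whose integrated brightness is
    drawn from that pool (total reporter flux per cell is constant
    before noise, so the cytosol visibly dims as condensates grow). In
    ``gcamp_mode`` all reporter-derived intensity is multiplied by the
    protocol's Ca²⁺ trace ``c(t)``. Poisson then Gaussian noise last.
    """
    if schedule.n_frames != protocol.n_frames:
        raise ValueError("schedule and protocol disagree on frame count")
    ny, nx = config.image_shape
    px = config.pixel_size_um
    masks = [cell_mask(config, i) for i in range(len(config.cells))]
    areas = [int(m.sum()) for m in masks]
    rng = np.random.default_rng([config.rng_seed, 2])

    frames = np.empty((schedule.n_frames, ny, nx))
    for t in range(schedule.n_frames):
        img = np.zeros((ny, nx))
        c = float(protocol.ca_level[t]) if gcamp_mode else 1.0
        for ci, (mask, area) in enumerate(zip(masks, areas)):
            E = config.expression_levels[ci]
            budget = E * area
            alive = schedule.alive(t, cell_id=ci)
            bright = [
                _droplet_brightness(d.diameter_um[t], E, config) for d in alive
            ]
            total_b = sum(bright)
            cap = 0.9 * budget
            if total_b > cap:  # pool nearly exhausted: ration it
                scale = cap / total_b
                bright = [b * scale for b in bright]
                total_b = cap
            diffuse = (budget - total_b) / area
            cell_img = np.zeros((ny, nx))
            cell_img[mask] = diffuse
            for d, b in zip(alive, bright):
                sigma_um = math.sqrt(
                    (d.diameter_um[t] / 4.0) ** 2 + config.psf_sigma_um**2
                )
                _add_gaussian_2d(
                    cell_img,
                    d.y_um[t] / px,
                    d.x_um[t] / px,
                    sigma_um / px,
                    b,
                )
            img += cell_img * c
        img += config.noise.offset
        frames[t] = _apply_noise(img, config, rng)

    stack = ImageStack(
        data=frames,
        axes="TYX",
        pixel_size_um=px,
        frame_interval_s=config.frame_interval_s,
    )
    counts = schedule.counts_per_frame()
    count_table = pd.DataFrame(
        {
            "frame": np.arange(schedule.n_frames),
            "time_s": np.arange(schedule.n_frames) * config.frame_interval_s,
            "true_count": counts,
            "kinase_activity": protocol.kinase_activity,
            "ca_level": protocol.ca_level,
        }
    )
    return MovieRender(stack, schedule.to_dataframe(), count_table)


# ---------------------------------------------------------------------
# Z-stack rendering
# ---------------------------------------------------------------------


@dataclass
class Droplet3D:
    """A static condensate for volumetric scenes (center in µm)."""

    z_um: float
    y_um: float
    x_um: float
    diameter_um: float
    cell_id: int = 0


def _add_sphere_3d(
    vol: np.ndarray,
    center_px: tuple[float, float, float],  # (z, y, x) in voxel units
    radius_um: float,
    edge_sigma_um: float,
    voxel_dims_um: tuple[float, float, float],
    integral: float,
) -> None:
    """Add a uniform-density sphere with a PSF-softened edge (in place).

    The radial profile is ``erfc((r - R) / (sqrt(2) sigma)) / 2`` — a
    solid droplet convolved with a Gaussian PSF of width sigma along the
    radial direction. Discretely normalized over its in-image window so
    it contributes exactly ``integral`` counts.
    """
    from scipy.special import erfc

    nz, ny, nx = vol.shape
    dims = np.asarray(voxel_dims_um, dtype=float)
    halves = np.ceil((radius_um + 5 * edge_sigma_um) / dims).astype(int) + 1
    c = np.asarray(center_px, dtype=float)
    lo = np.maximum(np.floor(c).astype(int) - halves, 0)
    hi = np.minimum(np.floor(c).astype(int) + halves + 1, [nz, ny, nx])
    if (lo >= hi).any():
        raise ValueError("droplet center outside the stack")
    zz = (np.arange(lo[0], hi[0]) + 0.5 - c[0]) * dims[0]
    yy = (np.arange(lo[1], hi[1]) + 0.5 - c[1]) * dims[1]
    xx = (np.arange(lo[2], hi[2]) + 0.5 - c[2]) * dims[2]
    r = np.sqrt(
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )
    sigma = max(edge_sigma_um, 1e-6)
    kernel = 0.5 * erfc((r - radius_um) / (math.sqrt(2.0) * sigma))
    vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += kernel * (
        integral / kernel.sum()
    )


def cell_mask_3d(config: SceneConfig, cell_index: int) -> np.ndarray:
    """Ellipsoid voxel mask of one cell, centered mid-stack in z."""
    ny, nx = config.image_shape
    nz = config.n_z
    cell = config.cells[cell_index]
    px, dz = config.pixel_size_um, config.z_step_um
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx]
    z_um = (zz + 0.5) * dz
    y_um = (yy + 0.5) * px
    x_um = (xx + 0.5) * px
    cz = nz * dz / 2.0
    cy, cx = cell.center_um
    ry, rx = cell.radii_um
    mask = (
        ((z_um - cz) / cell.z_radius_um) ** 2
        + ((y_um - cy) / ry) ** 2
        + ((x_um - cx) / rx) ** 2
        <= 1.0
    )
    if not mask.any():
        raise ValueError(f"cell {cell_index} has an empty voxel mask")
    return mask


def render_zstack(
    droplets: Sequence[Droplet3D], config: SceneConfig
) -> ImageStack:
    """Render a confocal z-stack of condensates.

    As :func:`render_movie` but volumetric: anisotropic voxels, an
    ellipsoidal diffuse cytosol per cell, and per-cell flux conservation
    before noise. Condensates are uniform-density spheres with a
    PSF-softened (erfc) edge — the physically appropriate forward model
    for a solid droplet imaged through Gaussian optics, and the one that
    keeps thresholded volumes close to the true sphere volume.
    """
    if config.n_z < 2:
        raise ValueError("render_zstack requires n_z >= 2")
    nz = config.n_z
    ny, nx = config.image_shape
    px, dz = config.pixel_size_um, config.z_step_um
    voxel_vol = dz * px * px
    rng = np.random.default_rng([config.rng_seed, 3])

    vol = np.zeros((nz, ny, nx))
    masks = [cell_mask_3d(config, i) for i in range(len(config.cells))]
    for ci, mask in enumerate(masks):
        E = config.expression_levels[ci]
        n_vox = int(mask.sum())
        budget = E * n_vox
        mine = [d for d in droplets if d.cell_id == ci]
        bright = [
            E * config.enrichment * (math.pi / 6.0 * d.diameter_um**3) / voxel_vol
            for d in mine
        ]
        total_b = sum(bright)
        cap = 0.9 * budget
        if total_b > cap:
            bright = [b * cap / total_b for b in bright]
            total_b = cap
        cell_vol = np.zeros_like(vol)
        cell_vol[mask] = (budget - total_b) / n_vox
        for d, b in zip(mine, bright):
            _add_sphere_3d(
                cell_vol,
                (d.z_um / dz, d.y_um / px, d.x_um / px),
                d.diameter_um / 2.0,
                config.psf_sigma_um,
                (dz, px, px),
                b,
            )
        vol += cell_vol
    vol += config.noise.offset
    vol = _apply_noise(vol, config, rng)
    return ImageStack(
        data=vol, axes="ZYX", pixel_size_um=px, z_step_um=dz
    )
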