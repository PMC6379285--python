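"""Digital nodule phantoms with exactly known ground-truth volume.

This module replaces a physical Agar-nodule phantom and the scanners that
imaged it.  Each phantom is a textured background (smoothed white noise
standing in for packing foam / lung parenchyma) into which spherical or
hemispherical nodules of analytically known volume are rasterized with
sub-voxel (supersampled) partial-volume fractions.  The composed image is
degraded with a Gaussian point-spread blur and modality noise (Rician for
MRI magnitude images, Gaussian for CT).

Two arm presets emulate the study conditions: an MRI-like arm at
(0.98 mm)^3 isotropic voxels and a CT-like arm at 0.7 x 0.7 x 1.25 mm
anisotropic voxels (1.25 mm slices).  Nodules span 16-561 mm^3; the default
study set has 22 nodules of which 4 fall below the 50 mm^3 analysis cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import VolumetricImage

__all__ = [
    "NoduleSpec",
    "PhantomSpec",
    "sample_nodule_volumes",
    "sample_study_volumes",
    "nodule_radius",
    "rasterize_nodule",
    "compose_phantom",
    "mri_phantom_spec",
    "ct_phantom_spec",
    "write_phantom",
    "GROUND_TRUTH_COLUMNS",
]

GROUND_TRUTH_COLUMNS = ["id", "volume_mm3", "cx_mm", "cy_mm", "cz_mm", "shape", "seed"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def nodule_radius(volume: float, shape: str) -> float:
    """Radius (mm) of a sphere or hemisphere of the given volume (mm^3)."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    if shape == "sphere":
        return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    if shape == "hemisphere":
        return (3.0 * volume / (2.0 * math.pi)) ** (1.0 / 3.0)
    raise ValueError(f"unknown nodule shape {shape!r}")


@dataclass
class NoduleSpec:
    """One synthetic nodule: identity, placement, true volume, shape.

    The true volume is exact by construction — it plays the role of a
    mass-derived volume from precision weighing.
    """

    id: str
    center: tuple[float, float, float]  # mm, world coordinates
    volume_true: float  # mm^3
    shape: str = "hemisphere"  # {"sphere", "hemisphere"}

    def __post_init__(self) -> None:
        if self.volume_true <= 0:
            raise ValueError(f"volume_true must be positive, got {self.volume_true}")
        if self.shape not in ("sphere", "hemisphere"):
            raise ValueError(f"unknown nodule shape {self.shape!r}")
        self.center = tuple(float(c) for c in self.center)

    @property
    def radius(self) -> float:
        return nodule_radius(self.volume_true, self.shape)


@dataclass
class PhantomSpec:
    """Full description of one phantom image.

    ``nodule_signal`` is the plateau intensity of a fully occupied nodule
    voxel (arbitrary units for the MRI arm, HU for the CT arm);
    ``background_mean`` is the mean of the textured background field.
    ``background_clip`` floors the background field (0 for MRI magnitude
    images; ``None`` for the CT arm, where air sits at -1000 HU).
    """

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    nodules: list[NoduleSpec] = field(default_factory=list)
    nodule_signal: float = 100.0
    background_mean: float = 0.0
    background_texture_sd: float = 0.0
    texture_correlation_mm: float = 3.0
    blur_fwhm: float = 0.0  # mm
    noise_model: str = "gaussian"  # {"rician", "gaussian"}
    noise_sd: float = 0.0
    seed: int = 0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    supersample: int = 4
    background_clip: float | None = 0.0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(n < 1 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.blur_fwhm < 0:
            raise ValueError("blur_fwhm must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.nodule_signal <= self.background_mean:
            raise ValueError("nodule_signal must exceed background_mean")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")


def sample_nodule_volumes(
    n: int, v_min: float, v_max: float, seed: int
) -> np.ndarray:
    """Draw ``n`` nodule volumes (mm^3) spanning ``[v_min, v_max]``.

    Volumes are log-uniform between the bounds, which covers the decades of
    the clinically relevant range evenly.  The bounds themselves are always
    included (first two entries) so the nominal range is spanned exactly.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0 < v_min < v_max):
        raise ValueError(f"need 0 < v_min < v_max, got ({v_min}, {v_max})")
    rng = np.random.default_rng(seed)
    out = np.empty(n, dtype=float)
    out[0] = v_min
    if n > 1:
        out[1] = v_max
    if n > 2:
        out[2:] = np.exp(rng.uniform(math.log(v_min), math.log(v_max), size=n - 2))
    return out


def sample_study_volumes(
    n: int = 22,
    v_min: float = 16.0,
    v_max: float = 561.0,
    cutoff: float = 50.0,
    n_below: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Stratified study set: exactly ``n_below`` volumes below ``cutoff``.

    The default reproduces the study conditions: 22 nodules between 16 and
    561 mm^3 of which 4 fall under the 50 mm^3 minimum-volume filter,
    independent of the seed.  Endpoints are forced as in
    :func:`sample_nodule_volumes`.
    """
    if not (0 < v_min < cutoff < v_max):
        raise ValueError("need 0 < v_min < cutoff < v_max")
    if not (1 <= n_below < n):
        raise ValueError("need 1 <= n_below < n")
    rng = np.random.default_rng(seed)
    lo_extra = np.exp(
        rng.uniform(math.log(v_min), math.log(cutoff), size=n_below - 1)
    )
    # keep strictly below the cutoff (the filter keeps exactly `cutoff`)
    lo_extra = np.minimum(lo_extra, np.nextafter(cutoff, 0.0))
    hi_extra = np.exp(
        rng.uniform(math.log(cutoff), math.log(v_max), size=n - n_below - 1)
    )
    return np.concatenate([[v_min, v_max], lo_extra, hi_extra])


def _fits_in_grid(
    spec: NoduleSpec,
    grid_shape: tuple[int, ...],
    spacing: tuple[float, ...],
    origin: tuple[float, ...],
) -> None:
    lo = np.asarray(origin) - np.asarray(spacing) / 2.0
    hi = lo + np.asarray(grid_shape) * np.asarray(spacing)
    c = np.asarray(spec.center)
    r = spec.radius
    if np.any(c - r < lo) or np.any(c + r > hi):
        raise ValueError(
            f"nodule {spec.id!r} (center {spec.center}, radius {r:.2f} mm) "
            f"extends outside the grid extent [{lo}, {hi}]"
        )


def rasterize_nodule(
    spec: NoduleSpec,
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    supersample: int = 4,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Per-voxel inside-fraction in [0, 1] of the analytic nodule shape.

    Each voxel near the nodule is subdivided into ``supersample**3`` sample
    points; the occupancy is the fraction of points inside the shape, so
    ``occupancy.sum() * voxel_volume`` converges to the analytic volume as
    ``supersample`` grows.  Hemispheres sit flat-face-down on the axial
    plane through the centre, dome toward +z.
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    _fits_in_grid(spec, grid_shape, spacing, origin)

    sp = np.asarray(spacing, dtype=float)
    org = np.asarray(origin, dtype=float)
    c = np.asarray(spec.center, dtype=float)
    r = spec.radius

    # bounding box of voxels that can intersect the shape
    lo_idx = np.maximum(np.floor((c - r - org) / sp - 0.5).astype(int), 0)
    hi_idx = np.minimum(
        np.ceil((c + r - org) / sp + 0.5).astype(int), np.asarray(grid_shape) - 1
    )

    s = supersample
    # sub-voxel offsets at the centres of an s^3 partition of the voxel
    off = (np.arange(s) + 0.5) / s - 0.5  # in voxel units
    axes_pts = [
        org[a] + (np.arange(lo_idx[a], hi_idx[a] + 1)[:, None] + off[None, :]) * sp[a]
        for a in range(3)
    ]  # each (n_vox, s): world coords of sample points along that axis

    dx = (axes_pts[0] - c[0])[:, None, None, :, None, None]
    dy = (axes_pts[1] - c[1])[None, :, None, None, :, None]
    dz1 = axes_pts[2] - c[2]  # (nz, s)
    dz = dz1[None, None, :, None, None, :]

    dist = np.sqrt(dx**2 + dy**2 + dz**2)
    if s == 1:
        # binary point-test rasterization: occupancy is an indicator
        inside = (dist <= r).astype(float)
        if spec.shape == "hemisphere":
            inside *= (dz >= 0.0).astype(float)
    else:
        # antialiased sub-cells: approximate each sub-cell's inside fraction
        # by linearly resolving the surface plane across the cell, which
        # removes the O(1/supersample) point-sampling error at the boundary
        h = sp / s
        with np.errstate(invalid="ignore", divide="ignore"):
            n_hat = np.abs(np.stack([dx / dist, dy / dist, dz / dist], axis=0))
        ell = np.where(
            dist > 0, (n_hat * h.reshape(3, 1, 1, 1, 1, 1, 1)).sum(axis=0), h.max()
        )
        # curvature correction: the linear ramp overestimates convex bodies
        # by ell^2 * (k1 + k2) / 24 per unit area; shift the surface inward
        inside = np.clip(0.5 - (dist - r + ell**2 / (12.0 * r)) / ell, 0.0, 1.0)
        if spec.shape == "hemisphere":
            # exact sub-cell fraction above the flat face (dome toward +z)
            inside *= np.clip((dz + h[2] / 2.0) / h[2], 0.0, 1.0)

    frac = inside.mean(axis=(3, 4, 5))
    occ = np.zeros(grid_shape, dtype=float)
    occ[
        lo_idx[0] : hi_idx[0] + 1,
        lo_idx[1] : hi_idx[1] + 1,
        lo_idx[2] : hi_idx[2] + 1,
    ] = frac
    return occ


def _background_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Textured background: smoothed white noise rescaled to the target sd."""
    field_ = np.full(spec.grid_shape, float(spec.background_mean))
    if spec.background_texture_sd > 0:
        white = rng.standard_normal(spec.grid_shape)
        sigma_vox = [
            spec.texture_correlation_mm / s if spec.texture_correlation_mm > 0 else 0.0
            for s in spec.spacing
        ]
        tex = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
        sd = tex.std()
        if sd > 0:
            tex *= spec.background_texture_sd / sd
        field_ += tex
    if spec.background_clip is not None:
        np.clip(field_, spec.background_clip, None, out=field_)
    return field_


def compose_phantom(spec: PhantomSpec) -> tuple[VolumetricImage, pd.DataFrame]:
    """Compose the phantom image and its ground-truth table.

    Pipeline: rasterize nodules -> add contrast ``(nodule_signal -
    background_mean) * occupancy`` on top of the textured background ->
    Gaussian blur of the stated FWHM -> modality noise.  A fixed seed gives
    a bit-identical image.
    """
    rng = np.random.default_rng(spec.seed)

    occupancy = np.zeros(spec.grid_shape, dtype=float)
    rows = []
    for nod in spec.nodules:
        occ = rasterize_nodule(
            nod, spec.grid_shape, spec.spacing, spec.supersample, spec.origin
        )
        occupancy += occ
        rows.append(
            {
                "id": nod.id,
                "volume_mm3": nod.volume_true,
                "cx_mm": nod.center[0],
                "cy_mm": nod.center[1],
                "cz_mm": nod.center[2],
                "shape": nod.shape,
                "seed": spec.seed,
            }
        )
    np.clip(occupancy, 0.0, 1.0, out=occupancy)

    img = _background_field(spec, rng)
    img += (spec.nodule_signal - spec.background_mean) * occupancy

    if spec.blur_fwhm > 0:
        sigma_vox = [spec.blur_fwhm * _FWHM_TO_SIGMA / s for s in spec.spacing]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")

    if spec.noise_sd > 0:
        if spec.noise_model == "rician":
            # magnitude of a complex signal with iid Gaussian channel noise
            re = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
            im = rng.normal(0.0, spec.noise_sd, size=img.shape)
            img = np.hypot(re, im)
        else:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    truth = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    return VolumetricImage(img, spec.spacing, spec.origin), truth


# --------------------------------------------------------------- arm presets


def mri_phantom_spec(nodules: list[NoduleSpec], seed: int = 0, **over) -> PhantomSpec:
    """MRI-like arm: (0.98 mm)^3 voxels, foam-like signal floor at 20% of
    the nodule plateau, 1.2 mm PSF, Rician magnitude noise."""
    params = dict(
        grid_shape=(96, 96, 96),
        spacing=(0.98, 0.98, 0.98),
        nodule_signal=100.0,
        background_mean=20.0,
        background_texture_sd=5.0,
        blur_fwhm=1.2,
        noise_model="rician",
        noise_sd=2.0,
        background_clip=0.0,
    )
    params.update(over)
    return PhantomSpec(nodules=nodules, seed=seed, **params)


def ct_phantom_spec(nodules: list[NoduleSpec], seed: int = 0, **over) -> PhantomSpec:
    """CT-like arm: 0.7 x 0.7 x 1.25 mm voxels, air background at -1000 HU,
    soft-tissue nodules at +20 HU, 1.5 mm axial-equivalent PSF, Gaussian noise."""
    params = dict(
        grid_shape=(134, 134, 76),
        spacing=(0.7, 0.7, 1.25),
        nodule_signal=20.0,
        background_mean=-1000.0,
        background_texture_sd=30.0,
        blur_fwhm=1.5,
        noise_model="gaussian",
        noise_sd=10.0,
        background_clip=None,
    )
    params.update(over)
    return PhantomSpec(nodules=nodules, seed=seed, **params)


def write_phantom(
    spec: PhantomSpec, out_dir: str | Path, stem: str = "phantom"
) -> tuple[Path, Path]:
    """Compose and write ``<stem>.nii.gz`` plus ``<stem>_truth.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image, truth = compose_phantom(spec)
    img_path = image.save(out_dir / f"{stem}.nii.gz")
    csv_path = out_dir / f"{stem}_truth.csv"
    truth.to_csv(csv_path, index=False)
    return img_path, csv_path
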