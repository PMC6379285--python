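"""Signal-intensity-threshold (SIT) segmentation inside a spherical ROI.

The SIT rule: place a sphere around the nodule containing the whole lesion
plus an air margin, record the intensity extremes ``I_min`` and ``I_max``
over the sphere, and keep every voxel with intensity between
``C * (I_max - I_min) + I_min`` and ``I_max`` (both bounds inclusive).
``C`` in [0, 1] tunes the lower bound: at C = 0 the whole ROI is selected,
and raising C discards progressively lower-intensity voxels, so masks are
nested (mask(C2) is a subset of mask(C1) whenever C1 <= C2).

ROI membership is decided by voxel-centre distance in world millimetres
(0-based indices), which is resolution-independent and unambiguous.

A simple HU-threshold segmenter (:func:`segment_ct_surrogate`) stands in
for a clinical semi-automatic CT lesion tool on the CT arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import VolumetricImage

__all__ = [
    "SphericalROI",
    "RoiExtremes",
    "NoduleMask",
    "EmptyMaskWarning",
    "BoundaryROIWarning",
    "roi_mask",
    "roi_voxels",
    "roi_extremes",
    "sit_lower_bound",
    "segment_sit",
    "segment_ct_surrogate",
    "keep_largest_component",
]

# 26-connectivity in 3D
_CONN26 = np.ones((3, 3, 3), dtype=int)


class EmptyMaskWarning(UserWarning):
    """A segmentation produced an empty mask (legal, but worth flagging)."""


class BoundaryROIWarning(UserWarning):
    """The ROI sphere extends past the image extent and was clipped; the
    air margin around the nodule may be incomplete."""


@dataclass(frozen=True)
class SphericalROI:
    """Sphere in world coordinates bounding one nodule plus an air margin."""

    center: tuple[float, float, float]  # mm
    radius: float  # mm

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"ROI radius must be positive, got {self.radius}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass(frozen=True)
class RoiExtremes:
    """Intensity extremes over an ROI."""

    i_min: float
    i_max: float

    def __post_init__(self) -> None:
        if self.i_min > self.i_max:
            raise ValueError(f"i_min={self.i_min} exceeds i_max={self.i_max}")


@dataclass
class NoduleMask:
    """Binary segmentation aligned to its source image grid."""

    member: np.ndarray  # bool, same shape as the source image
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.member.sum())

    def save(self, path) -> None:
        VolumetricImage(
            self.member.astype(np.uint8), self.spacing, self.origin
        ).save(path)


def _check_roi_inside(image: VolumetricImage, roi: SphericalROI) -> None:
    """Reject ROIs centred outside the image; warn when the sphere merely
    pokes past the extent (it is clipped to the grid)."""
    lo, hi = image.extent()
    c = np.asarray(roi.center)
    for axis, name in enumerate("xyz"):
        if c[axis] < lo[axis]:
            raise ValueError(
                f"ROI centre below the image {name}-extent: "
                f"{c[axis]:.3f} < {lo[axis]:.3f} mm"
            )
        if c[axis] > hi[axis]:
            raise ValueError(
                f"ROI centre above the image {name}-extent: "
                f"{c[axis]:.3f} > {hi[axis]:.3f} mm"
            )
    if np.any(c - roi.radius < lo) or np.any(c + roi.radius > hi):
        warnings.warn(
            f"ROI sphere (centre {roi.center}, radius {roi.radius:.2f} mm) "
            "touches the image boundary and was clipped",
            BoundaryROIWarning,
        )


def roi_mask(image: VolumetricImage, roi: SphericalROI) -> np.ndarray:
    """Boolean grid of voxels whose centres lie within the ROI sphere."""
    _check_roi_inside(image, roi)
    sp = np.asarray(image.spacing)
    org = np.asarray(image.origin)
    c = np.asarray(roi.center)
    coords = [
        (org[a] + np.arange(image.shape[a]) * sp[a] - c[a]) ** 2 for a in range(3)
    ]
    d2 = (
        coords[0][:, None, None]
        + coords[1][None, :, None]
        + coords[2][None, None, :]
    )
    return d2 <= roi.radius**2


def roi_voxels(image: VolumetricImage, roi: SphericalROI) -> np.ndarray:
    """Indices ``(n, 3)`` of voxels whose centres fall inside the ROI."""
    return np.argwhere(roi_mask(image, roi))


def roi_extremes(image: VolumetricImage, roi: SphericalROI) -> RoiExtremes:
    """Exact minimum and maximum intensity over the ROI voxels."""
    sel = roi_mask(image, roi)
    if not sel.any():
        raise ValueError("ROI contains no voxel centres")
    vals = image.data[sel]
    return RoiExtremes(float(vals.min()), float(vals.max()))


def sit_lower_bound(extremes: RoiExtremes, c: float) -> float:
    """Lower inclusion bound ``C * (I_max - I_min) + I_min``."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"threshold fraction C must be in [0, 1], got {c}")
    return c * (extremes.i_max - extremes.i_min) + extremes.i_min


def keep_largest_component(member: np.ndarray) -> np.ndarray:
    """Largest 26-connected component; ties broken by the component whose
    first voxel (lexicographic index order) comes first."""
    labels, n = ndimage.label(member, structure=_CONN26)
    if n <= 1:
        return member.copy()
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) == 1:
        keep = tied[0]
    else:
        # labels are assigned in raster order, so the smallest tied label
        # has the lexicographically smallest seed voxel
        keep = tied.min()
    return labels == keep


def segment_sit(
    image: VolumetricImage,
    roi: SphericalROI,
    c: float,
    keep_largest: bool = False,
) -> NoduleMask:
    """SIT segmentation: ROI voxels with intensity in
    ``[C*(I_max - I_min) + I_min, I_max]`` (inclusive bounds).

    An empty result is legal and returned with an :class:`EmptyMaskWarning`.
    """
    sel = roi_mask(image, roi)
    if not sel.any():
        raise ValueError("ROI contains no voxel centres")
    vals = image.data[sel]
    ext = RoiExtremes(float(vals.min()), float(vals.max()))
    bound = sit_lower_bound(ext, c)
    member = sel & (image.data >= bound) & (image.data <= ext.i_max)
    if keep_largest and member.any():
        member = keep_largest_component(member)
    if not member.any():
        warnings.warn("SIT segmentation produced an empty mask", EmptyMaskWarning)
    return NoduleMask(member, image.spacing, image.origin)


def segment_ct_surrogate(
    image: VolumetricImage,
    roi: SphericalROI,
    hu_cut: float = -400.0,
) -> NoduleMask:
    """CT-arm segmenter: ROI voxels at or above ``hu_cut`` (HU), reduced to
    the largest 26-connected component."""
    sel = roi_mask(image, roi)
    if not sel.any():
        raise ValueError("ROI contains no voxel centres")
    member = sel & (image.data >= hu_cut)
    if member.any():
        member = keep_largest_component(member)
    else:
        warnings.warn(
            "CT surrogate segmentation produced an empty mask", EmptyMaskWarning
        )
    return NoduleMask(member, image.spacing, image.origin)
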