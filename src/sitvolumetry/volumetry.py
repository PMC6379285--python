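"""Clinical volumetry metrics derived from nodule masks and volume pairs.

Volume is voxel-count times voxel volume.  Two size summaries are provided:
the sphere-equivalent diameter ``(6 V / pi)^(1/3)`` (unambiguous,
volume-derived) and the clinical average diameter — the mean of the long
axis (maximal Feret diameter) and the perpendicular short axis, measured on
the axial slice of largest cross-section, mirroring caliper practice.

Follow-up semantics use the screening-trial conventions: growth is a volume
increase of at least 25% between scans, and a volume doubling time (VDT)
below 400 days is the malignancy cut-off.  VDT = dt * ln 2 / ln(V2/V1);
it is negative for shrinking nodules and undefined for unchanged ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .segmentation import NoduleMask

__all__ = [
    "NoduleMeasurement",
    "VolumePair",
    "UndefinedDoublingTimeError",
    "mask_volume",
    "equivalent_diameter",
    "average_diameter",
    "percent_difference",
    "round_percent",
    "assess_growth",
    "volume_doubling_time",
    "filter_min_volume",
    "GROWTH_THRESHOLD_PCT",
    "VDT_MALIGNANCY_DAYS",
    "MIN_ANALYSIS_VOLUME_MM3",
]

GROWTH_THRESHOLD_PCT = 25.0
VDT_MALIGNANCY_DAYS = 400.0
MIN_ANALYSIS_VOLUME_MM3 = 50.0


class UndefinedDoublingTimeError(ValueError):
    """Raised when V2 == V1, where the doubling time is undefined."""


@dataclass
class NoduleMeasurement:
    """One nodule's size measurements under one method."""

    id: str
    volume: float  # mm^3
    equivalent_diameter: float  # mm
    average_diameter: float  # mm
    method: str  # {"sit_mri", "ct_surrogate", "external"}

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("volume must be >= 0")
        if (self.volume == 0) != (self.equivalent_diameter == 0):
            raise ValueError("equivalent diameter must vanish iff volume does")


@dataclass(frozen=True)
class VolumePair:
    """Baseline/follow-up volumes (mm^3) and the scan interval (days)."""

    v_baseline: float
    v_followup: float
    interval: float = 0.0

    def __post_init__(self) -> None:
        if self.v_baseline <= 0 or self.v_followup <= 0:
            raise ValueError("volumes must be positive")


def mask_volume(
    mask: NoduleMask | np.ndarray, spacing: Sequence[float] | None = None
) -> float:
    """Mask volume in mm^3: member-voxel count times voxel volume."""
    if isinstance(mask, NoduleMask):
        member, sp = mask.member, mask.spacing
    else:
        member = np.asarray(mask, dtype=bool)
        if spacing is None:
            raise ValueError("spacing is required for a bare array mask")
        sp = spacing
    return float(member.sum()) * float(np.prod(np.asarray(sp, dtype=float)))


def equivalent_diameter(volume: float) -> float:
    """Diameter (mm) of the sphere with the given volume (mm^3)."""
    if volume < 0:
        raise ValueError(f"volume must be >= 0, got {volume}")
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)


def _feret_axes(points: np.ndarray) -> tuple[float, float]:
    """Long axis (max Feret) and perpendicular short axis over 2D points."""
    n = len(points)
    if n == 1:
        return 0.0, 0.0
    diff = points[:, None, :] - points[None, :, :]
    d2 = (diff**2).sum(axis=2)
    i, j = np.unravel_index(int(d2.argmax()), d2.shape)
    long_axis = math.sqrt(d2[i, j])
    u = points[j] - points[i]
    norm = np.linalg.norm(u)
    if norm == 0:
        return 0.0, 0.0
    perp = np.array([-u[1], u[0]]) / norm
    proj = points @ perp
    return long_axis, float(proj.max() - proj.min())


def average_diameter(
    mask: NoduleMask | np.ndarray,
    spacing: Sequence[float] | None = None,
    axis: int = 2,
) -> float:
    """Mean of long and short axes on the slice of maximal area (mm).

    The slice plane is perpendicular to ``axis`` (default: axial, i.e. the
    z-axis).  Axes are measured over voxel-centre coordinates plus the mean
    in-plane spacing, accounting for the half-voxel footprint on each side;
    a single-voxel mask therefore measures the mean of the in-plane
    spacings.
    """
    if isinstance(mask, NoduleMask):
        member, sp = mask.member, np.asarray(mask.spacing)
    else:
        member = np.asarray(mask, dtype=bool)
        if spacing is None:
            raise ValueError("spacing is required for a bare array mask")
        sp = np.asarray(spacing, dtype=float)
    if not member.any():
        raise ValueError("cannot measure an empty mask")

    in_plane = [a for a in range(3) if a != axis]
    counts = member.sum(axis=tuple(in_plane))
    k = int(counts.argmax())
    sl = np.take(member, k, axis=axis)
    idx = np.argwhere(sl).astype(float)
    pts = idx * sp[in_plane]

    long_axis, short_axis = _feret_axes(pts)
    pad = float(sp[in_plane].mean())
    return ((long_axis + pad) + (short_axis + pad)) / 2.0


def percent_difference(v_test: float, v_ref: float) -> float:
    """Percent difference ``100 * (v_test - v_ref) / v_ref``."""
    if v_ref <= 0:
        raise ValueError(f"reference volume must be positive, got {v_ref}")
    return 100.0 * (v_test - v_ref) / v_ref


def round_percent(pct: float) -> int:
    """Round half away from zero to an integer percent (reporting layer)."""
    return int(math.floor(abs(pct) + 0.5) * (1 if pct >= 0 else -1))


def assess_growth(pair: VolumePair) -> bool:
    """Growth call: volume increase of at least 25% between two scans."""
    return percent_difference(pair.v_followup, pair.v_baseline) >= GROWTH_THRESHOLD_PCT


def volume_doubling_time(pair: VolumePair) -> float:
    """VDT in days: ``interval * ln 2 / ln(V2 / V1)``.

    Negative for shrinking nodules.  Raises
    :class:`UndefinedDoublingTimeError` when the volumes are equal.
    """
    if pair.interval <= 0:
        raise ValueError("interval must be positive for a doubling time")
    if pair.v_followup == pair.v_baseline:
        raise UndefinedDoublingTimeError(
            "doubling time is undefined for unchanged volume"
        )
    return pair.interval * math.log(2.0) / math.log(pair.v_followup / pair.v_baseline)


def filter_min_volume(
    records: Iterable, min_volume: float = MIN_ANALYSIS_VOLUME_MM3, key=None
):
    """Keep records with true volume >= ``min_volume`` (boundary kept).

    Mirrors the screening convention of not following nodules below
    50 mm^3.  ``key`` extracts the volume from a record (default: the
    record's ``volume_true`` attribute, falling back to the record itself).

    Returns ``(kept, n_excluded)``.
    """
    if key is None:
        key = lambda r: getattr(r, "volume_true", r)
    records = list(records)
    kept = [r for r in records if key(r) >= min_volume]
    return kept, len(records) - len(kept)
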