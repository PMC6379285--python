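"""End-to-end phantom study and single-case volumetry.

:func:`run_phantom_experiment` replays the full method-comparison study on
synthetic data: manufacture nodules of known volume, image them in an
MRI-like and a CT-like arm, drop nodules under the 50 mm^3 analysis cutoff,
segment the MRI arm with the SIT rule at each threshold C in the grid and
the CT arm with the HU-cut surrogate, calibrate C by Lin concordance
against the true volumes, and report concordance + Bland-Altman agreement
for MRI-vs-truth and MRI-vs-CT.  The whole run is deterministic for a fixed
seed, down to the serialized report bytes.

:func:`run_single_case` measures one nodule on one image (the in-vivo
workflow): SIT segmentation at the calibrated C (default 0.30), volume and
diameters, and the percent difference against a reference volume when one
is given.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import DEFAULT_C_GRID, MethodAgreement, lin_ccc
from .image import VolumetricImage
from .phantom import (
    NoduleSpec,
    compose_phantom,
    ct_phantom_spec,
    mri_phantom_spec,
    nodule_radius,
    sample_study_volumes,
)
from .segmentation import SphericalROI, segment_ct_surrogate, segment_sit
from .volumetry import (
    MIN_ANALYSIS_VOLUME_MM3,
    NoduleMeasurement,
    average_diameter,
    equivalent_diameter,
    mask_volume,
    percent_difference,
    round_percent,
)

__all__ = [
    "ExperimentConfig",
    "StudyReport",
    "run_phantom_experiment",
    "run_single_case",
    "DEFAULT_C",
]

logger = logging.getLogger("sitvolumetry")

DEFAULT_C = 0.30  # calibrated optimum used downstream


@dataclass
class ExperimentConfig:
    """Configuration of one phantom experiment; round-trips through YAML."""

    n_nodules: int = 22
    v_min: float = 16.0
    v_max: float = 561.0
    min_volume: float = MIN_ANALYSIS_VOLUME_MM3
    n_below_min: int = 4
    shape: str = "hemisphere"
    roi_margin_factor: float = 2.0
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    ct_hu_cut: float = -400.0
    keep_largest: bool = False
    supersample: int = 4
    seed: int = 0
    mri_params: dict = field(default_factory=dict)  # overrides for the MRI arm
    ct_params: dict = field(default_factory=dict)  # overrides for the CT arm

    def to_dict(self) -> dict:
        d = asdict(self)
        d["c_grid"] = [float(c) for c in self.c_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "c_grid" in d:
            d["c_grid"] = tuple(float(c) for c in d["c_grid"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class StudyReport:
    """Full record of one phantom experiment."""

    config: dict
    provenance: dict
    ground_truth: list[dict]
    n_manufactured: int
    n_excluded: int
    n_analyzed: int
    calibration_table: list[dict]
    selected_c: float
    measurements: list[dict]
    volumes_per_c: dict  # {"truth": [...], "ct": [...], "c=0.30": [...], ...}
    agreement: dict  # {"sit_mri_vs_truth": {...}, "sit_mri_vs_ct": {...}}

    def __post_init__(self) -> None:
        if self.n_excluded + self.n_analyzed != self.n_manufactured:
            raise ValueError(
                "nodule bookkeeping does not reconcile: "
                f"{self.n_excluded} + {self.n_analyzed} != {self.n_manufactured}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _auto_roi(nod: NoduleSpec, image: VolumetricImage, margin: float) -> SphericalROI:
    """ROI centred on the nodule with radius = margin x equivalent radius,
    capped so the sphere stays inside the image extent."""
    r_eq = nodule_radius(nod.volume_true, "sphere")
    radius = margin * r_eq
    lo, hi = image.extent()
    c = np.asarray(nod.center)
    cap = float(min((c - lo).min(), (hi - c).min()))
    return SphericalROI(nod.center, min(radius, cap))


def _measurement_row(nod_id: str, method: str, mask, c: float | None) -> dict:
    vol = mask_volume(mask)
    row = {
        "id": nod_id,
        "method": method,
        "c": c,
        "volume_mm3": vol,
        "eq_diam_mm": equivalent_diameter(vol),
        "avg_diam_mm": average_diameter(mask) if mask.n_voxels else 0.0,
    }
    return row


def run_phantom_experiment(config: ExperimentConfig | None = None) -> StudyReport:
    """Run the full phantom study and return its report."""
    if config is None:
        config = ExperimentConfig()
    c_grid = sorted(float(c) for c in config.c_grid)

    volumes = sample_study_volumes(
        config.n_nodules,
        config.v_min,
        config.v_max,
        config.min_volume,
        config.n_below_min,
        config.seed,
    )
    seed_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sub_seeds = seed_rng.integers(0, 2**31 - 1, size=(len(volumes), 2))

    # manufacture: one nodule per subgrid, centred
    mri_proto = mri_phantom_spec([], supersample=config.supersample,
                                 **config.mri_params)
    nodules = []
    for i, v in enumerate(volumes):
        center = tuple(
            (n - 1) / 2.0 * s for n, s in zip(mri_proto.grid_shape, mri_proto.spacing)
        )
        nodules.append(
            NoduleSpec(id=f"nod{i + 1:02d}", center=center, volume_true=float(v),
                       shape=config.shape)
        )

    truth_rows = [
        {
            "id": nod.id,
            "volume_mm3": nod.volume_true,
            "cx_mm": nod.center[0],
            "cy_mm": nod.center[1],
            "cz_mm": nod.center[2],
            "shape": nod.shape,
            "seed": int(sub_seeds[i, 0]),
        }
        for i, nod in enumerate(nodules)
    ]

    analyzed = [
        (i, nod) for i, nod in enumerate(nodules)
        if nod.volume_true >= config.min_volume
    ]
    n_excluded = len(nodules) - len(analyzed)
    logger.info(
        "manufactured %d nodules, excluded %d below %.0f mm^3, analyzing %d",
        len(nodules), n_excluded, config.min_volume, len(analyzed),
    )

    truths: list[float] = []
    ct_vols: list[float] = []
    mri_vols: dict[float, list[float]] = {c: [] for c in c_grid}
    measurements: list[dict] = []

    # CT nodule centre must be recomputed for the CT grid geometry
    ct_proto = ct_phantom_spec([], supersample=config.supersample,
                               **config.ct_params)
    ct_center = tuple(
        (n - 1) / 2.0 * s for n, s in zip(ct_proto.grid_shape, ct_proto.spacing)
    )

    for i, nod in analyzed:
        logger.info("nodule %s: composing phantoms", nod.id)
        mri_spec = mri_phantom_spec(
            [nod], seed=int(sub_seeds[i, 0]), supersample=config.supersample,
            **config.mri_params,
        )
        mri_img, _ = compose_phantom(mri_spec)

        ct_nod = NoduleSpec(nod.id, ct_center, nod.volume_true, nod.shape)
        ct_spec = ct_phantom_spec(
            [ct_nod], seed=int(sub_seeds[i, 1]), supersample=config.supersample,
            **config.ct_params,
        )
        ct_img, _ = compose_phantom(ct_spec)

        mri_roi = _auto_roi(nod, mri_img, config.roi_margin_factor)
        ct_roi = _auto_roi(ct_nod, ct_img, config.roi_margin_factor)

        truths.append(nod.volume_true)
        for c in c_grid:
            mask = segment_sit(mri_img, mri_roi, c, config.keep_largest)
            mri_vols[c].append(mask_volume(mask))
            measurements.append(_measurement_row(nod.id, "sit_mri", mask, c))

        ct_mask = segment_ct_surrogate(ct_img, ct_roi, config.ct_hu_cut)
        ct_vols.append(mask_volume(ct_mask))
        measurements.append(_measurement_row(nod.id, "ct_surrogate", ct_mask, None))

    # --- calibration: concordance of SIT volumes vs truth at each C
    calib_rows = []
    for c in c_grid:
        cc = lin_ccc(truths, mri_vols[c])
        calib_rows.append(
            {"c": c, "n": len(truths), "rho": cc.rho, "c_b": cc.c_b,
             "rho_c": cc.rho_c}
        )
    calib = pd.DataFrame(calib_rows)
    selected_c = float(calib.loc[calib["rho_c"] == calib["rho_c"].max(), "c"].min())
    logger.info("calibration selected C = %.2f", selected_c)

    sel_vols = mri_vols[selected_c]
    agreement = {
        "sit_mri_vs_truth": MethodAgreement(
            truths, sel_vols, xname="truth", yname="sit_mri"
        ).fit().to_dict(),
        "sit_mri_vs_ct": MethodAgreement(
            ct_vols, sel_vols, xname="ct_surrogate", yname="sit_mri"
        ).fit().to_dict(),
    }

    volumes_per_c = {"truth": truths, "ct_surrogate": ct_vols}
    for c in c_grid:
        volumes_per_c[f"c={c:.2f}"] = mri_vols[c]

    return StudyReport(
        config=config.to_dict(),
        provenance={
            "seed": config.seed,
            "config_sha256": config.sha256(),
            "version": __version__,
        },
        ground_truth=truth_rows,
        n_manufactured=len(nodules),
        n_excluded=n_excluded,
        n_analyzed=len(analyzed),
        calibration_table=calib_rows,
        selected_c=selected_c,
        measurements=measurements,
        volumes_per_c=volumes_per_c,
        agreement=agreement,
    )


def run_single_case(
    image: VolumetricImage | str | Path,
    roi: SphericalROI,
    c: float = DEFAULT_C,
    reference_volume: float | None = None,
    keep_largest: bool = False,
) -> dict:
    """Measure one nodule with SIT segmentation at threshold ``c``.

    Returns the measurement as a dict; when ``reference_volume`` is given,
    adds the raw and integer-rounded percent differences against it.
    """
    if not isinstance(image, VolumetricImage):
        image = VolumetricImage.load(image)
    mask = segment_sit(image, roi, c, keep_largest)
    vol = mask_volume(mask)
    meas = NoduleMeasurement(
        id="case",
        volume=vol,
        equivalent_diameter=equivalent_diameter(vol),
        average_diameter=average_diameter(mask) if mask.n_voxels else 0.0,
        method="sit_mri",
    )
    out = {
        "volume_mm3": meas.volume,
        "eq_diam_mm": meas.equivalent_diameter,
        "avg_diam_mm": meas.average_diameter,
        "method": meas.method,
        "c": c,
    }
    if reference_volume is not None:
        pd_raw = percent_difference(vol, reference_volume)
        out["reference_volume_mm3"] = float(reference_volume)
        out["percent_difference"] = pd_raw
        out["percent_difference_rounded"] = round_percent(pd_raw)
    return out
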