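"""Per-subject measurements: regional CSF volumes, ICV normalization, and the
VOSS (ventricle over subarachnoid space) index.

``subject_pipeline`` composes the whole measurement chain: brain extraction,
bias correction, tissue classification with partial-volume estimation,
graph-cuts lateral-ventricle segmentation, the Talairach grid ROIs, regional
CSF volumetry, ICV normalization, and the VOSS index.  The lateral-ventricle
volume comes from the dedicated graph-cuts segmentation, not from a grid box;
the high-convexity and Sylvian volumes come from the CSF map limited to their
ROI boxes, with largest-connected-component filtering applied per hemisphere
to the Sylvian measurement to remove false positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import preprocess, talairach, ventricle_seg
from .config import RunConfig
from .grid import VolumeGrid
from .labels import Tissue

__all__ = [
    "SubjectRecord",
    "VolumetryError",
    "StageError",
    "regional_csf_volume",
    "voss_index",
    "subject_pipeline",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "subject_id", "group", "lv_mm3", "hc_mm3", "syl_mm3", "icv_mm3",
    "lv_norm", "hc_norm", "syl_norm", "voss",
]


class VolumetryError(RuntimeError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SubjectRecord:
    """One subject's regional CSF volumetry.

    Raw volumes in mm^3; ``*_norm`` are ratios of ICV; ``voss`` is the
    lateral-ventricle / high-convexity ratio (identical whether computed from
    raw or normalized volumes, since ICV cancels).
    """

    subject_id: str
    group: str
    lv_volume: float
    hc_volume: float
    sylvian_volume: float
    icv: float

    @property
    def lv_norm(self) -> float:
        return self.lv_volume / self.icv

    @property
    def hc_norm(self) -> float:
        return self.hc_volume / self.icv

    @property
    def syl_norm(self) -> float:
        return self.sylvian_volume / self.icv

    @property
    def voss(self) -> float:
        return voss_index(self.lv_volume, self.hc_volume)

    def to_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "lv_mm3": self.lv_volume,
            "hc_mm3": self.hc_volume,
            "syl_mm3": self.sylvian_volume,
            "icv_mm3": self.icv,
            "lv_norm": self.lv_norm,
            "hc_norm": self.hc_norm,
            "syl_norm": self.syl_norm,
            "voss": self.voss,
        }


def regional_csf_volume(
    csf: preprocess.TissueMaps,
    roi: VolumeGrid,
    mode: str = "fraction",
    largest_component_only: bool = False,
) -> float:
    """CSF amount inside an ROI, in mm^3.

    ``fraction`` mode sums partial-volume CSF fractions over the ROI;
    ``hard`` mode counts CSF-labeled voxels.  With ``largest_component_only``
    the measurement is restricted to the largest 6-connected CSF component
    inside the ROI (used for the Sylvian region to drop false positives).
    """
    if mode not in ("fraction", "hard"):
        raise ValueError(f"mode must be 'fraction' or 'hard', got {mode!r}")
    roi_mask = roi.data.astype(bool)
    if roi_mask.shape != csf.hard_labels.shape:
        raise ValueError("ROI shape does not match the tissue maps")
    if not np.any(roi_mask):
        raise VolumetryError("empty ROI")
    csf_hard = (csf.hard_labels.data == Tissue.CSF) & roi_mask
    if largest_component_only:
        lab, n = ndimage.label(csf_hard, structure=ndimage.generate_binary_structure(3, 1))
        if n == 0:
            return 0.0
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
        region = lab == (1 + int(np.argmax(sizes)))
    else:
        region = csf_hard if mode == "hard" else roi_mask
    voxvol = csf.hard_labels.voxel_volume
    if mode == "hard":
        return float(np.count_nonzero(csf_hard & region)) * voxvol
    return float(csf.csf_fraction()[region].sum()) * voxvol


def voss_index(lv: float, hc: float) -> float:
    """Ratio of lateral-ventricle to high-convexity subarachnoid CSF volume.

    Accepts raw mm^3 or ICV-normalized volumes (any common normalization
    cancels).  An empty high-convexity compartment makes the ratio undefined
    and raises :class:`VolumetryError`.
    """
    if hc <= 0:
        raise VolumetryError(f"VOSS index undefined: high-convexity volume {hc} <= 0")
    return float(lv) / float(hc)


def subject_pipeline(
    intensity: VolumeGrid,
    atlas_prior: VolumeGrid,
    config: RunConfig,
    ac,
    pc,
    subject_id: str = "subject",
    group: str = "unknown",
    artifacts: dict | None = None,
) -> SubjectRecord:
    """Run the full measurement chain on one AC/PC-aligned T1-like volume.

    Deterministic for fixed input and config.  Stage failures propagate as
    :class:`StageError` with the failing stage named.  When ``artifacts`` is a
    dict, intermediate products (brain mask, tissue maps, ventricle mask,
    grid) are stashed into it for inspection.
    """

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    brain = _stage("extract_brain", preprocess.extract_brain, intensity)
    corrected = _stage(
        "correct_bias", preprocess.correct_bias, intensity, brain,
        degree=config.bias_degree, rounds=config.bias_rounds,
    )
    maps = _stage(
        "classify_tissues", preprocess.classify_tissues, corrected, brain,
        init_percentiles=config.classify_init_percentiles,
    )
    maps = _stage(
        "estimate_partial_volume", preprocess.estimate_partial_volume,
        corrected, maps, interface_only=config.pve_interface_only,
        pure_sigma_k=config.pve_pure_sigma_k,
    )
    icv = _stage("compute_icv", preprocess.compute_icv, brain)

    seeds = _stage(
        "make_seeds", ventricle_seg.make_seeds, atlas_prior, maps,
        erode_r=config.seeds_erode_r, dilate_r=config.seeds_dilate_r,
        support_threshold=config.seeds_support_threshold,
    )
    energy = ventricle_seg.CutEnergy(
        lam=config.graphcut_lambda, sigma=config.graphcut_sigma,
        connectivity=config.graphcut_connectivity,
    )
    prob_csf = VolumeGrid(maps.csf_fraction(), intensity.spacing)
    lv_mask = _stage(
        "graph_cut", ventricle_seg.graph_cut, prob_csf, atlas_prior, seeds,
        energy, intensity=corrected,
    )
    lv_mask = _stage(
        "postprocess_mask", ventricle_seg.postprocess_mask, lv_mask,
        config.post_open_r, seeds,
    )
    voxvol = intensity.voxel_volume
    if config.volumetry_mode == "fraction":
        lv_volume = float(maps.csf_fraction()[lv_mask.data.astype(bool)].sum()) * voxvol
    else:
        lv_volume = float(np.count_nonzero(lv_mask.data)) * voxvol

    bbox = _stage("bounding_box", talairach.bounding_box, brain, config.grid_erode_r)
    grid = _stage("build_grid", talairach.build_grid, bbox, ac, pc)
    hc_roi = _stage("roi_mask", talairach.roi_mask, grid, "high_convexity", intensity.shape)
    hc_volume = _stage(
        "regional_csf_volume", regional_csf_volume, maps, hc_roi,
        mode=config.volumetry_mode,
    )
    syl_volume = 0.0
    for side in ("sylvian_left", "sylvian_right"):
        roi = _stage("roi_mask", talairach.roi_mask, grid, side, intensity.shape)
        syl_volume += _stage(
            "regional_csf_volume", regional_csf_volume, maps, roi,
            mode=config.volumetry_mode, largest_component_only=True,
        )

    if artifacts is not None:
        artifacts.update(
            brain_mask=brain, tissue_maps=maps, lv_mask=lv_mask, grid=grid,
            hc_roi=hc_roi,
        )
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        lv_volume=lv_volume,
        hc_volume=hc_volume,
        sylvian_volume=syl_volume,
        icv=icv,
    )


def records_to_frame(records) -> pd.DataFrame:
    """Cohort table with the canonical column order."""
    return pd.DataFrame([r.to_row() for r in records], columns=COHORT_COLUMNS)
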