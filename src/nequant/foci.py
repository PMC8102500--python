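"""Punctate nuclear object counting: chromocenters in 3D, PLA foci in 2D.

Chromocenters (dense heterochromatin foci in DAPI z-stacks) are segmented
per nucleus by thresholding at a high percentile of the within-nucleus
intensity histogram (default 99.5%), labelling connected components in 3D,
and retaining components whose voxel volume lies within an inclusive
[min, max] window (defaults 7 and 2000 voxels). Proximity-ligation-assay
(PLA) foci are counted per cell in 2D after maximum projection, with the
same percentile-threshold / component / size-filter scheme. Percentile
thresholding makes both counts invariant to global intensity rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImageStack


@dataclass
class FociConfig:
    """Detection parameters for punctate objects.

    ``threshold_percentile`` is applied to the within-nucleus (or, with
    ``whole_stack_threshold``, whole-stack) intensity histogram. Volume
    bounds are inclusive and in raw voxels; ``voxel_calibration`` (x, y, z
    scale factors) only converts reported volumes, it never changes the
    filter.
    """

    threshold_percentile: float = 99.5
    min_volume: int = 7
    max_volume: int = 2000
    voxel_calibration: tuple[float, float, float] = (0.075, 0.075, 0.029)
    connectivity: int = 3  # full 26-neighbourhood in 3D, 8 in 2D
    whole_stack_threshold: bool = False

    def validate(self) -> None:
        if not 0.0 < self.threshold_percentile < 100.0:
            raise ValueError("threshold percentile must be in (0, 100)")
        if not 0 < self.min_volume <= self.max_volume:
            raise ValueError("need 0 < min_volume <= max_volume")


@dataclass
class FociRecord:
    """Foci surviving the size filter for one nucleus (or cell)."""

    parent_id: int
    volumes: list[int] = field(default_factory=list)
    calibrated_volumes: list[float] = field(default_factory=list)

    @property
    def foci_count(self) -> int:
        return len(self.volumes)

    @property
    def mean_volume(self) -> float:
        return float(np.mean(self.volumes)) if self.volumes else float("nan")


def _component_volumes(binary: np.ndarray, connectivity: int) -> list[int]:
    structure = ndimage.generate_binary_structure(binary.ndim,
                                                  min(connectivity, binary.ndim))
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return []
    return np.bincount(labels.ravel())[1:].tolist()


def size_filter(volumes: list[int], config: FociConfig) -> list[int]:
    """Inclusive volume window: components of exactly min or max voxels survive."""
    return [v for v in volumes if config.min_volume <= v <= config.max_volume]


def segment_chromocenters(stack, nucleus_mask: np.ndarray,
                          config: FociConfig | None = None) -> list[FociRecord]:
    """Per-nucleus chromocenter counts and voxel volumes from a 3D stack.

    ``nucleus_mask`` is a labelled (or boolean) array congruent with the
    stack. Nuclei smaller than ``min_volume`` yield an empty record with a
    warning. Calibrated volumes use the product of the voxel calibration
    factors per voxel.
    """
    config = config or FociConfig()
    config.validate()
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, float)
    labels = np.asarray(nucleus_mask)
    if labels.dtype == bool:
        labels = labels.astype(np.int32)
    if labels.shape != data.shape:
        raise ValueError("stack and nucleus mask are not congruent")

    voxel_unit = float(np.prod(config.voxel_calibration))
    records = []
    global_thr = (np.percentile(data, config.threshold_percentile)
                  if config.whole_stack_threshold else None)
    for nid in np.unique(labels):
        if nid == 0:
            continue
        mask = labels == nid
        if mask.sum() < config.min_volume:
            warnings.warn(f"nucleus {nid} smaller than min_volume; empty record",
                          stacklevel=2)
            records.append(FociRecord(int(nid)))
            continue
        thr = global_thr if global_thr is not None else \
            np.percentile(data[mask], config.threshold_percentile)
        binary = (data > thr) & mask
        vols = size_filter(_component_volumes(binary, config.connectivity), config)
        records.append(FociRecord(int(nid), vols, [v * voxel_unit for v in vols]))
    return records


def count_pla_foci(image, cell_labels: np.ndarray,
                   config: FociConfig | None = None) -> pd.DataFrame:
    """Per-cell PLA focus counts from a 2D image or a thin z-stack.

    A stack with a z axis is maximum-projected first. Within each cell mask,
    pixels above the percentile threshold are grouped into 8-connected spots
    and size-filtered in 2D (the volume bounds act on pixel areas). Two
    spots merged below the resolution of the connectivity are counted once.
    """
    config = config or FociConfig()
    config.validate()
    if isinstance(image, ImageStack) and "z" in image.axes:
        data = image.data.max(axis=image.axis("z"))
    else:
        data = image.data if isinstance(image, ImageStack) else np.asarray(image, float)
    labels = np.asarray(cell_labels)
    if labels.shape != data.shape:
        raise ValueError("image and cell labels are not congruent")
    cell_ids = [c for c in np.unique(labels) if c != 0]
    if not cell_ids:
        raise ValueError("no cells detected in the label mask")

    global_thr = (np.percentile(data, config.threshold_percentile)
                  if config.whole_stack_threshold else None)
    rows = []
    for cid in cell_ids:
        mask = labels == cid
        thr = global_thr if global_thr is not None else \
            np.percentile(data[mask], config.threshold_percentile)
        binary = (data > thr) & mask
        vols = size_filter(_component_volumes(binary, config.connectivity), config)
        rows.append({"cell_id": int(cid), "foci_count": len(vols),
                     "mean_area_px": float(np.mean(vols)) if vols else float("nan")})
    return pd.DataFrame(rows)


def normalize_foci(condition_counts: dict[str, np.ndarray],
                   control: str) -> pd.DataFrame:
    """Fold change of per-cell focus counts relative to a control condition.

    Every cell's count is divided by the control condition's mean count, so
    the control's mean fold is exactly 1. Reports per-condition mean fold
    with s.e.m. across cells.
    """
    if control not in condition_counts:
        raise ValueError(f"control condition {control!r} not among the conditions")
    control_mean = float(np.mean(condition_counts[control]))
    if control_mean <= 0:
        raise ValueError("control mean count must be positive for normalization")
    rows = []
    for cond, counts in condition_counts.items():
        folds = np.asarray(counts, float) / control_mean
        sem = folds.std(ddof=1) / np.sqrt(len(folds)) if len(folds) > 1 else float("nan")
        rows.append({"condition": cond, "n_cells": len(folds),
                     "mean_fold": float(folds.mean()), "sem_fold": float(sem),
                     "is_control": cond == control})
    return pd.DataFrame(rows)
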