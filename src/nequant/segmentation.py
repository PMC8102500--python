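"""Nucleus segmentation, rim/nucleoplasm partition, and drift registration.

Nuclei are segmented from an intensity channel (typically DAPI) by global
thresholding, hole filling and size filtering. Each retained nucleus is then
partitioned into a nuclear-envelope rim band and a nucleoplasm core at a
fixed pixel distance measured inward from the mask boundary — the geometry
behind the rim:nucleoplasm intensity ratio.

Conventions: 0-based (row, column) = (y, x) coordinates; Euclidean
distances; 8-connectivity in 2D and 26-connectivity in 3D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation as sk_seg
from skimage.registration import phase_cross_correlation

from .core import ImageStack


class DegeneratePartitionError(ValueError):
    """Object too small for the requested rim distance/width: empty core or rim."""


@dataclass
class SegmentationConfig:
    """Segmentation knobs.

    ``threshold``: "otsu" for a global Otsu threshold, or a fixed numeric
    value. ``min_area_px`` removes debris; ``exclude_border`` drops nuclei
    touching the image edge (their rim geometry is truncated).
    """

    threshold: str | float = "otsu"
    min_area_px: int = 64
    exclude_border: bool = False
    smoothing_sigma: float = 0.0  # optional pre-threshold Gaussian blur


@dataclass
class RegionPartition:
    """Per-nucleus rim band and nucleoplasm core.

    ``rim`` holds mask pixels whose Euclidean distance to the background lies
    in ``(rim_distance_px, rim_distance_px + rim_width_px]``; ``nucleoplasm``
    holds pixels deeper than that. Pixels at distance <= ``rim_distance_px``
    (an excluded collar, empty by default) belong to neither.
    """

    object_id: int
    rim: np.ndarray  # boolean mask
    nucleoplasm: np.ndarray  # boolean mask
    rim_distance_px: int = 0
    rim_width_px: int = 3

    def __post_init__(self) -> None:
        if np.any(self.rim & self.nucleoplasm):
            raise ValueError("rim and nucleoplasm overlap")


def _as_plane(image) -> np.ndarray:
    if isinstance(image, ImageStack):
        return image.data
    return np.asarray(image, dtype=float)


def segment_objects(image, config: SegmentationConfig | None = None) -> np.ndarray:
    """Label nuclei in a single-channel 2D plane or 3D stack.

    Returns an integer label array (0 = background). An all-zero image
    yields an empty mask; non-finite pixels are an error.
    """
    config = config or SegmentationConfig()
    plane = _as_plane(image)
    if plane.ndim not in (2, 3):
        raise ValueError("expected a 2D plane or 3D stack")
    if not np.all(np.isfinite(plane)):
        raise ValueError("image contains non-finite pixels")
    if config.smoothing_sigma > 0:
        plane = ndimage.gaussian_filter(plane, config.smoothing_sigma)

    if isinstance(config.threshold, str):
        if config.threshold != "otsu":
            raise ValueError(f"unknown threshold method {config.threshold!r}")
        if np.ptp(plane) == 0:
            return np.zeros(plane.shape, dtype=np.int32)
        thr = filters.threshold_otsu(plane)
    else:
        thr = float(config.threshold)

    binary = plane > thr
    binary = ndimage.binary_fill_holes(binary)
    if config.exclude_border:
        binary = sk_seg.clear_border(binary)
    if config.min_area_px > 1:
        binary = morphology.remove_small_objects(binary, max_size=config.min_area_px - 1)
    # full connectivity: 8-connected in 2D, 26-connected in 3D
    labels = measure.label(binary, connectivity=binary.ndim)
    return labels.astype(np.int32)


def partition_rim_nucleoplasm(labels: np.ndarray, object_id: int,
                              rim_distance_px: int = 0,
                              rim_width_px: int = 3) -> RegionPartition:
    """Split one labelled object into rim band and nucleoplasm core.

    Raises :class:`DegeneratePartitionError` when the object's interior does
    not survive erosion by ``rim_distance_px + rim_width_px`` (empty core),
    or the band itself is empty.
    """
    if rim_width_px < 1 or rim_distance_px < 0:
        raise ValueError("rim_width_px must be >= 1 and rim_distance_px >= 0")
    mask = np.asarray(labels) == object_id
    if not mask.any():
        raise ValueError(f"object {object_id} not present in mask")
    dist = ndimage.distance_transform_edt(mask)
    inner = rim_distance_px
    outer = rim_distance_px + rim_width_px
    rim = mask & (dist > inner) & (dist <= outer)
    core = mask & (dist > outer)
    if not rim.any() or not core.any():
        raise DegeneratePartitionError(
            f"object {object_id} too small for rim distance {inner} + width {rim_width_px}"
        )
    return RegionPartition(object_id, rim, core, rim_distance_px, rim_width_px)


def partition_all(labels: np.ndarray, rim_distance_px: int = 0,
                  rim_width_px: int = 3) -> tuple[list[RegionPartition], list[int]]:
    """Partition every labelled object; degenerate objects are excluded and logged.

    Returns (partitions, excluded_object_ids)."""
    parts, excluded = [], []
    for oid in np.unique(labels):
        if oid == 0:
            continue
        try:
            parts.append(partition_rim_nucleoplasm(labels, int(oid),
                                                   rim_distance_px, rim_width_px))
        except DegeneratePartitionError:
            excluded.append(int(oid))
    if excluded:
        warnings.warn(f"{len(excluded)} object(s) excluded as degenerate partitions: "
                      f"{excluded}", stacklevel=2)
    return parts, excluded


def register_translation(series: ImageStack,
                         upsample_factor: int = 1) -> tuple[ImageStack, np.ndarray]:
    """Rigid drift correction of a time-lapse by translation to the first frame.

    Per-frame offsets are estimated by phase cross-correlation against the
    first frame and undone by translation (integer shifts via roll, subpixel
    via linear interpolation). Returns the corrected series and the applied
    offsets (negated drift), shape (n_frames, 2) as (dy, dx). A warning is
    raised for frames whose registration error is high (e.g. pure noise).
    """
    if "time" not in series.axes:
        raise ValueError("series must have a time axis")
    n_t = series.n("time")
    if n_t < 2:
        raise ValueError("need at least 2 frames to register")
    frames = [series.frame(i).data for i in range(n_t)]
    if any(f.shape != frames[0].shape for f in frames):
        raise ValueError("frames of unequal shape")

    ref = frames[0]
    offsets = np.zeros((n_t, 2))
    corrected = [ref]
    noisy_frames = []
    for i in range(1, n_t):
        shift, _, _ = phase_cross_correlation(ref, frames[i],
                                              upsample_factor=upsample_factor,
                                              normalization=None)
        offsets[i] = shift
        if np.allclose(shift, np.round(shift)):
            moved = np.roll(frames[i], tuple(int(s) for s in np.round(shift)), axis=(0, 1))
        else:
            moved = ndimage.shift(frames[i], shift, order=1, mode="nearest")
        # registration confidence: shared structure after alignment
        if np.corrcoef(ref.ravel(), moved.ravel())[0, 1] < 0.5:
            noisy_frames.append(i)
        corrected.append(moved)
    if noisy_frames:
        warnings.warn(f"low-confidence registration on frames {noisy_frames}: "
                      "little shared structure with the reference", stacklevel=2)
    out = ImageStack(np.stack(corrected), series.axes, dict(series.calibration))
    return out, offsets
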