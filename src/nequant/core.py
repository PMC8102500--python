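"""Core image container with explicit axis semantics and TIFF round-tripping.

Fluorescence stacks move through the pipeline as :class:`ImageStack`: an
n-dimensional non-negative intensity array whose axes are labelled from
``{"time", "z", "channel", "y", "x"}``. Every downstream module indexes by
axis name rather than position, so a 2D image, a z-stack and a time-lapse
all flow through the same code paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Recognised axis labels, in canonical storage order.
AXIS_ORDER = ("time", "z", "channel", "y", "x")


@dataclass
class ImageStack:
    """n-dimensional intensity array with named axes.

    Parameters
    ----------
    data
        Non-negative, finite intensity array (arbitrary units).
    axes
        One label per array dimension, drawn from ``AXIS_ORDER``; ``"y"``
        and ``"x"`` are mandatory, labels must be unique.
    calibration
        Optional physical size per axis, e.g. ``{"x": 0.075, "z": 0.029}``.
        Units are opaque to the pipeline.
    """

    data: np.ndarray
    axes: tuple[str, ...]
    calibration: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.axes = tuple(self.axes)
        if self.data.ndim != len(self.axes):
            raise ValueError(
                f"data has {self.data.ndim} dimensions but {len(self.axes)} axis labels"
            )
        if len(set(self.axes)) != len(self.axes):
            raise ValueError(f"axis labels must be unique, got {self.axes}")
        unknown = set(self.axes) - set(AXIS_ORDER)
        if unknown:
            raise ValueError(f"unknown axis labels {sorted(unknown)}")
        if "y" not in self.axes or "x" not in self.axes:
            raise ValueError("ImageStack requires y and x axes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity data must be finite")

    # -- axis helpers -------------------------------------------------

    def axis(self, label: str) -> int:
        """Positional index of a named axis."""
        try:
            return self.axes.index(label)
        except ValueError:
            raise KeyError(f"stack has no {label!r} axis (axes: {self.axes})") from None

    def n(self, label: str) -> int:
        """Extent along a named axis."""
        return self.data.shape[self.axis(label)]

    def take(self, label: str, index: int) -> "ImageStack":
        """Slice out one plane along a named axis, dropping that axis."""
        ax = self.axis(label)
        new_axes = self.axes[:ax] + self.axes[ax + 1 :]
        return ImageStack(np.take(self.data, index, axis=ax), new_axes, dict(self.calibration))

    def channel(self, index: int) -> "ImageStack":
        return self.take("channel", index)

    def frame(self, index: int) -> "ImageStack":
        return self.take("time", index)

    def plane_shape(self) -> tuple[int, int]:
        return self.n("y"), self.n("x")

    def iter_frames(self):
        for t in range(self.n("time")):
            yield self.frame(t)


def write_tiff(path, stack: ImageStack, *, dtype=np.uint16) -> float:
    """Write a stack as multi-page TIFF, quantizing to 16-bit.

    Intensities are scaled so the data maximum maps to the dtype maximum;
    the scale factor and axis labels are recorded in the TIFF description
    so :func:`read_tiff` can restore the original values. Returns the
    scale factor applied (original = stored / scale).
    """
    peak = float(stack.data.max()) if stack.data.size else 0.0
    scale = (np.iinfo(dtype).max / peak) if peak > 0 else 1.0
    stored = np.round(stack.data * scale).astype(dtype)
    meta = {"axes": list(stack.axes), "scale": scale, "calibration": stack.calibration}
    tifffile.imwrite(path, stored, photometric="minisblack",
                     description=json.dumps(meta))
    return scale


def read_tiff(path) -> ImageStack:
    """Read a TIFF written by :func:`write_tiff`, restoring intensity scale.

    Plain TIFFs without the embedded metadata are accepted: trailing axes
    are labelled ``(..., y, x)`` with leading axes guessed as time/z.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
        axes = tuple(meta["axes"])
        data = data / float(meta.get("scale", 1.0))
        calibration = dict(meta.get("calibration", {}))
    except (json.JSONDecodeError, KeyError, TypeError):
        guessed = ("time", "z", "channel")[: data.ndim - 2] + ("y", "x")
        axes, calibration = tuple(guessed[-data.ndim :]), {}
    return ImageStack(data, axes, calibration)
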