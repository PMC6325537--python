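"""Trace extraction from frame stacks and head-angle measurement from masks.

ROIs for the loop, nrV, and nrD axonal domains are supplied as binary
masks (drawn manually in practice; rendered by the simulator in tests).
Head bend angle is measured either from the major axis of an ellipse fit
to the free portion of the head (second image moments) or from the vector
joining the most anterior restrained midline point to the tip of the nose;
the two conventions agree on well-formed heads.

Image convention: row-major arrays, origin top-left, neutral (unbent) body
axis vertical.  Positive angles tilt the head toward increasing column
index, the ventral side under this package's sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.measure import label, regionprops

#: minimum major/minor axis ratio for a defined orientation
ELONGATION_THRESHOLD = 1.2


class DegenerateOrientationError(ValueError):
    """Raised when a mask is too round for its orientation to be defined."""


@dataclass
class ROISet:
    """Named binary masks (loop, nrV, nrD) on the frame pixel grid."""

    masks: dict

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("ROISet requires at least one mask")
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all ROI masks must share one shape")
        for name, mask in self.masks.items():
            if not np.any(mask):
                raise ValueError(f"ROI {name!r} is empty")

    @property
    def shape(self) -> tuple:
        return next(iter(self.masks.values())).shape

    @classmethod
    def from_label_image(cls, labels: np.ndarray, names: dict) -> "ROISet":
        """Build from a label image and a {label_value: roi_name} mapping."""
        return cls({name: labels == value for value, name in names.items()})

    @classmethod
    def from_tiffs(cls, paths: dict) -> "ROISet":
        return cls({name: tifffile.imread(p) > 0 for name, p in paths.items()})


def roi_mean_intensity(stack: np.ndarray, rois: ROISet) -> pd.DataFrame:
    """Mean pixel intensity under each ROI mask, per frame.

    ``stack`` is a (frames, rows, cols) array (e.g. from
    ``tifffile.imread`` on a multi-page TIFF).  Returns one column per ROI.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frames, rows, cols) array")
    if stack.shape[1:] != rois.shape:
        raise ValueError(
            f"frame shape {stack.shape[1:]} does not match ROI shape {rois.shape}"
        )
    flat = stack.reshape(stack.shape[0], -1)
    out = {}
    for name, mask in rois.masks.items():
        idx = np.flatnonzero(mask.ravel())
        out[name] = flat[:, idx].mean(axis=1)
    return pd.DataFrame(out)


def _largest_region(mask: np.ndarray):
    mask = np.asarray(mask) > 0
    if np.count_nonzero(mask) < 5:
        raise ValueError("mask must contain at least 5 foreground pixels")
    regions = regionprops(label(mask))
    return max(regions, key=lambda r: r.area)


def fit_head_angle(mask: np.ndarray, neutral_axis_deg: float = 0.0) -> float:
    """Signed head-bend angle from the second-moment ellipse fit, in degrees.

    The angle between the major axis of the ellipse fit to the head mask
    and the neutral (vertical, unbent) axis, in (-90, 90], positive toward
    increasing column index (ventral).  ``neutral_axis_deg`` rotates the
    reference axis for tilted acquisitions.

    Raises :class:`DegenerateOrientationError` for near-circular masks
    (major/minor axis ratio below 1.2), whose orientation is undefined.
    """
    region = _largest_region(mask)
    if region.axis_minor_length <= 0 or (
        region.axis_major_length / region.axis_minor_length < ELONGATION_THRESHOLD
    ):
        raise DegenerateOrientationError(
            "mask is too round for a defined orientation (elongation < "
            f"{ELONGATION_THRESHOLD})"
        )
    # regionprops orientation: angle of major axis from the row axis,
    # counter-clockwise in (row, col) coordinates; negate for our
    # column-positive convention
    angle = -np.rad2deg(region.orientation) - neutral_axis_deg
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return float(angle)


def nose_tip_angle(
    mask: np.ndarray, anchor: tuple[float, float] | None = None
) -> float:
    """Head-bend angle from the nose-tip vector, in degrees.

    The angle between the vector running from the most anterior restrained
    midline point (``anchor``; by default the centroid of the mask's most
    posterior row) to the extreme anterior point of the head mask, and the
    neutral vertical axis.  Same sign convention as
    :func:`fit_head_angle`; the two approaches yield equivalent results on
    well-formed heads.
    """
    m = np.asarray(mask) > 0
    if np.count_nonzero(m) < 5:
        raise ValueError("mask must contain at least 5 foreground pixels")
    rows, cols = np.nonzero(m)
    if anchor is None:
        base_row = rows.max()
        anchor = (float(base_row), float(cols[rows == base_row].mean()))
    d2 = (rows - anchor[0]) ** 2 + (cols - anchor[1]) ** 2
    tip = np.argmax(d2)
    drow = rows[tip] - anchor[0]
    dcol = cols[tip] - anchor[1]
    if drow == 0 and dcol == 0:
        raise DegenerateOrientationError("anchor coincides with the mask extreme")
    return float(np.rad2deg(np.arctan2(dcol, -drow)))


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF stack as (frames, rows, cols)."""
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(stack))
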