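"""Cell-shape metrics and monolayer hole quantification.

Area is pixel count times the squared pixel size; elongation is the aspect
ratio (major axis / minor axis) of the second-central-moment equivalent
ellipse of the region.  Holes in a monolayer mask are enclosed background
components (4-connected, not touching the image border) above a minimum
area, reported as a count and a summed area per field.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops, label as sk_label

__all__ = [
    "cell_area",
    "aspect_ratio",
    "quantify_holes",
    "RegionError",
]


class RegionError(ValueError):
    """Empty or degenerate region."""


def _as_bool(region: np.ndarray) -> np.ndarray:
    region = np.asarray(region)
    if region.ndim != 2:
        raise RegionError("region mask must be 2-D")
    return region > 0


def cell_area(region: np.ndarray, pixel_size_um: float) -> float:
    """Region area in um^2: pixel count times pixel_size^2."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    mask = _as_bool(region)
    n = int(mask.sum())
    if n == 0:
        raise RegionError("empty region")
    return n * pixel_size_um**2


def aspect_ratio(region: np.ndarray, method: str = "moments") -> float:
    """Elongation of a region: major axis / minor axis, >= 1.

    ``method='moments'`` (default) uses the moment-equivalent ellipse;
    ``method='feret'`` uses the ratio of maximum to minimum Feret diameter.
    Collinear (degenerate) regions raise :class:`RegionError`.
    """
    mask = _as_bool(region)
    if int(mask.sum()) < 3:
        raise RegionError("region needs >= 3 pixels")
    props = regionprops(mask.astype(np.uint8))[0]
    if method == "moments":
        minor = props.axis_minor_length
        if minor == 0:
            raise RegionError("degenerate (collinear) region")
        return float(props.axis_major_length / minor)
    if method == "feret":
        maxf = props.feret_diameter_max
        # minimum Feret via rotating the coordinates of the boundary
        coords = props.coords.astype(float)
        coords -= coords.mean(axis=0)
        angles = np.linspace(0, np.pi, 180, endpoint=False)
        widths = [
            np.ptp(coords @ np.array([np.cos(a), np.sin(a)])) + 1.0 for a in angles
        ]
        minf = float(np.min(widths))
        if minf == 0:
            raise RegionError("degenerate (collinear) region")
        return float(maxf / minf)
    raise ValueError(f"unknown method {method!r}")


def quantify_holes(
    mask: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 10.0,
) -> dict:
    """Count and total area of holes in a binary monolayer mask.

    A hole is a 4-connected background component fully enclosed by
    foreground (components touching the image border are open gaps, not
    holes) with area >= ``min_area_um2``.

    Returns ``{"holes_per_field": int, "hole_area_per_field_um2": float,
    "hole_areas_um2": list}``.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    fg = _as_bool(mask)
    background = ~fg
    labels, n_components = ndimage.label(
        background, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    border_labels = set(np.unique(labels[0, :])) | set(np.unique(labels[-1, :]))
    border_labels |= set(np.unique(labels[:, 0])) | set(np.unique(labels[:, -1]))

    areas = []
    counts = np.bincount(labels.ravel(), minlength=n_components + 1)
    for comp in range(1, n_components + 1):
        if comp in border_labels:
            continue
        area = counts[comp] * pixel_size_um**2
        if area >= min_area_um2:
            areas.append(float(area))
    return {
        "holes_per_field": len(areas),
        "hole_area_per_field_um2": float(sum(areas)),
        "hole_areas_um2": areas,
    }
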