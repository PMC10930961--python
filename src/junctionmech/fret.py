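"""Ratiometric FRET-index quantification for junctional tension sensors.

Three confocal channels are acquired per field: the donor channel (donor
emission under donor excitation), the acceptor channel (acceptor emission
under acceptor excitation) and the FRET channel (acceptor emission under
donor excitation).  Spectral bleed-through (SBT) of each fluorophore into
the FRET channel is estimated from single-fluorophore control constructs,

    SBT_donor    = I_FRET / I_donor      (donor-only control)
    SBT_acceptor = I_FRET / I_acceptor   (acceptor-only control)

where each ``I`` is a mean intensity over a junctional ROI.  Sensor images
are then corrected and normalised per ROI:

    cFRET      = I_FRET - SBT_donor * I_donor - SBT_acceptor * I_acceptor
    FRET index = cFRET / I_acceptor

The index is a ratio, so it is invariant under global rescaling of all three
channels, and for elastic-linker tension sensors it decreases as mechanical
tension across the module increases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import profile_line

__all__ = [
    "FretImageSet",
    "SbtCoefficients",
    "FretResult",
    "subtract_background",
    "estimate_sbt",
    "corrected_fret",
    "fret_index",
    "quantify_junctions",
    "linescan",
    "roi_labels",
    "DegenerateRoiError",
]


class DegenerateRoiError(ValueError):
    """ROI is empty or has a zero denominator mean."""


@dataclass(frozen=True)
class FretImageSet:
    """Donor / acceptor / FRET channel rasters of identical shape (counts)."""

    donor: np.ndarray
    acceptor: np.ndarray
    fret: np.ndarray

    def __post_init__(self) -> None:
        for name in ("donor", "acceptor", "fret"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.donor.shape == self.acceptor.shape == self.fret.shape):
            raise ValueError("all three channels must have identical shape")
        if self.donor.ndim != 2:
            raise ValueError("channels must be 2-D rasters")

    @property
    def shape(self) -> tuple[int, int]:
        return self.donor.shape


@dataclass(frozen=True)
class SbtCoefficients:
    """Spectral bleed-through constants pooled over control ROIs."""

    sbt_donor: float
    sbt_acceptor: float
    n_rois_used: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sbt_donor) and np.isfinite(self.sbt_acceptor)):
            raise ValueError("SBT coefficients must be finite")
        if self.sbt_donor < 0 or self.sbt_acceptor < 0:
            raise ValueError("SBT coefficients must be >= 0")


@dataclass(frozen=True)
class FretResult:
    """Per-ROI corrected FRET and FRET index."""

    roi_id: int
    cfret: float
    fret_index: float
    flagged_negative: bool = False


def roi_labels(mask: np.ndarray) -> list[int]:
    """Positive labels present in a label mask, sorted."""
    labels = np.unique(np.asarray(mask))
    return [int(v) for v in labels if v > 0]


def _roi_mean(image: np.ndarray, mask: np.ndarray) -> float:
    sel = np.asarray(mask, dtype=bool)
    if not sel.any():
        raise DegenerateRoiError("empty ROI")
    return float(image[sel].mean())


def subtract_background(
    images: FretImageSet,
    method: str = "constant",
    value: float = 0.0,
) -> FretImageSet:
    """Background-subtract all three channels equally, clamping negatives to 0.

    ``method='constant'`` subtracts ``value`` counts from every channel.
    ``method='percentile'`` estimates the background per image set as the
    given percentile of the donor channel (the same estimate is applied to
    all channels so the channels stay comparable).
    """
    if value < 0:
        raise ValueError("value must be >= 0")
    if method == "constant":
        background = float(value)
    elif method == "percentile":
        if not (0.0 < value < 100.0):
            raise ValueError("percentile must be in (0, 100)")
        background = float(np.percentile(images.donor, value))
    else:
        raise ValueError(f"unknown method {method!r}")
    return FretImageSet(
        donor=np.clip(images.donor - background, 0.0, None),
        acceptor=np.clip(images.acceptor - background, 0.0, None),
        fret=np.clip(images.fret - background, 0.0, None),
    )


def estimate_sbt(
    donor_only: FretImageSet,
    donor_only_mask: np.ndarray,
    acceptor_only: FretImageSet,
    acceptor_only_mask: np.ndarray,
) -> SbtCoefficients:
    """Estimate SBT constants from single-fluorophore control image sets.

    Per control ROI the ratio of the mean FRET-channel intensity to the mean
    denominator-channel intensity is computed; ratios are pooled across ROIs
    by unweighted mean.  Images are expected to be background-subtracted.
    """

    def _ratios(images: FretImageSet, mask: np.ndarray, denom_channel: str) -> list[float]:
        denom_image = getattr(images, denom_channel)
        out = []
        for label in roi_labels(mask):
            roi = mask == label
            denom = _roi_mean(denom_image, roi)
            if denom == 0.0:
                raise DegenerateRoiError(
                    f"ROI {label}: zero mean in {denom_channel} channel"
                )
            out.append(_roi_mean(images.fret, roi) / denom)
        if not out:
            raise DegenerateRoiError("control mask contains no ROI")
        return out

    donor_ratios = _ratios(donor_only, donor_only_mask, "donor")
    acceptor_ratios = _ratios(acceptor_only, acceptor_only_mask, "acceptor")
    return SbtCoefficients(
        sbt_donor=float(np.mean(donor_ratios)),
        sbt_acceptor=float(np.mean(acceptor_ratios)),
        n_rois_used=len(donor_ratios) + len(acceptor_ratios),
    )


def corrected_fret(images: FretImageSet, sbt: SbtCoefficients, roi: np.ndarray) -> float:
    """Bleed-through-corrected mean FRET-channel intensity over one ROI."""
    return (
        _roi_mean(images.fret, roi)
        - sbt.sbt_donor * _roi_mean(images.donor, roi)
        - sbt.sbt_acceptor * _roi_mean(images.acceptor, roi)
    )


def fret_index(cfret: float, images: FretImageSet, roi: np.ndarray) -> float:
    """Corrected FRET normalised by the mean acceptor intensity over the ROI."""
    acceptor_mean = _roi_mean(images.acceptor, roi)
    if acceptor_mean == 0.0:
        raise DegenerateRoiError("zero mean acceptor intensity in ROI")
    return cfret / acceptor_mean


def quantify_junctions(
    donor_only: FretImageSet,
    donor_only_mask: np.ndarray,
    acceptor_only: FretImageSet,
    acceptor_only_mask: np.ndarray,
    sensor_groups: dict[str, list[tuple[FretImageSet, np.ndarray]]],
    background: float = 0.0,
    background_method: str = "constant",
) -> pd.DataFrame:
    """Full pipeline: background subtraction, SBT estimation, per-ROI index.

    Parameters
    ----------
    donor_only, acceptor_only :
        Single-fluorophore control image sets with their ROI label masks.
    sensor_groups :
        Mapping from group label to a list of (image set, ROI label mask)
        pairs for the tension-sensor construct.
    background :
        Background level (counts, or percentile when
        ``background_method='percentile'``) subtracted equally from all
        channels of every image set.

    Returns
    -------
    DataFrame with columns ``group, image, roi_id, cfret, fret_index,
    flagged_negative``.  Negative cFRET is reported and flagged rather than
    clamped so downstream group medians are not biased.
    """

    def _bg(images: FretImageSet) -> FretImageSet:
        return subtract_background(images, method=background_method, value=background)

    try:
        sbt = estimate_sbt(
            _bg(donor_only), donor_only_mask, _bg(acceptor_only), acceptor_only_mask
        )
    except DegenerateRoiError as exc:
        raise DegenerateRoiError(f"SBT estimation: {exc}") from exc

    rows = []
    for group, image_pairs in sensor_groups.items():
        for image_idx, (images, mask) in enumerate(image_pairs):
            images = _bg(images)
            for label in roi_labels(mask):
                roi = mask == label
                try:
                    cfret = corrected_fret(images, sbt, roi)
                    index = fret_index(cfret, images, roi)
                except DegenerateRoiError as exc:
                    raise DegenerateRoiError(
                        f"group {group!r}, image {image_idx}, ROI {label}: {exc}"
                    ) from exc
                rows.append(
                    {
                        "group": group,
                        "image": image_idx,
                        "roi_id": label,
                        "cfret": cfret,
                        "fret_index": index,
                        "flagged_negative": cfret < 0,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["group", "image", "roi_id", "cfret", "fret_index", "flagged_negative"],
    )


def linescan(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    width: int = 1,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Intensity profile along a segment, averaged across its width.

    ``start`` and ``end`` are (row, col) endpoints inside the image; the
    profile is sampled at pixel pitch and averaged over ``width`` parallel
    lines perpendicular to the segment.  Distances are reported in um
    relative to the segment midpoint (negative towards ``start``).
    """
    image = np.asarray(image, dtype=float)
    if width < 1:
        raise ValueError("width must be >= 1")
    for point in (start, end):
        r, c = point
        if not (0 <= r <= image.shape[0] - 1 and 0 <= c <= image.shape[1] - 1):
            raise ValueError(f"segment endpoint {point} outside image bounds")
    profile = profile_line(
        image, start, end, linewidth=width, reduce_func=np.mean, mode="reflect"
    )
    distance_px = np.arange(profile.size, dtype=float)
    distance_px -= distance_px[-1] / 2.0
    return pd.DataFrame(
        {"distance_um": distance_px * pixel_size_um, "intensity": profile}
    )
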