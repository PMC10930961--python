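"""Sneddon-model analysis of AFM force-indentation curves.

A rigid conical tip indenting an elastic half-space produces a force

    F = (2/pi) * E / (1 - nu**2) * tan(alpha) * delta**2

where ``E`` is the Young's modulus of the sample, ``nu`` its Poisson ratio,
``alpha`` the half-opening angle of the cone and ``delta`` the indentation
depth measured from the point of tip-sample contact.  For apical-membrane
rigidity measurements on epithelial monolayers the conventional parameters
are ``alpha = 18 deg`` and ``nu = 0.5`` (incompressible cell), with ``E``
reported in kPa, ``F`` in nN and ``delta`` in nm.

The module covers the full single-curve workflow: baseline correction of the
pre-contact segment, contact-point detection from the baseline noise floor,
least-squares estimation of ``E`` over the post-contact region, and the
goodness-of-fit filter (``R^2 >= 0.98`` by default) applied before curves
enter group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ForceCurve",
    "SneddonFit",
    "sneddon_force",
    "correct_baseline",
    "detect_contact_point",
    "fit_sneddon",
    "filter_fits",
    "fit_curves",
    "BaselineError",
    "NoContactError",
    "InsufficientDataError",
    "FitError",
]

# F[nN] = (2/pi) * E[kPa]/(1-nu^2) * tan(alpha) * (delta[nm])^2 * 1e-6
# because kPa * nm^2 = 1e3 Pa * 1e-18 m^2 = 1e-15 N = 1e-6 nN.
_KPA_NM2_TO_NN = 1e-6


class BaselineError(ValueError):
    """No identifiable pre-contact segment for baseline correction."""


class NoContactError(ValueError):
    """Force never exceeds the contact threshold."""


class InsufficientDataError(ValueError):
    """Too few post-contact points to fit the model."""


class FitError(RuntimeError):
    """Least-squares fit failed (e.g. non-positive stiffness estimate)."""


@dataclass(frozen=True)
class ForceCurve:
    """One force-indentation trace.

    Parameters
    ----------
    indentation_nm : array
        Indentation depth in nm, monotone non-decreasing.
    force_nn : array
        Measured force in nN, same length.
    tip_half_angle_deg : float
        Half-opening angle of the conical tip in degrees.
    poisson_ratio : float
        Poisson ratio of the sample.
    curve_id : str
        Optional identifier carried through to fit tables.
    """

    indentation_nm: np.ndarray
    force_nn: np.ndarray
    tip_half_angle_deg: float = 18.0
    poisson_ratio: float = 0.5
    curve_id: str = ""

    def __post_init__(self) -> None:
        indentation = np.asarray(self.indentation_nm, dtype=float)
        force = np.asarray(self.force_nn, dtype=float)
        object.__setattr__(self, "indentation_nm", indentation)
        object.__setattr__(self, "force_nn", force)
        if indentation.ndim != 1 or force.ndim != 1:
            raise ValueError("indentation and force must be 1-D")
        if indentation.shape != force.shape:
            raise ValueError("indentation and force must have equal length")
        if indentation.size < 10:
            raise ValueError("force curve needs >= 10 points")
        if np.any(np.diff(indentation) < 0):
            raise ValueError("indentation must be monotone non-decreasing")
        if not (0.0 <= self.poisson_ratio < 1.0):
            raise ValueError("poisson_ratio must be in [0, 1)")
        if not (0.0 < self.tip_half_angle_deg < 90.0):
            raise ValueError("tip_half_angle_deg must be in (0, 90)")

    def __len__(self) -> int:
        return self.indentation_nm.size


@dataclass(frozen=True)
class SneddonFit:
    """Result of fitting the conical-indenter model to one curve."""

    youngs_modulus_kpa: float
    r_squared: float
    contact_offset_nm: float
    residual_norm_nn: float
    n_points_fit: int
    curve_id: str = ""


def sneddon_force(
    youngs_modulus_kpa: float,
    poisson_ratio: float,
    half_angle_deg: float,
    indentation_nm,
):
    """Closed-form conical-indenter force in nN.

    ``indentation_nm`` may be a scalar or array; negative indentation is a
    domain error.
    """
    if not (0.0 <= poisson_ratio < 1.0):
        raise ValueError("poisson_ratio must be in [0, 1)")
    if not (0.0 < half_angle_deg < 90.0):
        raise ValueError("half_angle_deg must be in (0, 90)")
    delta = np.asarray(indentation_nm, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be >= 0")
    prefactor = (
        (2.0 / math.pi)
        * youngs_modulus_kpa
        / (1.0 - poisson_ratio**2)
        * math.tan(math.radians(half_angle_deg))
        * _KPA_NM2_TO_NN
    )
    out = prefactor * delta**2
    return float(out) if np.isscalar(indentation_nm) else out


def _baseline_slice(curve: ForceCurve, n_baseline: int | None) -> slice:
    if n_baseline is None:
        n_baseline = max(5, int(0.2 * len(curve)))
    if n_baseline < 5:
        raise BaselineError("pre-contact segment needs >= 5 points")
    if n_baseline > len(curve):
        raise BaselineError(
            f"baseline segment of {n_baseline} points exceeds curve length {len(curve)}"
        )
    return slice(0, n_baseline)


def correct_baseline(curve: ForceCurve, n_baseline: int | None = None) -> ForceCurve:
    """Subtract a straight line fitted to the pre-contact segment.

    By default the first 20 % of samples (at least 5) are treated as
    pre-contact; pass ``n_baseline`` when the contact point is known to sit
    elsewhere.  Idempotent on already-flat curves.
    """
    sl = _baseline_slice(curve, n_baseline)
    x = curve.indentation_nm[sl]
    y = curve.force_nn[sl]
    if np.ptp(x) == 0:
        slope, intercept = 0.0, float(np.mean(y))
    else:
        slope, intercept = np.polyfit(x, y, 1)
    corrected = curve.force_nn - (slope * curve.indentation_nm + intercept)
    return replace(curve, force_nn=corrected)


def detect_contact_point(
    curve: ForceCurve,
    threshold_sd: float = 3.0,
    n_baseline: int | None = None,
    run_length: int = 5,
) -> float:
    """Locate the tip-sample contact point on a baseline-corrected curve.

    The threshold is ``threshold_sd`` times the noise sd of the pre-contact
    segment (a tiny floor is used for noise-free data).  Contact is the last
    sample at or below threshold before the force exceeds it for
    ``run_length`` consecutive samples, so that on noise-free data the
    returned offset is exact whenever it lies on the sample grid.
    """
    sl = _baseline_slice(curve, n_baseline)
    # noise sd of the baseline after linear detrend, so a residual slope (or
    # a curve whose contact sits at the very first sample) does not inflate
    # the threshold
    x, y = curve.indentation_nm[sl], curve.force_nn[sl]
    if np.ptp(x) > 0:
        y = y - np.polyval(np.polyfit(x, y, 1), x)
    noise_sd = float(np.std(y))
    threshold = max(threshold_sd * noise_sd, 1e-12)

    above = curve.force_nn > threshold
    n = len(curve)
    run = min(run_length, max(1, n // 10))
    # first index where `run` consecutive samples exceed the threshold
    start = None
    count = 0
    for i in range(n):
        count = count + 1 if above[i] else 0
        if count >= run:
            start = i - run + 1
            break
    if start is None:
        raise NoContactError(
            f"force never exceeds {threshold:.3g} nN for {run} consecutive samples"
        )
    idx = max(start - 1, 0)
    return float(curve.indentation_nm[idx])


def fit_sneddon(
    curve: ForceCurve,
    contact_offset_nm: float | None = None,
    threshold_sd: float = 3.0,
    n_baseline: int | None = None,
) -> SneddonFit:
    """Least-squares estimate of the Young's modulus from one curve.

    The model is linear in ``E`` once the contact offset is fixed, so the fit
    reduces to an exact weighted projection onto ``(delta - offset)**2`` over
    the post-contact region.  ``R^2`` is reported against the fitted model on
    that region.  When ``contact_offset_nm`` is None the contact point is
    detected from the baseline noise floor.
    """
    if contact_offset_nm is None:
        contact_offset_nm = detect_contact_point(
            curve, threshold_sd=threshold_sd, n_baseline=n_baseline
        )
    mask = curve.indentation_nm > contact_offset_nm
    if int(mask.sum()) < 5:
        raise InsufficientDataError(
            f"only {int(mask.sum())} post-contact points; >= 5 required"
        )
    x = (curve.indentation_nm[mask] - contact_offset_nm) ** 2
    y = curve.force_nn[mask]
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise FitError("degenerate post-contact indentation range")
    slope = float(np.dot(x, y)) / denom  # nN / nm^2
    if not np.isfinite(slope) or slope <= 0:
        raise FitError("non-positive stiffness estimate; curve has no elastic response")
    youngs = (
        slope
        * (1.0 - curve.poisson_ratio**2)
        * math.pi
        / (2.0 * math.tan(math.radians(curve.tip_half_angle_deg)))
        / _KPA_NM2_TO_NN
    )
    residuals = y - slope * x
    ss_res = float(np.dot(residuals, residuals))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return SneddonFit(
        youngs_modulus_kpa=youngs,
        r_squared=r_squared,
        contact_offset_nm=float(contact_offset_nm),
        residual_norm_nn=math.sqrt(ss_res),
        n_points_fit=int(mask.sum()),
        curve_id=curve.curve_id,
    )


def filter_fits(fits: list[SneddonFit], r2_min: float = 0.98) -> list[SneddonFit]:
    """Retain fits with ``r_squared >= r2_min`` (inclusive), order preserved."""
    return [f for f in fits if f.r_squared >= r2_min]


def fit_curves(
    curves: list[ForceCurve],
    r2_min: float | None = 0.98,
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit a batch of curves and return a tidy fit table.

    Curves that raise a fit/contact error are skipped.  With ``r2_min`` set
    (default 0.98) the goodness-of-fit filter is applied; pass ``None`` to
    keep every successful fit.
    """
    rows = []
    for i, curve in enumerate(curves):
        try:
            fit = fit_sneddon(curve, **fit_kwargs)
        except (NoContactError, InsufficientDataError, FitError):
            continue
        rows.append(
            {
                "curve_id": fit.curve_id or str(i),
                "E_kPa": fit.youngs_modulus_kpa,
                "r_squared": fit.r_squared,
                "contact_offset_nm": fit.contact_offset_nm,
            }
        )
    table = pd.DataFrame(rows, columns=["curve_id", "E_kPa", "r_squared", "contact_offset_nm"])
    if r2_min is not None:
        table = table[table["r_squared"] >= r2_min].reset_index(drop=True)
    return table
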