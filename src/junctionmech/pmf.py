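"""Umbrella-sampling free-energy estimation by WHAM with bootstrap errors.

Umbrella sampling biases a reaction coordinate ``xi`` with harmonic
restraints ``w_i(xi) = k/2 (xi - c_i)^2`` at spaced centers ``c_i``.  The
weighted histogram analysis method (WHAM) recombines the biased window
histograms into a single unbiased potential of mean force (PMF) by solving
the self-consistent equations

    p_j  proportional to  sum_i H_ij / sum_i N_i exp(beta (f_i - w_ij))
    exp(-beta f_i) = sum_j p_j exp(-beta w_ij)

for the unbiased bin probabilities ``p_j`` and the per-window free-energy
constants ``f_i``; the PMF is ``F_j = -kT ln p_j`` up to an additive
constant (gauge), fixed here by anchoring the minimum (or the unbound
plateau) to zero.  Statistical errors come from a Bayesian bootstrap:
windows are reweighted with flat Dirichlet weights, WHAM is re-solved per
replicate, and per-bin standard deviations are reported.  The binding
energy is the depth of the PMF well relative to the unbound plateau.

Units: ``xi`` in nm, energies in kJ/mol, force constants in kJ/mol/nm^2,
temperature in K with k_B = 0.0083145 kJ/mol/K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KB_KJ_MOL_K",
    "UmbrellaWindow",
    "PmfProfile",
    "BindingEnergy",
    "BootstrapResult",
    "bias_potential",
    "wham",
    "wham_from_histograms",
    "bootstrap_error",
    "binding_energy",
    "CoverageError",
]

KB_KJ_MOL_K = 0.0083145


class CoverageError(ValueError):
    """Umbrella windows leave a gap along the reaction coordinate."""


@dataclass(frozen=True)
class UmbrellaWindow:
    """Biased samples of xi from one harmonic umbrella window."""

    center_nm: float
    force_constant: float  # kJ/mol/nm^2
    samples_nm: np.ndarray
    acceptance_rate: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples_nm, dtype=float)
        object.__setattr__(self, "samples_nm", samples)
        if self.force_constant <= 0:
            raise ValueError("force_constant must be > 0")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples_nm must be a non-empty 1-D array")


@dataclass(frozen=True)
class PmfProfile:
    """Estimated free-energy profile over a xi grid.

    ``grid_nm`` holds bin centers; unsampled bins carry NaN free energy.
    ``reference`` records the anchoring convention ('min' or 'plateau').
    """

    grid_nm: np.ndarray
    free_energy_kj_mol: np.ndarray
    error_kj_mol: np.ndarray | None
    reference: str
    converged: bool
    n_iterations: int
    bin_edges_nm: np.ndarray | None = None


@dataclass(frozen=True)
class BindingEnergy:
    """PMF well depth relative to the unbound plateau."""

    delta_g_kj_mol: float
    error_kj_mol: float | None
    xi_min_nm: float
    minimum_at_edge: bool = False


@dataclass(frozen=True)
class BootstrapResult:
    per_bin_sd_kj_mol: np.ndarray
    delta_g_sd_kj_mol: float
    error_at_min_kj_mol: float
    n_failed: int
    n_boot: int


def bias_potential(force_constant: float, center_nm: float, xi_nm):
    """Harmonic umbrella bias ``k/2 (xi - c)^2`` in kJ/mol."""
    if force_constant <= 0:
        raise ValueError("force_constant must be > 0")
    xi = np.asarray(xi_nm, dtype=float)
    out = 0.5 * force_constant * (xi - center_nm) ** 2
    return float(out) if np.isscalar(xi_nm) else out


def _check_overlap(hists: np.ndarray, centers: np.ndarray) -> None:
    """Require histogram supports of center-adjacent windows to share a bin."""
    order = np.argsort(centers)
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hists[a] > 0) & (hists[b] > 0)):
            raise CoverageError(
                "windows centered at "
                f"{centers[a]:.3f} and {centers[b]:.3f} nm share no histogram bin"
            )


def _solve_wham(
    hists: np.ndarray,
    n_samples: np.ndarray,
    bias: np.ndarray,
    beta: float,
    tolerance_kj_mol: float,
    max_iter: int,
    f_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Fixed-point WHAM iteration.

    Returns (log unbiased bin weights, window constants f_i in kJ/mol,
    converged flag, iterations used).  Empty bins get -inf log weight.
    """
    h_tot = hists.sum(axis=0)
    sampled = h_tot > 0
    # Boltzmann factors of the biases are constant across iterations, so the
    # fixed-point update reduces to two small matrix-vector products.
    with np.errstate(under="ignore"):
        boltz = np.exp(-beta * bias)  # (windows, bins)

    f = np.zeros(len(n_samples)) if f_init is None else f_init.copy()
    converged = False
    iterations = 0
    p = np.zeros_like(h_tot)
    for iterations in range(1, max_iter + 1):
        denom = (n_samples * np.exp(beta * f)) @ boltz  # (bins,)
        with np.errstate(invalid="ignore"):
            p = np.where(sampled, h_tot / denom, 0.0)
        z = boltz @ p  # exp(-beta f_i), unnormalised
        f_new = -np.log(z) / beta
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tolerance_kj_mol:
            converged = True
            break
    denom = (n_samples * np.exp(beta * f)) @ boltz
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = np.where(sampled, np.log(h_tot) - np.log(denom), -np.inf)
    return log_p, f, converged, iterations


def _anchor(free_energy: np.ndarray, reference: str, plateau_fraction: float = 0.1) -> np.ndarray:
    finite = np.isfinite(free_energy)
    if not finite.any():
        return free_energy
    if reference == "min":
        shift = np.nanmin(free_energy[finite])
    elif reference == "plateau":
        n_tail = max(1, int(np.ceil(plateau_fraction * free_energy.size)))
        tail = free_energy[-n_tail:]
        tail = tail[np.isfinite(tail)]
        if tail.size == 0:
            raise ValueError("plateau region contains no sampled bins")
        shift = float(np.mean(tail))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return free_energy - shift


def wham_from_histograms(
    hists: np.ndarray,
    bin_edges_nm: np.ndarray,
    centers_nm: np.ndarray,
    force_constants: np.ndarray,
    temperature_k: float = 310.15,
    tolerance_kj_mol: float = 1e-6,
    max_iter: int = 100_000,
    reference: str = "min",
    window_weights: np.ndarray | None = None,
    f_init: np.ndarray | None = None,
    min_counts: float = 10.0,
) -> PmfProfile:
    """WHAM on precomputed per-window histograms (rows = windows).

    Bins with fewer than ``min_counts`` total (weighted) counts are reported
    as unsampled (NaN): the free-energy estimate in such bins is dominated
    by rare excursions and its variance is of order kT or worse.
    """
    hists = np.asarray(hists, dtype=float)
    bin_edges = np.asarray(bin_edges_nm, dtype=float)
    centers = np.asarray(centers_nm, dtype=float)
    ks = np.broadcast_to(np.asarray(force_constants, dtype=float), centers.shape)
    if temperature_k <= 0:
        raise ValueError("temperature must be > 0")
    if window_weights is not None:
        w = np.asarray(window_weights, dtype=float)[:, None]
        hists = hists * w
    n_samples = hists.sum(axis=1)
    if np.any(n_samples <= 0):
        raise ValueError("every window needs a positive (weighted) sample count")
    _check_overlap(hists, centers)

    grid = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    beta = 1.0 / (KB_KJ_MOL_K * temperature_k)
    bias = 0.5 * ks[:, None] * (grid[None, :] - centers[:, None]) ** 2
    log_p, _, converged, iterations = _solve_wham(
        hists, n_samples, bias, beta, tolerance_kj_mol, max_iter, f_init=f_init
    )
    if not converged:
        warnings.warn(
            f"WHAM did not converge within {max_iter} iterations", RuntimeWarning
        )
    with np.errstate(invalid="ignore"):
        free_energy = np.where(np.isfinite(log_p), -log_p / beta, np.nan)
    free_energy[hists.sum(axis=0) < min_counts] = np.nan
    free_energy = _anchor(free_energy, reference)
    return PmfProfile(
        grid_nm=grid,
        free_energy_kj_mol=free_energy,
        error_kj_mol=None,
        reference=reference,
        converged=converged,
        n_iterations=iterations,
        bin_edges_nm=bin_edges,
    )


def _window_arrays(windows: list[UmbrellaWindow], min_samples: int):
    if not windows:
        raise ValueError("need at least one umbrella window")
    for w in windows:
        if w.samples_nm.size < min_samples:
            raise ValueError(
                f"window at {w.center_nm} nm has {w.samples_nm.size} samples; "
                f">= {min_samples} required for estimation"
            )
    centers = np.array([w.center_nm for w in windows])
    ks = np.array([w.force_constant for w in windows])
    return centers, ks


def _histogram_windows(windows, bin_edges):
    return np.stack(
        [np.histogram(w.samples_nm, bins=bin_edges)[0].astype(float) for w in windows]
    )


def wham(
    windows: list[UmbrellaWindow],
    n_bins: int = 200,
    bin_edges_nm: np.ndarray | None = None,
    temperature_k: float = 310.15,
    tolerance_kj_mol: float = 1e-6,
    max_iter: int = 100_000,
    reference: str = "min",
    min_samples: int = 100,
    min_counts: float = 10.0,
) -> PmfProfile:
    """Estimate the PMF from umbrella windows.

    Bins are half-open ``[lo, hi)`` over the sampled xi range (or explicit
    ``bin_edges_nm``).  Windows must overlap pairwise along xi; a gap raises
    :class:`CoverageError`.  An unconverged run is returned with
    ``converged=False`` and a warning.
    """
    centers, ks = _window_arrays(windows, min_samples)
    if bin_edges_nm is None:
        all_samples = np.concatenate([w.samples_nm for w in windows])
        lo, hi = float(all_samples.min()), float(all_samples.max())
        bin_edges_nm = np.linspace(lo, np.nextafter(hi, np.inf), n_bins + 1)
    hists = _histogram_windows(windows, bin_edges_nm)
    return wham_from_histograms(
        hists,
        bin_edges_nm,
        centers,
        ks,
        temperature_k=temperature_k,
        tolerance_kj_mol=tolerance_kj_mol,
        max_iter=max_iter,
        reference=reference,
        min_counts=min_counts,
    )


def bootstrap_error(
    windows: list[UmbrellaWindow],
    n_boot: int = 200,
    seed: int = 0,
    n_bins: int = 200,
    bin_edges_nm: np.ndarray | None = None,
    temperature_k: float = 310.15,
    tolerance_kj_mol: float = 1e-6,
    max_iter: int = 100_000,
    reference: str = "min",
    granularity: str = "windows",
    plateau_fraction: float = 0.1,
    min_samples: int = 100,
) -> BootstrapResult:
    """Bayesian-bootstrap errors for the WHAM profile and the well depth.

    Per replicate, flat Dirichlet weights reweight whole windows
    (``granularity='windows'``) or the samples inside each window
    (``granularity='samples'``); WHAM is re-solved warm-started from the
    full-data solution.  Reports the per-bin free-energy sd (replicates
    anchored with the requested convention), the sd of the extracted well
    depth, the sd at the minimum bin of the full-data profile, and the
    number of replicates that failed to converge (still included).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    centers, ks = _window_arrays(windows, min_samples)
    if bin_edges_nm is None:
        all_samples = np.concatenate([w.samples_nm for w in windows])
        lo, hi = float(all_samples.min()), float(all_samples.max())
        bin_edges_nm = np.linspace(lo, np.nextafter(hi, np.inf), n_bins + 1)
    base_hists = _histogram_windows(windows, bin_edges_nm)
    base = wham_from_histograms(
        base_hists, bin_edges_nm, centers, ks,
        temperature_k=temperature_k, tolerance_kj_mol=tolerance_kj_mol,
        max_iter=max_iter, reference=reference,
    )
    min_bin = int(np.nanargmin(base.free_energy_kj_mol))

    rng = np.random.default_rng(seed)
    n_windows = len(windows)
    profiles = np.full((n_boot, base.grid_nm.size), np.nan)
    depths = np.empty(n_boot)
    n_failed = 0
    for b in range(n_boot):
        if granularity == "windows":
            weights = rng.dirichlet(np.ones(n_windows)) * n_windows
            hists = base_hists
            window_weights = weights
        elif granularity == "samples":
            hists = np.stack(
                [
                    np.histogram(
                        w.samples_nm,
                        bins=bin_edges_nm,
                        weights=rng.dirichlet(np.ones(w.samples_nm.size))
                        * w.samples_nm.size,
                    )[0]
                    for w in windows
                ]
            )
            window_weights = None
        else:
            raise ValueError(f"unknown granularity {granularity!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            profile = wham_from_histograms(
                hists, bin_edges_nm, centers, ks,
                temperature_k=temperature_k, tolerance_kj_mol=tolerance_kj_mol,
                max_iter=max_iter, reference=reference,
                window_weights=window_weights,
            )
        if not profile.converged:
            n_failed += 1
        # gauge-align the replicate to the full-data profile: the anchoring
        # constant is not a physical quantity, and anchoring each replicate
        # at its own (noisy) minimum would leak extreme-value noise of the
        # worst bin into every bin's spread
        replicate = profile.free_energy_kj_mol
        common = np.isfinite(replicate) & np.isfinite(base.free_energy_kj_mol)
        if common.any():
            replicate = replicate - np.mean(
                replicate[common] - base.free_energy_kj_mol[common]
            )
        profiles[b] = replicate
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                depths[b] = binding_energy(
                    profile, plateau_fraction=plateau_fraction
                ).delta_g_kj_mol
            except ValueError:  # replicate left the plateau unsampled
                depths[b] = np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_bin_sd = np.nanstd(profiles, axis=0, ddof=1)
        delta_g_sd = (
            float(np.nanstd(depths, ddof=1))
            if int(np.isfinite(depths).sum()) >= 2
            else float("nan")
        )
    return BootstrapResult(
        per_bin_sd_kj_mol=per_bin_sd,
        delta_g_sd_kj_mol=delta_g_sd,
        error_at_min_kj_mol=float(per_bin_sd[min_bin]),
        n_failed=n_failed,
        n_boot=n_boot,
    )


def binding_energy(
    profile: PmfProfile, plateau_fraction: float = 0.1
) -> BindingEnergy:
    """Well depth of the PMF: minimum minus the unbound-plateau mean.

    The plateau is the trailing ``plateau_fraction`` of the grid (sampled
    bins only).  A minimum in the first or last sampled bin is flagged as
    unreliable.  Gauge-invariant: shifting the whole profile by a constant
    leaves the result unchanged.
    """
    free_energy = profile.free_energy_kj_mol
    finite = np.where(np.isfinite(free_energy))[0]
    if finite.size == 0:
        raise ValueError("profile has no sampled bins")
    min_idx = int(finite[np.argmin(free_energy[finite])])
    n_tail = max(1, int(np.ceil(plateau_fraction * free_energy.size)))
    tail = free_energy[-n_tail:]
    tail = tail[np.isfinite(tail)]
    if tail.size == 0:
        raise ValueError("plateau region contains no sampled bins")
    delta_g = float(free_energy[min_idx] - np.mean(tail))

    error = None
    if profile.error_kj_mol is not None:
        err = profile.error_kj_mol
        tail_err = err[-n_tail:]
        tail_err = tail_err[np.isfinite(tail_err)]
        plateau_var = float(np.sum(tail_err**2)) / max(tail_err.size, 1) ** 2
        error = float(np.sqrt(err[min_idx] ** 2 + plateau_var))

    at_edge = min_idx in (int(finite[0]), int(finite[-1]))
    if at_edge:
        warnings.warn(
            "PMF minimum lies at the edge of the sampled range; "
            "the well depth may be unreliable",
            RuntimeWarning,
        )
    return BindingEnergy(
        delta_g_kj_mol=delta_g,
        error_kj_mol=error,
        xi_min_nm=float(profile.grid_nm[min_idx]),
        minimum_at_edge=at_edge,
    )
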