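"""Synthetic-data generators with known ground truth for every pipeline.

Each generator is a pure, seeded function of its truth parameters, so every
downstream stage (Sneddon fitting, FRET quantification, contact mapping,
WHAM) can be tested against exact forward-model ground truth without any
external data.

The generators emulate the study conditions of the corresponding wet-lab /
in-silico protocols: conical-tip force curves (half-angle 18 deg, Poisson
ratio 0.5), three-channel junctional FRET images with spectral bleed-through
and shot noise, Boltzmann-distributed umbrella-window samples at 310.15 K,
and peptide-in-pocket pseudo-atom structures with a planted contact map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import reference
from .contacts import Residue, Structure, three_letter
from .fret import FretImageSet
from .nanoindentation import ForceCurve, sneddon_force
from .pmf import KB_KJ_MOL_K, UmbrellaWindow

__all__ = [
    "ForceCurveTruth",
    "FretTruth",
    "JunctionGeometry",
    "PmfSpec",
    "gen_force_curve",
    "gen_fret_imageset",
    "donor_only_truth",
    "acceptor_only_truth",
    "gen_umbrella_samples",
    "gen_peptide_pocket",
    "reference_binding_pmf",
    "gen_reference_umbrella_dataset",
    "double_well_pmf",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Generator could not satisfy its geometric constraints."""


# ---------------------------------------------------------------------------
# force curves


@dataclass(frozen=True)
class ForceCurveTruth:
    """Ground truth for one synthetic force-indentation curve.

    ``noise_sd_nn`` adds Gaussian noise in nN; ``noise_multiplicative`` adds
    relative Gaussian noise (e.g. 0.02 for 2 %) proportional to the
    noise-free force, so the pre-contact region stays exactly zero.
    """

    youngs_modulus_kpa: float
    poisson_ratio: float = 0.5
    tip_half_angle_deg: float = 18.0
    contact_offset_nm: float = 0.0
    noise_sd_nn: float = 0.0
    noise_multiplicative: float = 0.0
    max_indentation_nm: float = 500.0
    n_points: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.youngs_modulus_kpa <= 0:
            raise ValueError("youngs_modulus_kpa must be > 0")
        if not (0.0 <= self.poisson_ratio < 1.0):
            raise ValueError("poisson_ratio must be in [0, 1)")
        if not (0.0 < self.tip_half_angle_deg < 90.0):
            raise ValueError("tip_half_angle_deg must be in (0, 90)")
        if self.contact_offset_nm < 0:
            raise ValueError("contact_offset_nm must be >= 0")
        if self.noise_sd_nn < 0 or self.noise_multiplicative < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")
        if self.max_indentation_nm <= 0:
            raise ValueError("max_indentation_nm must be > 0")


def gen_force_curve(truth: ForceCurveTruth, curve_id: str = "") -> ForceCurve:
    """Forward-model force curve: zero before contact, Sneddon beyond.

    The indentation axis spans 0 to ``contact_offset + max_indentation`` so
    the pre-contact fraction is set by the offset.  Identical truth (same
    seed) reproduces bit-identical curves.
    """
    indentation = np.linspace(
        0.0, truth.contact_offset_nm + truth.max_indentation_nm, truth.n_points
    )
    depth = np.clip(indentation - truth.contact_offset_nm, 0.0, None)
    force = sneddon_force(
        truth.youngs_modulus_kpa,
        truth.poisson_ratio,
        truth.tip_half_angle_deg,
        depth,
    )
    if truth.noise_sd_nn > 0 or truth.noise_multiplicative > 0:
        rng = np.random.default_rng(truth.seed)
        if truth.noise_multiplicative > 0:
            force = force * (
                1.0 + truth.noise_multiplicative * rng.standard_normal(force.size)
            )
        if truth.noise_sd_nn > 0:
            force = force + truth.noise_sd_nn * rng.standard_normal(force.size)
    return ForceCurve(
        indentation_nm=indentation,
        force_nn=force,
        tip_half_angle_deg=truth.tip_half_angle_deg,
        poisson_ratio=truth.poisson_ratio,
        curve_id=curve_id,
    )


# ---------------------------------------------------------------------------
# FRET image sets


@dataclass(frozen=True)
class FretTruth:
    """Ground truth for a synthetic three-channel junction image set.

    ``transfer_fractions`` lists the true FRET transfer fraction per
    junction segment (one segment per ROI).  Sensitized emission is modelled
    as ``E * donor_expression`` with unit detector gain; the FRET index is a
    ratio so the gain cancels in recovery.
    """

    transfer_fractions: tuple[float, ...]
    donor_expression: float = 2000.0
    acceptor_expression: float = 1500.0
    sbt_donor_true: float = 0.3
    sbt_acceptor_true: float = 0.1
    background_level: float = 100.0
    noise_model: str = "none"  # none | gaussian | poisson
    gaussian_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "transfer_fractions", tuple(float(e) for e in self.transfer_fractions)
        )
        if not all(0.0 <= e <= 1.0 for e in self.transfer_fractions):
            raise ValueError("transfer fractions must lie in [0, 1]")
        if not (0.0 <= self.sbt_donor_true < 1.0):
            raise ValueError("sbt_donor_true must be in [0, 1)")
        if not (0.0 <= self.sbt_acceptor_true < 1.0):
            raise ValueError("sbt_acceptor_true must be in [0, 1)")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError("noise_model must be none, gaussian or poisson")


@dataclass(frozen=True)
class JunctionGeometry:
    """Layout of junctional segments (thick line segments) in an image.

    ``segments`` is a sequence of ((r0, c0), (r1, c1), width) tuples; each
    segment becomes one ROI labelled 1..n in order.
    """

    shape: tuple[int, int] = (64, 64)
    segments: tuple = (((16, 8), (16, 56), 5), ((44, 8), (44, 56), 5))

    def masks(self) -> np.ndarray:
        """Label mask: pixels within width/2 of segment i carry label i+1."""
        rows, cols = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        labels = np.zeros(self.shape, dtype=int)
        for i, ((r0, c0), (r1, c1), width) in enumerate(self.segments):
            for r, c in ((r0, c0), (r1, c1)):
                if not (0 <= r < self.shape[0] and 0 <= c < self.shape[1]):
                    raise ValueError(f"segment endpoint ({r}, {c}) outside image")
            p = np.stack([rows - r0, cols - c0], axis=-1).astype(float)
            d = np.array([r1 - r0, c1 - c0], dtype=float)
            norm2 = float(d @ d)
            t = (p @ d) / norm2 if norm2 > 0 else np.zeros(self.shape)
            t = np.clip(t, 0.0, 1.0)
            closest = t[..., None] * d
            dist = np.linalg.norm(p - closest, axis=-1)
            labels[(dist <= width / 2.0) & (labels == 0)] = i + 1
        return labels


def gen_fret_imageset(
    truth: FretTruth, geometry: JunctionGeometry | None = None
) -> tuple[FretImageSet, np.ndarray]:
    """Forward-model three-channel image set and its ROI label mask.

    Per segment i with transfer fraction E_i:

    * donor channel    = background + (1 - E_i) * donor_expression
    * acceptor channel = background + acceptor_expression
    * FRET channel     = background + E_i * donor_expression
                         + sbt_donor * (1 - E_i) * donor_expression
                         + sbt_acceptor * acceptor_expression
    """
    geometry = geometry or JunctionGeometry()
    if len(geometry.segments) != len(truth.transfer_fractions):
        raise ValueError("one transfer fraction per junction segment required")
    labels = geometry.masks()

    donor = np.zeros(geometry.shape)
    acceptor = np.zeros(geometry.shape)
    fret = np.zeros(geometry.shape)
    for i, transfer in enumerate(truth.transfer_fractions):
        sel = labels == i + 1
        donor_signal = (1.0 - transfer) * truth.donor_expression
        acceptor_signal = truth.acceptor_expression
        donor[sel] = donor_signal
        acceptor[sel] = acceptor_signal
        fret[sel] = (
            transfer * truth.donor_expression
            + truth.sbt_donor_true * donor_signal
            + truth.sbt_acceptor_true * acceptor_signal
        )
    donor += truth.background_level
    acceptor += truth.background_level
    fret += truth.background_level

    if truth.noise_model != "none":
        rng = np.random.default_rng(truth.seed)
        if truth.noise_model == "gaussian":
            donor = donor + truth.gaussian_sd * rng.standard_normal(donor.shape)
            acceptor = acceptor + truth.gaussian_sd * rng.standard_normal(acceptor.shape)
            fret = fret + truth.gaussian_sd * rng.standard_normal(fret.shape)
        else:  # poisson shot noise on expected counts
            donor = rng.poisson(donor).astype(float)
            acceptor = rng.poisson(acceptor).astype(float)
            fret = rng.poisson(fret).astype(float)
    images = FretImageSet(
        donor=np.clip(donor, 0.0, None),
        acceptor=np.clip(acceptor, 0.0, None),
        fret=np.clip(fret, 0.0, None),
    )
    return images, labels


def donor_only_truth(truth: FretTruth) -> FretTruth:
    """Donor-only control: acceptor fluorophore absent, hence no transfer."""
    return replace(
        truth,
        transfer_fractions=tuple(0.0 for _ in truth.transfer_fractions),
        acceptor_expression=0.0,
    )


def acceptor_only_truth(truth: FretTruth) -> FretTruth:
    """Acceptor-only control: donor fluorophore absent."""
    return replace(
        truth,
        transfer_fractions=tuple(0.0 for _ in truth.transfer_fractions),
        donor_expression=0.0,
    )


# ---------------------------------------------------------------------------
# umbrella sampling


@dataclass(frozen=True)
class PmfSpec:
    """A 1-D free-energy landscape U(xi) on a finite domain.

    ``energy`` is a vectorised callable xi (nm) -> kJ/mol; build one from a
    table with :meth:`from_table`.
    """

    energy: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]
    temperature_k: float = 310.15

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("domain must be a finite increasing interval")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be > 0")
        probe = self.energy(np.linspace(lo, hi, 101))
        if not np.all(np.isfinite(probe)):
            raise ValueError("energy must be finite on the domain")

    @classmethod
    def from_table(
        cls, xi_nm: np.ndarray, energy_kj_mol: np.ndarray, temperature_k: float = 310.15
    ) -> "PmfSpec":
        xi = np.asarray(xi_nm, dtype=float)
        energy = np.asarray(energy_kj_mol, dtype=float)

        def interpolated(x):
            return np.interp(x, xi, energy)

        return cls(
            energy=interpolated,
            domain=(float(xi[0]), float(xi[-1])),
            temperature_k=temperature_k,
        )


def gen_umbrella_samples(
    spec: PmfSpec,
    centers_nm: Sequence[float],
    force_constant: float,
    n_per_window: int,
    seed: int = 0,
    thin: int = 10,
    burn_in: int = 1000,
    grid_points: int = 4001,
) -> list[UmbrellaWindow]:
    """Draw biased samples per window by Metropolis sampling on a xi grid.

    Each window samples p(xi) proportional to
    ``exp(-[U(xi) + k/2 (xi - c)^2] / kT)`` with a Gaussian proposal of sd
    ``sqrt(kT / k)`` (about one biased-distribution width, which puts the
    acceptance rate near 0.5 and decorrelates kept samples), 1000-step
    burn-in and 10x thinning; the acceptance rate is stored on the window.
    Deterministic per (spec, centers, seed).
    """
    centers = list(centers_nm)
    if not centers:
        raise ValueError("centers_nm must not be empty")
    if force_constant <= 0:
        raise ValueError("force_constant must be > 0")
    lo, hi = spec.domain
    for c in centers:
        if not (lo <= c <= hi):
            raise ValueError(f"center {c} nm outside domain [{lo}, {hi}]")

    xi_grid = np.linspace(lo, hi, grid_points)
    dx = xi_grid[1] - xi_grid[0]
    u_grid = np.asarray(spec.energy(xi_grid), dtype=float)
    kt = KB_KJ_MOL_K * spec.temperature_k
    proposal_sd = math.sqrt(kt / force_constant)

    windows = []
    for w_idx, center in enumerate(centers):
        rng = np.random.default_rng([seed, w_idx])
        energy = u_grid + 0.5 * force_constant * (xi_grid - center) ** 2
        n_steps = burn_in + n_per_window * thin
        steps = np.rint(rng.standard_normal(n_steps) * proposal_sd / dx).astype(int)
        log_u = np.log(rng.random(n_steps))
        state = int(np.argmin(energy))
        accepted = 0
        kept = np.empty(n_per_window, dtype=int)
        keep_idx = 0
        for t in range(n_steps):
            proposal = state + steps[t]
            if 0 <= proposal < grid_points:
                if log_u[t] < (energy[state] - energy[proposal]) / kt:
                    state = proposal
                    accepted += 1
            if t >= burn_in and (t - burn_in) % thin == thin - 1:
                kept[keep_idx] = state
                keep_idx += 1
        windows.append(
            UmbrellaWindow(
                center_nm=float(center),
                force_constant=float(force_constant),
                samples_nm=xi_grid[kept],
                acceptance_rate=accepted / n_steps,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# named landscapes


def double_well_pmf(
    depth_kj_mol: float = 10.0,
    well_separation_nm: float = 0.7,
    center_nm: float = 1.5,
    temperature_k: float = 310.15,
) -> PmfSpec:
    """Symmetric quartic double well: two wells at 0, barrier of ``depth``."""
    half = well_separation_nm / 2.0

    def energy(xi):
        x = (np.asarray(xi, dtype=float) - center_nm) / half
        return depth_kj_mol * (x**2 - 1.0) ** 2

    margin = 0.45 * well_separation_nm
    return PmfSpec(
        energy=energy,
        domain=(center_nm - half - margin, center_nm + half + margin),
        temperature_k=temperature_k,
    )


def reference_binding_pmf(
    depth_kj_mol: float = -reference.BINDING_ENERGY_KJ_MOL,
    xi_min_nm: float = reference.PMF_MINIMUM_XI_NM,
    steepness_per_nm: float = 4.0,
) -> PmfSpec:
    """Morse-shaped binding landscape matching the reported well geometry.

    Single minimum of ``-depth`` at ``xi_min`` rising to a zero plateau at
    large xi, with a repulsive wall at short range — the desk-scale stand-in
    for the all-atom peptide-unbinding PMF.
    """

    def energy(xi):
        d = np.asarray(xi, dtype=float) - xi_min_nm
        x = np.exp(-steepness_per_nm * d)
        return depth_kj_mol * ((1.0 - x) ** 2 - 1.0)

    return PmfSpec(
        energy=energy,
        domain=(xi_min_nm - 0.2, xi_min_nm + 1.7),
        temperature_k=reference.TEMPERATURE_K,
    )


def gen_reference_umbrella_dataset(
    seed: int = 0, n_per_window: int = 5000
) -> tuple[list[UmbrellaWindow], PmfSpec]:
    """Toy umbrella dataset over the reference binding landscape.

    Windows at 0.05 nm spacing with k = 800 kJ/mol/nm^2 at 310.15 K, the
    umbrella protocol of the underlying steered-MD study, spanning the bound
    well through the unbound plateau.
    """
    spec = reference_binding_pmf()
    lo, hi = spec.domain
    centers = np.arange(
        lo + 0.05, hi - 0.049, reference.UMBRELLA_WINDOW_SPACING_NM
    )
    windows = gen_umbrella_samples(
        spec,
        centers,
        force_constant=reference.UMBRELLA_FORCE_CONSTANT,
        n_per_window=n_per_window,
        seed=seed,
    )
    return windows, spec


# ---------------------------------------------------------------------------
# peptide-in-pocket fixtures


def gen_peptide_pocket(
    n_pocket_residues: int,
    n_peptide_residues: int,
    planted_contacts: set[tuple[int, int]],
    seed: int = 0,
    contact_distance: float = 5.0,
    cutoff: float = 6.5,
    exclusion: float = 8.0,
    max_retries: int = 200,
) -> tuple[Structure, Structure]:
    """Pseudo-atom peptide + pocket whose contact map is exactly as planted.

    ``planted_contacts`` holds 0-based (peptide_index, pocket_index) pairs.
    Residues are single pseudo-atoms at their COG.  Placement guarantees
    planted pairs sit within ``cutoff`` (6.5 A) and every other
    peptide-pocket pair at least ``exclusion`` (8 A) apart; infeasible
    plantings (e.g. one pocket residue contacting non-adjacent peptide
    residues) raise :class:`GenerationError` after bounded retries.
    """
    for p, d in planted_contacts:
        if not (0 <= p < n_peptide_residues and 0 <= d < n_pocket_residues):
            raise ValueError(f"planted pair ({p}, {d}) references invalid indices")
    rng = np.random.default_rng(seed)

    spacing = 9.0  # peptide COG spacing (A); > exclusion, < 2 * cutoff
    pep_coords = np.zeros((n_peptide_residues, 3))
    pep_coords[:, 0] = spacing * np.arange(n_peptide_residues)

    partners: dict[int, list[int]] = {d: [] for d in range(n_pocket_residues)}
    for p, d in planted_contacts:
        partners[d].append(p)

    pocket_coords = np.zeros((n_pocket_residues, 3))
    far_offset = np.array([0.0, 0.0, 100.0])
    n_far = 0
    for d in range(n_pocket_residues):
        targets = sorted(partners[d])
        if not targets:
            pocket_coords[d] = far_offset + [spacing * n_far, 0.0, 0.0]
            n_far += 1
            continue
        anchor = pep_coords[targets].mean(axis=0)
        placed = False
        for _ in range(max_retries):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            radius = contact_distance * rng.uniform(0.5, 1.0)
            candidate = anchor + radius * direction
            dists = np.linalg.norm(pep_coords - candidate, axis=1)
            ok = all(
                (dists[p] <= cutoff if p in targets else dists[p] >= exclusion)
                for p in range(n_peptide_residues)
            )
            if ok:
                pocket_coords[d] = candidate
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place pocket residue {d} with partners {targets}"
            )

    def _structure(coords: np.ndarray, chain: str, first_index: int) -> Structure:
        residues = tuple(
            Residue(chain=chain, index=first_index + i, name="GLY", atoms=coords[i])
            for i in range(coords.shape[0])
        )
        return Structure(residues=residues)

    peptide = _structure(pep_coords, "P", 1)
    pocket = _structure(pocket_coords, "D", 1)
    return peptide, pocket
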