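# Methods

This note records the models behind each pipeline, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what validation on synthetic data does and does not establish.

## AFM nanoindentation (Sneddon model)

A rigid cone of half-angle α indenting an elastic half-space obeys
F = (2/π)·E/(1−ν²)·tan(α)·δ². Units are fixed throughout: E in kPa, δ in
nm, F in nN (conversion factor 10⁻⁶ nN per kPa·nm²). Defaults are α = 18°
(sharp silicon-nitride probe) and ν = 0.5 (incompressible cell), both
overridable per curve.

Workflow and choices:

* **Baseline correction** subtracts a straight line fitted to the
  pre-contact segment — by default the first 20 % of samples (at least 5);
  the segment is configurable because the true pre-contact fraction depends
  on how the approach was cropped. The operation is idempotent on flat
  curves.
* **Contact-point detection** thresholds at `threshold_sd` (default 3)
  times the baseline noise sd, where the sd is measured *after* linearly
  detrending the baseline segment so that residual drift — or a curve whose
  contact sits at the very first sample — does not inflate the threshold.
  The contact point is the last sample at or below threshold before the
  force stays above it for 5 consecutive samples; on noise-free data this
  is exact whenever the true offset lies on the sample grid, and good to a
  couple of sample spacings otherwise.
* **Fitting**: with the contact offset fixed, the model is linear in E, so
  the least-squares estimate is the exact projection of F onto (δ−δ₀)² over
  the post-contact region (contact to maximum indentation; no tip-radius or
  viscoelastic corrections). R² is reported against the fitted model on
  that region, and the conventional R² ≥ 0.98 filter (inclusive boundary)
  is applied before fits enter group statistics.

The synthetic generator produces zero force before a planted contact
offset and the closed form beyond it, with additive (nN) and/or
multiplicative (relative) Gaussian noise; multiplicative noise leaves the
pre-contact region exactly zero, mirroring the quiet baseline of a real
approach curve. It does not emulate cantilever dynamics, hydrodynamic drag
or adhesion on retract, so passing recovery tests demonstrates estimator
correctness, not robustness to those artefacts.

## FRET tension-sensor quantification

Channels follow the standard three-cube convention: donor (donor emission,
donor excitation), acceptor (acceptor/acceptor), FRET (acceptor emission,
donor excitation). All three channels are background-subtracted by the
same constant (or a per-set percentile estimate), because a shared detector
offset must be removed identically for the ratios to be meaningful;
negatives are clamped to zero.

Bleed-through constants come from single-fluorophore controls as per-ROI
ratios of channel means, pooled across control ROIs by unweighted mean —
one constant pair per experiment, matching how such constants are derived
from dedicated control constructs. Per sensor ROI,
cFRET = I_FRET − SBT_donor·I_donor − SBT_acceptor·I_acceptor and
FRET index = cFRET/I_acceptor. Negative cFRET is reported and flagged,
never clamped, since clamping would bias group medians upward.

The forward model behind the generator: each junctional segment carries a
true transfer fraction E_t; the donor channel sees (1−E_t)·I_D, the
acceptor channel I_A, and the FRET channel E_t·I_D (sensitized emission at
unit detector gain) plus the two bleed-through terms. Because the index is
a ratio, the gain convention cancels; the closed-form prediction is
index = E_t·I_D/I_A, which the pipeline reproduces to machine precision on
noise-free data and monotonically under shot noise. Defaults (16-bit-style
counts, background 100, donor/acceptor expression 2000/1500) are arbitrary
but configurable. The generator draws junctions as uniform thick line
segments without a microscope PSF, fluorophore maturation differences or
acceptor photobleaching — so the tests validate the correction algebra,
not imaging physics.

Linescans use sub-pixel bilinear sampling along the segment (averaged over
`width` parallel lines), with distance reported from the segment midpoint.

## Residue contact analysis

Contacts are registered between residue centers of geometry (unweighted
atom means) at an inclusive 6.5 Å cutoff; the KD-tree search is verified
against a brute-force all-pairs oracle. Peptide positions are labelled
backwards from the C-terminus (C-1 = last residue), the natural convention
for C-terminal PDZ-binding motifs. Structural distances are in Å; the
0.315 nm water-contact cutoff is converted at a single site (3.15 Å).
Water contacts use the minimum atom–oxygen distance by default (a residue
"touches" a water through any atom), with a COG mode available.

PARCH hydropathy classification follows the printed threshold rule
strictly: value < 1 ⇒ hydrophobic, ≥ 1 ⇒ hydrophilic. Note that for the
shipped JAM-A table this rule classifies the C-9 phenylalanine (0.3) as
hydrophobic even though narrative descriptions group the EFK stretch as
the hydrophilic end; the package reports the rule, not the narrative.
Computing PARCH values themselves requires thermal-annealing molecular
dynamics and is out of scope; the package ships the published values for
the JAM-A/ZO-2 PDZ-2 complex as reference data.

The pocket-fixture generator places single pseudo-atom residues so that
exactly the planted peptide–pocket pairs fall within the cutoff and all
other cross pairs are ≥ 8 Å apart (peptide spacing 9 Å; pocket residues
rejection-sampled around their partners). Plantings that are geometrically
infeasible — one pocket residue contacting non-adjacent peptide residues —
raise a generation error after bounded retries rather than silently
violating the contract.

## Umbrella sampling and WHAM

The generator draws window samples from
p(ξ) ∝ exp(−[U(ξ) + k/2(ξ−c)²]/k_BT) by Metropolis sampling on a dense ξ
grid (4001 points), with a Gaussian proposal of sd √(k_BT/k) — about one
biased-distribution width, which puts the measured acceptance near 0.5 —
1000-step burn-in and 10× thinning. A narrower proposal (0.25·√(k_BT/k))
was tried first and rejected: it accepted ~92 % of moves and left kept
samples strongly autocorrelated, which inflated profile noise well beyond
what the nominal sample count suggests. Distributional correctness is
checked against an exact inverse-CDF sampler on the same grid
(two-sample KS at the 0.01 level).

WHAM solves the self-consistent equations by fixed-point iteration in
probability space (the Boltzmann factors of the biases are precomputed, so
each sweep is two small matrix–vector products), converging on the
max-change of the window constants below 10⁻⁶ kJ/mol with a 10⁵-iteration
cap; unconverged runs are returned flagged with a warning. Histogram bins
are half-open over the sampled range (default 200); neighbouring windows
must share at least one occupied bin or a coverage error lists the gap.
Bins with fewer than 10 total counts are reported as unsampled (NaN):
their free-energy estimates are dominated by rare excursions with errors
of order k_BT and would otherwise dominate any profile-level error metric.
An independently implemented reference (direct minimisation of the convex
WHAM log-likelihood) agrees with the fixed-point solution to < 0.1 kJ/mol
per bin in the tests.

Errors use the Bayesian bootstrap: flat Dirichlet weights over whole
windows (default; a per-sample mode exists), WHAM re-solved per replicate.
Replicates are gauge-aligned to the full-data profile before the per-bin
sd is computed — anchoring each replicate at its own noisy minimum would
leak the worst bin's extreme-value noise into every bin. Both the sd at
the minimum bin and the sd of the extracted well depth are reported, since
either convention is defensible for quoting a binding-energy error.

Binding energy is the PMF minimum minus the mean over the trailing 10 % of
the grid (the unbound plateau); the extraction is gauge-invariant, and a
minimum in an edge bin is flagged as unreliable. Profile comparisons in
the tests are made after removing the arbitrary additive constant by
least squares, the gauge-invariant way to compare free-energy curves.

The toy reference landscape is a Morse well of depth 59.4 kJ/mol at
ξ = 0.9 nm (steepness 4 nm⁻¹, repulsive wall at short range, zero plateau
at large ξ), sampled with the standard umbrella protocol for this class of
problem: windows every 0.05 nm, k = 800 kJ·mol⁻¹·nm⁻², T = 310.15 K,
5·10³ samples per window (~37 windows spanning 0.75–2.5 nm). Recovery of
the depth within 2 kJ/mol and the minimum within 0.05 nm demonstrates
estimator self-consistency at desk scale — it says nothing about the
all-atom peptide-unbinding problem, which would require cluster-scale
steered and umbrella molecular dynamics. Steered-MD provenance (pull rate
and restraints) is metadata only; no dynamics are performed.

Problem sizes used by the tests and the acceptance script — 100 curves per
AFM condition, 100-seed FRET recovery, 21–37 umbrella windows × 5·10³
samples, 100 random contact fixtures up to ~500 residues, 100 bootstrap
replicates — were chosen so the complete validation runs comfortably on a
single CPU while keeping Monte-Carlo error well inside each tolerance.

## Morphometry and statistics

Area is pixel count × pixel size²; aspect ratio is major/minor axis of the
second-central-moment equivalent ellipse (a Feret-diameter mode is
provided as an alternative). Holes in a monolayer mask are 4-connected
background components that do not touch the image border — a border gap is
an open edge, not a hole — filtered at a minimum area (default 10 µm²) to
suppress single-pixel noise.

Kruskal–Wallis uses the tie-corrected H; the omnibus p is chi-squared by
default, with an exact mode that enumerates all group assignments (guarded
to ≤ 2·10⁵ assignments). Dunn's pairwise z uses the pooled-rank variance
with tie correction; p-values are uncorrected by default (the "uncorrected
Dunn's" convention), with Bonferroni available. Mann–Whitney enumerates
the exact tie-aware null for samples of ≤ 8 each (two-sided
p = 2·min(P(U ≤ u), P(U ≥ u)), capped at 1) and otherwise uses the
tie-corrected normal approximation with continuity correction. All-equal
data returns the degenerate H = 0, p = 1 rather than an error. A thin
two-way ANOVA + Fisher's-LSD routine (via statsmodels OLS) serves
factorial designs such as rigidity × coating; it makes no bespoke claims.

## Known limitations

* The synthetic image model has no PSF, no chromatic registration error
  and no fluorophore photophysics; FRET validation covers the correction
  algebra only.
* WHAM is strictly 1-D; no MBAR, no multidimensional reaction coordinates.
* Contact analysis operates on provided coordinates; no structure
  prediction, alignment or pose generation.
* The exact statistics are enumeration-based and intentionally refuse
  sample sizes where enumeration is infeasible.
* No metric is provided for "cell aggregation" scores: the upstream
  definition of that readout is not specified tightly enough to
  re-implement without guessing.
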