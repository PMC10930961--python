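# junctionmech

Quantitative analyses for junctional mechanobiology: how epithelial cells
distribute mechanical tension across their apical membrane, tight junctions
(TJ) and adherens junctions, and how scaffold proteins such as ZO-2 shape
that distribution. The package re-implements, as a tested library, the
measurement stack such studies rely on:

* **AFM nanoindentation** (`junctionmech.nanoindentation`) — fits Sneddon's
  conical-indenter model

  F = (2/π) · E/(1−ν²) · tan(α) · δ²

  to force-indentation curves (F in nN, E in kPa, δ in nm; defaults
  α = 18°, ν = 0.5), after baseline correction and contact-point detection,
  and applies the conventional R² ≥ 0.98 goodness-of-fit filter.
* **FRET tension sensors** (`junctionmech.fret`) — three-channel ratiometric
  quantification with spectral bleed-through (SBT) correction:
  SBT_donor = I_FRET/I_donor and SBT_acceptor = I_FRET/I_acceptor from
  single-fluorophore controls, then per junctional ROI
  cFRET = I_FRET − SBT_donor·I_donor − SBT_acceptor·I_acceptor and
  FRET index = cFRET/I_acceptor, plus linescan intensity profiles.
* **Residue contact analysis** (`junctionmech.contacts`) — center-of-geometry
  contact maps at a 6.5 Å cutoff for peptide–PDZ complexes (e.g. the JAM-A
  C-terminal 10-mer EFKQTSSFLV in the ZO-2 PDZ-2 groove), PARCH-scale
  hydropathy classification (< 1 ⇒ hydrophobic), and water-contact counting
  at 0.315 nm.
* **Umbrella sampling / WHAM** (`junctionmech.pmf`) — a 1-D weighted
  histogram analysis method with Bayesian-bootstrap errors and
  binding-energy extraction as the PMF well depth relative to the unbound
  plateau (k_B = 0.0083145 kJ·mol⁻¹·K⁻¹, default T = 310.15 K).
* **Morphometry & statistics** (`junctionmech.morphometry`,
  `junctionmech.stats`) — cell area, aspect ratio (major/minor axis of the
  moment-equivalent ellipse), enclosed-hole quantification in monolayer
  masks, Kruskal–Wallis with Dunn's post-hoc comparisons (exact enumeration
  available for small samples) and Mann–Whitney U with exact
  tie-aware enumeration for n ≤ 8 per group.
* **Synthetic data** (`junctionmech.synthetic`) — seeded forward-model
  generators for every input class (force curves, three-channel junction
  images, Boltzmann-distributed umbrella windows via Metropolis sampling,
  peptide-in-pocket structures with planted contact maps), so every
  pipeline can be validated against exact ground truth.

## Worked example

```python
import numpy as np
from junctionmech import nanoindentation as ni, pmf, synthetic as syn

# --- AFM: recover a 5 kPa modulus from a noisy synthetic curve
truth = syn.ForceCurveTruth(youngs_modulus_kpa=5.0, contact_offset_nm=125.0,
                            noise_multiplicative=0.02, seed=1)
curve = ni.correct_baseline(syn.gen_force_curve(truth))
fit = ni.fit_sneddon(curve)
print(f"E = {fit.youngs_modulus_kpa:.2f} kPa, R^2 = {fit.r_squared:.4f}")

# --- PMF: binding energy from the toy umbrella dataset
windows, spec = syn.gen_reference_umbrella_dataset(seed=1)
profile = pmf.wham(windows, n_bins=200, temperature_k=spec.temperature_k)
result = pmf.binding_energy(profile)
print(f"deltaG = {result.delta_g_kj_mol:.1f} kJ/mol at xi = {result.xi_min_nm:.2f} nm")
```

Output:

```
E = 4.93 kPa, R^2 = 0.9990
deltaG = -58.9 kJ/mol at xi = 0.90 nm
```

The fitted modulus recovers the generating 5 kPa within the noise level and
would pass the R² ≥ 0.98 filter; the well depth and minimum location match
the toy landscape's generating parameters (−59.4 kJ/mol at 0.9 nm), i.e.
the umbrella-sampling estimator is self-consistent at this sampling depth.

A thin CLI mirrors the library (`junctionmech --help`): `synthesize
forcecurves|umbrella|pocket`, `indent-fit`, `fret-quantify`, `contacts-map`,
`pmf-wham`, `stats-kruskal`, `morph-holes`.

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
decisions and the limits of what the synthetic-data validation shows.
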