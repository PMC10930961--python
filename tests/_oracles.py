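"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different algorithmic route than the code
under test: convex-optimisation WHAM instead of fixed-point iteration,
inverse-CDF sampling instead of Metropolis, brute-force all-pairs distance
scans instead of KD-trees, and enumeration/Monte-Carlo permutation nulls
instead of closed-form rank statistics.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

KB = 0.0083145


def reference_wham(hists, bin_edges, centers, force_constants, temperature_k):
    """WHAM by direct minimisation of the convex log-likelihood.

    Minimises Phi(g) = -sum_i N_i g_i + sum_j H_j ln sum_i N_i e^{g_i} c_ij
    over the window constants ``g_i = beta f_i`` (gauge fixed by g_0 = 0)
    with L-BFGS, then recovers the unbiased bin free energies.  Returns
    (bin centers, free energy min-anchored, total counts per bin).
    """
    hists = np.asarray(hists, dtype=float)
    centers = np.asarray(centers, dtype=float)
    ks = np.broadcast_to(np.asarray(force_constants, dtype=float), centers.shape)
    grid = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    beta = 1.0 / (KB * temperature_k)
    bias = 0.5 * ks[:, None] * (grid[None, :] - centers[:, None]) ** 2
    with np.errstate(under="ignore"):
        c = np.exp(-beta * bias)
    n_i = hists.sum(axis=1)
    h_tot = hists.sum(axis=0)
    sampled = h_tot > 0
    c_s = c[:, sampled]
    h_s = h_tot[sampled]

    def split(x):
        return np.concatenate([[0.0], x])

    def objective(x):
        g = split(x)
        w = n_i * np.exp(g)
        denom = w @ c_s
        phi = -float(n_i @ g) + float(h_s @ np.log(denom))
        ratio = h_s / denom
        grad_full = -n_i + w * (c_s @ ratio)
        return phi, grad_full[1:]

    x0 = np.zeros(len(n_i) - 1)
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10})
    g = split(res.x)
    denom = (n_i * np.exp(g)) @ c_s
    free = np.full(grid.shape, np.nan)
    free[sampled] = -np.log(h_s / denom) / beta
    free -= np.nanmin(free)
    return grid, free, h_tot


def inverse_cdf_umbrella_samples(spec, center, force_constant, n, seed,
                                 grid_points=4001):
    """Exact (inverse-CDF) sampling from the biased grid density."""
    lo, hi = spec.domain
    grid = np.linspace(lo, hi, grid_points)
    energy = spec.energy(grid) + 0.5 * force_constant * (grid - center) ** 2
    kt = KB * spec.temperature_k
    weights = np.exp(-(energy - energy.min()) / kt)
    cdf = np.cumsum(weights)
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    idx = np.searchsorted(cdf, rng.random(n))
    return grid[idx]


def brute_force_contact_pairs(peptide, domain, cutoff):
    """All (peptide_index, domain_index) pairs with COG distance <= cutoff."""
    pairs = set()
    for p, pres in enumerate(peptide.residues):
        pc = pres.atoms.mean(axis=0)
        for d, dres in enumerate(domain.residues):
            dc = dres.atoms.mean(axis=0)
            if np.linalg.norm(pc - dc) <= cutoff:
                pairs.add((p, d))
    return pairs


def brute_force_water_counts(structure, waters, cutoff_angstrom, mode="atom"):
    waters = np.atleast_2d(np.asarray(waters, dtype=float))
    counts = []
    for residue in structure.residues:
        n = 0
        for w in waters:
            if mode == "atom":
                d = np.min(np.linalg.norm(residue.atoms - w, axis=1))
            else:
                d = np.linalg.norm(residue.atoms.mean(axis=0) - w)
            if d <= cutoff_angstrom:
                n += 1
        counts.append(n)
    return np.array(counts)


def monte_carlo_kruskal_p(groups, n_perm, seed):
    """Permutation p-value for the Kruskal-Wallis H via scipy's statistic."""
    from scipy.stats import kruskal

    samples = [np.asarray(g, dtype=float) for g in groups]
    sizes = [s.size for s in samples]
    pooled = np.concatenate(samples)
    h_obs = kruskal(*samples).statistic
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if kruskal(*parts).statistic >= h_obs - 1e-9:
            count += 1
    return count / n_perm


def enumerate_mann_whitney_p(a, b):
    """Exact two-sided Mann-Whitney p via rank-sum enumeration (ties OK)."""
    import itertools

    from scipy.stats import rankdata

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a, n_tot = a.size, pooled.size
    w_obs = ranks[:n_a].sum()
    w_values = np.array(
        [sum(ranks[i] for i in combo)
         for combo in itertools.combinations(range(n_tot), n_a)]
    )
    p_le = np.mean(w_values <= w_obs + 1e-9)
    p_ge = np.mean(w_values >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))
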