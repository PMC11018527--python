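"""Independent brute-force oracles used to check the fast implementations.

Each function here is deliberately written from the textbook definition
(loops, enumeration, closed forms) and shares no code with the package.
"""

import math

import numpy as np
from scipy.stats import binom as binom_dist
from scipy.stats import hypergeom


def pi_pairwise(genotypes) -> np.ndarray:
    """Per-site mean pairwise haplotype difference, all pairs, no missing."""
    g = np.asarray(genotypes)
    n_samples, n_sites = g.shape
    out = np.zeros(n_sites)
    for j in range(n_sites):
        haps = []
        for i in range(n_samples):
            v = g[i, j]
            assert v >= 0, "oracle assumes complete data"
            haps.extend([1] * v + [0] * (2 - v))
        diffs = 0
        pairs = 0
        for a in range(len(haps)):
            for b in range(a + 1, len(haps)):
                diffs += haps[a] != haps[b]
                pairs += 1
        out[j] = diffs / pairs
    return out


def tajima_d_direct(k_hat: float, s: int, n: int) -> float:
    """Direct transcription of the 1989 formulas."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def wc_theta_site(geno_a, geno_b) -> float:
    """Weir & Cockerham (1984) theta for one site, two populations.

    Inputs are lists of diploid alt counts (no missing).
    """
    r = 2
    pops = [list(geno_a), list(geno_b)]
    n = [len(p) for p in pops]
    p_freq = [sum(p) / (2.0 * len(p)) for p in pops]
    h_freq = [sum(1 for v in p if v == 1) / len(p) for p in pops]
    n_bar = sum(n) / r
    n_c = (sum(n) - sum(v * v for v in n) / sum(n)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p_freq)) / sum(n)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p_freq)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h_freq)) / sum(n)
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1.0) / r) * s2 - ((2 * n_bar - 1) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0
    if a + b + c == 0:
        return float("nan")
    return a / (a + b + c)


def chi2_sf_df1(x: float) -> float:
    """Upper tail of chi-squared(1) via the normal tail: 2(1 - Phi(sqrt(x)))."""
    return math.erfc(math.sqrt(x / 2.0))


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed that of the observed table (with the
    usual relative tolerance guard).
    """
    (a, b), (c, d) = table
    row1 = a + b
    col1 = a + c
    total = a + b + c + d
    p_obs = hypergeom.pmf(a, total, col1, row1)
    p = 0.0
    for k in range(max(0, row1 + col1 - total), min(row1, col1) + 1):
        pk = hypergeom.pmf(k, total, col1, row1)
        if pk <= p_obs * (1 + 1e-7):
            p += pk
    return min(p, 1.0)


def binom_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p by pmf enumeration."""
    p_obs = binom_dist.pmf(k, n, p0)
    total = 0.0
    for j in range(n + 1):
        pj = binom_dist.pmf(j, n, p0)
        if pj <= p_obs * (1 + 1e-7):
            total += pj
    return min(total, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up, written out longhand."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        value = p[idx] * m / (rank_from_top + 1)
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted
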