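"""Population-genetic statistic suite.

All estimators consume a :class:`~polykit.core.GenotypeMatrix` and are
implemented directly from the standard definitions:

* per-site nucleotide diversity ``pi = 2 p (1 - p) n / (n - 1)`` with
  complete-case haplotype counts, summed over sliding windows and
  divided by the window span in bp;
* Tajima's D with the usual a1, a2, b1, b2, c1, c2, e1, e2 constants;
* per-site Weir & Cockerham (1984) theta for two populations, averaged
  per gene over the gene span plus flanks;
* F3 = mean over sites of (t - a)(t - b) with a weighted delete-one
  block jackknife (Busing-style), Z = estimate / SE, negative Z being
  the admixture signal;
* frequency-based ABBA/BABA D and f_d in nonoverlapping windows with
  the same weighted jackknife;
* lower-tail Z -> p -> Benjamini-Hochberg -> Z adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenotypeMatrix

# ---------------------------------------------------------------------------
# windowed diversity


def site_pi(g: GenotypeMatrix, samples=None) -> np.ndarray:
    """Unbiased per-site pi (expected pairwise difference); NaN if n < 2."""
    ac, an = g.alt_counts(samples)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = ac / np.maximum(an, 1)
        pi = 2.0 * p * (1.0 - p) * an / np.maximum(an - 1, 1)
    return np.where(an >= 2, pi, np.nan)


def _windows(chrom_len: int, window_bp: int, step_bp: int):
    starts = range(1, chrom_len - window_bp + 2, step_bp)
    return [(s, s + window_bp - 1) for s in starts]


def _chrom_lengths(g: GenotypeMatrix) -> dict[str, int]:
    lengths = dict(g.contig_lengths or {})
    for c in dict.fromkeys(g.chrom.tolist()):
        lengths.setdefault(c, int(g.pos[g.chrom == c].max()))
    return lengths


def windowed_pi(
    g: GenotypeMatrix,
    samples=None,
    window_bp: int = 100_000,
    step_bp: int = 10_000,
) -> tuple[pd.DataFrame, float]:
    """Sliding-window nucleotide diversity per bp, plus the genome mean.

    Window values are site-pi sums divided by the window span
    (monomorphic positions contribute zero); trailing spans shorter
    than a full window are not emitted.  The genome value is the
    unweighted mean of window values.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    pi = np.nan_to_num(site_pi(g, samples))
    rows = []
    lengths = _chrom_lengths(g)
    for chrom, chrom_len in lengths.items():
        on = g.chrom == chrom
        pos = g.pos[on]
        vals = pi[on]
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        for start, end in _windows(chrom_len, window_bp, step_bp):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "value": (cum[hi] - cum[lo]) / window_bp,
                    "n_sites": int(hi - lo),
                    "statistic": "pi",
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "n_sites", "statistic"])
    mean = float(df["value"].mean()) if len(df) else float("nan")
    return df, mean


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for n haplotypes."""
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d(k_hat: float, s: int, n: int) -> float:
    """Tajima's D from mean pairwise diversity, S and haplotype count."""
    if s < 1:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    return (k_hat - s / c["a1"]) / np.sqrt(var)


def windowed_tajima_d(
    g: GenotypeMatrix,
    samples=None,
    window_bp: int = 100_000,
    step_bp: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Windowed Tajima's D (nonoverlapping by default) and its mean.

    Windows without segregating sites emit NaN and are excluded from
    the genome mean.  With missing data the constants use the rounded
    mean called-haplotype count over the window's segregating sites.
    """
    step_bp = step_bp or window_bp
    ac, an = g.alt_counts(samples)
    seg = (ac > 0) & (ac < an)
    pi = np.nan_to_num(site_pi(g, samples))
    rows = []
    for chrom, chrom_len in _chrom_lengths(g).items():
        on = g.chrom == chrom
        pos = g.pos[on]
        for start, end in _windows(chrom_len, window_bp, step_bp):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            win = np.flatnonzero(on)[lo:hi]
            win_seg = win[seg[win]]
            s = int(win_seg.size)
            if s == 0:
                value = float("nan")
            else:
                n_eff = int(round(an[win_seg].mean()))
                value = tajima_d(float(pi[win_seg].sum()), s, n_eff) if n_eff >= 4 else float("nan")
            rows.append(
                {"chrom": chrom, "start": start, "end": end, "value": value,
                 "n_sites": s, "statistic": "tajima_d"}
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "n_sites", "statistic"])
    mean = float(df["value"].dropna().mean()) if df["value"].notna().any() else float("nan")
    return df, mean


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST


def wc_fst_sites(g: GenotypeMatrix, pop_a, pop_b) -> np.ndarray:
    """Per-site Weir & Cockerham (1984) theta for two populations.

    Sites with fewer than 2 called diploids in either population, or
    with zero total variance components, are NaN.  Negative estimates
    are retained.
    """
    comps = wc_components(g, pop_a, pop_b)
    a, b, c = comps["a"], comps["b"], comps["c"]
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / denom
    return np.where(np.abs(denom) > 0, theta, np.nan)


def wc_components(g: GenotypeMatrix, pop_a, pop_b) -> dict[str, np.ndarray]:
    """The a (among-population), b, c variance components per site."""
    r = 2
    n_i, p_i, h_i = [], [], []
    for pop in (pop_a, pop_b):
        sub = g._sub(pop)
        called = sub >= 0
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called, sub, 0).sum(axis=0) / np.maximum(2 * n, 1)
            h = (sub == 1).sum(axis=0) / np.maximum(n, 1)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.array(n_i)
    p_i = np.array(p_i)
    h_i = np.array(h_i)
    ok = (n_i >= 2).all(axis=0)

    n_sum = n_i.sum(axis=0)
    n_bar = n_sum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_sum - (n_i**2).sum(axis=0) / n_sum) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / n_sum
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / n_sum
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    nan = np.full(a.shape, np.nan)
    return {
        "a": np.where(ok, a, nan),
        "b": np.where(ok, b, nan),
        "c": np.where(ok, c, nan),
    }


def wc_fst_genome(g: GenotypeMatrix, pop_a, pop_b) -> float:
    """Genome-wide Weir & Cockerham theta as the ratio of summed
    variance components (the estimator's recommended multi-locus form;
    the unweighted mean of per-site ratios is biased toward zero by
    low-frequency sites)."""
    comps = wc_components(g, pop_a, pop_b)
    a, b, c = comps["a"], comps["b"], comps["c"]
    ok = ~np.isnan(a)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if not ok.any() or denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def gene_fst(
    g: GenotypeMatrix,
    pop_a,
    pop_b,
    genes: pd.DataFrame,
    flank_bp: int = 2000,
    method: str = "mean",
) -> pd.DataFrame:
    """Per-gene F_ST over the gene span plus flanks.

    ``method='mean'`` averages per-site theta (undefined sites are
    skipped); ``method='ratio'`` uses the ratio-of-sums estimator over
    the same sites.  Genes without informative sites get NaN.
    """
    theta = wc_fst_sites(g, pop_a, pop_b)
    comps = wc_components(g, pop_a, pop_b) if method == "ratio" else None
    rows = []
    for _, gene in genes.iterrows():
        on = (
            (g.chrom == gene["chrom"])
            & (g.pos >= gene["start"] - flank_bp)
            & (g.pos <= gene["end"] + flank_bp)
        )
        vals = theta[on]
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            value = float("nan")
        elif method == "mean":
            value = float(vals.mean())
        elif method == "ratio":
            a = comps["a"][on]
            denom = a + comps["b"][on] + comps["c"][on]
            keep = ~np.isnan(denom)
            value = float(a[keep].sum() / denom[keep].sum()) if np.abs(denom[keep].sum()) > 0 else float("nan")
        else:
            raise ValueError("method must be 'mean' or 'ratio'")
        rows.append({"gene_id": gene["gene_id"], "fst": value, "n_sites": int(vals.size)})
    return pd.DataFrame(rows, columns=["gene_id", "fst", "n_sites"])


# ---------------------------------------------------------------------------
# SNP filtering


@dataclass
class FilterRules:
    """Active site filters; None disables a rule.

    LD pruning greedily drops the later site of any pair with genotype
    correlation r^2 above ``ld_r2`` inside a sliding window of
    ``ld_window`` sites advanced by ``ld_step`` (earlier site kept —
    deterministic).
    """

    max_missing: float | None = None
    min_maf: float | None = None
    ld_r2: float | None = None
    ld_window: int = 50
    ld_step: int = 10
    het_in_control: str | None = None
    repeat_mask: pd.DataFrame | None = None  # BED-style chrom/start/end


def snp_filter(g: GenotypeMatrix, rules: FilterRules) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the active rules in a fixed order; returns matrix + log."""
    keep = np.ones(g.n_sites, dtype=bool)
    log: dict[str, int] = {}

    if rules.repeat_mask is not None and len(rules.repeat_mask):
        masked = np.zeros(g.n_sites, dtype=bool)
        for _, iv in rules.repeat_mask.iterrows():
            masked |= (g.chrom == iv["chrom"]) & (g.pos > iv["start"]) & (g.pos <= iv["end"])
        log["repeat_mask"] = int((masked & keep).sum())
        keep &= ~masked

    if rules.het_in_control is not None:
        if rules.het_in_control not in g.samples:
            raise ValueError(f"control sample {rules.het_in_control!r} absent from matrix")
        control = g.genotypes[g.samples.index(rules.het_in_control)]
        bad = control == 1
        log["het_in_control"] = int((bad & keep).sum())
        keep &= ~bad

    if rules.max_missing is not None:
        missing_frac = (g.genotypes < 0).mean(axis=0)
        bad = missing_frac > rules.max_missing
        log["max_missing"] = int((bad & keep).sum())
        keep &= ~bad

    if rules.min_maf is not None:
        ac, an = g.alt_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = ac / np.maximum(an, 1)
        maf = np.minimum(p, 1 - p)
        bad = (an == 0) | (maf < rules.min_maf)
        log["min_maf"] = int((bad & keep).sum())
        keep &= ~bad

    if rules.ld_r2 is not None:
        idx = np.flatnonzero(keep)
        dropped = _ld_prune(g.genotypes[:, idx], rules.ld_r2, rules.ld_window, rules.ld_step)
        log["ld_prune"] = int(dropped.sum())
        keep[idx[dropped]] = False

    return g.take_sites(keep), log


def _ld_prune(genotypes: np.ndarray, r2_max: float, window: int, step: int) -> np.ndarray:
    n_sites = genotypes.shape[1]
    drop = np.zeros(n_sites, dtype=bool)
    gt = np.where(genotypes >= 0, genotypes, np.nan).astype(float)
    for w_start in range(0, max(n_sites - 1, 1), step):
        w_end = min(w_start + window, n_sites)
        cols = range(w_start, w_end)
        for i in cols:
            if drop[i]:
                continue
            for j in range(i + 1, w_end):
                if drop[j]:
                    continue
                if _pair_r2(gt[:, i], gt[:, j]) > r2_max:
                    drop[j] = True
        if w_end >= n_sites:
            break
    return drop


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# polarization and SFS


def polarize_ancestral(g: GenotypeMatrix, outgroup_samples) -> np.ndarray:
    """Majority vote over outgroup haplotypes.

    Returns per-site codes: 0 = REF ancestral, 1 = ALT ancestral,
    -1 = unresolved (tie or no calls).
    """
    sub = g._sub(outgroup_samples)
    called = sub >= 0
    alt_haps = np.where(called, sub, 0).sum(axis=0)
    total_haps = 2 * called.sum(axis=0)
    ref_haps = total_haps - alt_haps
    out = np.full(g.n_sites, -1, dtype=np.int8)
    out[ref_haps > alt_haps] = 0
    out[alt_haps > ref_haps] = 1
    out[total_haps == 0] = -1
    return out


@dataclass
class SFSResult:
    spectrum: np.ndarray  # counts indexed by allele count 1..len(spectrum)
    folded: bool
    n_haplotypes: int
    n_used: int
    n_excluded_missing: int
    n_excluded_unresolved: int
    n_monomorphic: int


def sfs(
    g: GenotypeMatrix,
    samples=None,
    polarized: bool = False,
    ancestral: np.ndarray | None = None,
) -> SFSResult:
    """Site frequency spectrum over complete-case sites.

    Unfolded (``polarized=True``) counts derived-allele occurrences
    1..2N-1, using ``ancestral`` codes (defaults to ``g.ancestral``);
    unresolved sites are excluded and logged.  Folded counts minor
    alleles 1..N.  Sites with any missing call among the chosen
    samples are excluded and logged.
    """
    sub = g._sub(samples)
    n_dip = sub.shape[0]
    n_hap = 2 * n_dip
    complete = (sub >= 0).all(axis=0)
    n_excluded_missing = int((~complete).sum())
    alt_count = sub.sum(axis=0)

    if polarized:
        anc = ancestral if ancestral is not None else g.ancestral
        if anc is None:
            raise ValueError("polarized SFS requires ancestral assignments")
        resolved = anc >= 0
        usable = complete & resolved
        n_excluded_unresolved = int((complete & ~resolved).sum())
        derived = np.where(anc == 0, alt_count, n_hap - alt_count)[usable]
        seg = (derived > 0) & (derived < n_hap)
        counts = np.bincount(derived[seg], minlength=n_hap)[1:n_hap]
        spectrum = counts
        folded = False
    else:
        usable = complete
        n_excluded_unresolved = 0
        ac = alt_count[usable]
        seg = (ac > 0) & (ac < n_hap)
        minor = np.minimum(ac[seg], n_hap - ac[seg])
        spectrum = np.bincount(minor, minlength=n_dip + 1)[1:n_dip + 1]
        folded = True
    n_monomorphic = int(usable.sum() - seg.sum())
    return SFSResult(
        spectrum=spectrum.astype(np.int64),
        folded=folded,
        n_haplotypes=n_hap,
        n_used=int(seg.sum()),
        n_excluded_missing=n_excluded_missing,
        n_excluded_unresolved=n_excluded_unresolved,
        n_monomorphic=n_monomorphic,
    )


def fold_sfs(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded spectrum (length 2N-1) to minor counts 1..N."""
    unfolded = np.asarray(unfolded)
    n_hap = unfolded.size + 1
    n = n_hap // 2
    folded = np.zeros(n, dtype=unfolded.dtype)
    for i in range(1, n_hap):
        m = min(i, n_hap - i)
        folded[m - 1] += unfolded[i - 1]
    # midpoint class was added twice when 2N is even
    if n_hap % 2 == 0:
        folded[n - 1] = unfolded[n - 1]
    return folded


# ---------------------------------------------------------------------------
# F3 and the weighted block jackknife


@dataclass
class JackknifeResult:
    estimate: float
    se: float
    z: float
    n_blocks: int
    block_weights: np.ndarray = field(default_factory=lambda: np.array([]))
    flagged: bool = False


def weighted_block_jackknife(num: np.ndarray, den: np.ndarray) -> JackknifeResult:
    """Delete-one-block jackknife for a ratio-of-sums statistic.

    ``num`` and ``den`` are per-block sums; the estimate is
    sum(num)/sum(den), block weights are the denominators, and the
    variance follows the weighted jackknife of Busing et al. (1999).
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    ok = den > 0
    num, den = num[ok], den[ok]
    g_blocks = num.size
    total_n = den.sum()
    estimate = float(num.sum() / total_n)
    if g_blocks < 2:
        return JackknifeResult(estimate, float("nan"), float("nan"), g_blocks, den, flagged=True)
    theta_j = (num.sum() - num) / (total_n - den)
    h = total_n / den
    theta_jack = g_blocks * estimate - ((1.0 - den / total_n) * theta_j).sum()
    tau = h * estimate - (h - 1.0) * theta_j
    var = float(np.sum((tau - theta_jack) ** 2 / (h - 1.0)) / g_blocks)
    se = float(np.sqrt(var))
    z = estimate / se if se > 0 else float("nan")
    return JackknifeResult(estimate, se, z, g_blocks, den)


def _block_ids(g: GenotypeMatrix, block_bp: int) -> np.ndarray:
    keys = [f"{c}:{int(p // block_bp)}" for c, p in zip(g.chrom, g.pos)]
    _, ids = np.unique(keys, return_inverse=True)
    return ids


def f3_statistic(
    g: GenotypeMatrix,
    target,
    source_a,
    source_b,
    block_bp: int = 1_000_000,
    het_correction: bool = False,
) -> JackknifeResult:
    """F3(target; A, B) = mean over sites of (t - a)(t - b).

    Negative Z indicates the target is admixed between the sources.
    SE comes from the weighted delete-one-block jackknife with blocks
    of ``block_bp`` and weights proportional to usable site counts.

    With ``het_correction=True`` the target's sampling-variance term
    t(1-t)/(n_hap - 1) is subtracted per site, making the estimator
    unbiased at zero for unstructured data (needed for null
    calibration); the default keeps the raw product so that a target
    identical to a source gives exactly zero.
    """
    t = g.alt_freq(target)
    a = g.alt_freq(source_a)
    b = g.alt_freq(source_b)
    term = (t - a) * (t - b)
    if het_correction:
        _, an_t = g.alt_counts(target)
        with np.errstate(invalid="ignore", divide="ignore"):
            term = term - t * (1.0 - t) / np.maximum(an_t - 1, 1)
        term = np.where(an_t >= 2, term, np.nan)
    usable = ~np.isnan(term)
    if usable.sum() == 0:
        raise ValueError("no sites with frequencies in all three groups")
    ids = _block_ids(g, block_bp)
    n_blocks = ids.max() + 1
    num = np.bincount(ids[usable], weights=term[usable], minlength=n_blocks)
    den = np.bincount(ids[usable], minlength=n_blocks).astype(float)
    return weighted_block_jackknife(num, den)


def z_fdr_adjust(z_scores) -> np.ndarray:
    """Lower-tail Z -> p -> Benjamini-Hochberg -> Z, order preserved."""
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise ValueError("empty Z input")
    if not np.isfinite(z).all():
        raise ValueError("Z scores must be finite")
    p = stats.norm.cdf(z)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return stats.norm.ppf(np.minimum(p_adj, 1.0 - 1e-16))


# ---------------------------------------------------------------------------
# introgression scan


def introgression_scan(
    g: GenotypeMatrix,
    p1,
    p2,
    p3,
    outgroup,
    window_bp: int = 20_000,
    statistic: str = "D",
    z_threshold: float = 3.0,
) -> tuple[pd.DataFrame, JackknifeResult]:
    """Windowed ABBA/BABA introgression scan with genome-wide jackknife.

    Frequency-based ABBA = (1-f1) f2 f3 (1-f4) and BABA = f1 (1-f2) f3
    (1-f4) per site; window D = sum(ABBA-BABA)/sum(ABBA+BABA) over
    nonoverlapping windows.  ``statistic='f_d'`` replaces the
    denominator with the dynamic-donor sums of Martin et al. (2015).
    The genome-wide result is a weighted delete-one-window jackknife
    (weights = window denominator sums); windows are flagged
    significant when the genome |Z| path would exceed ``z_threshold``
    standard-error units, i.e. |window D| > z_threshold * SE.
    """
    f1 = g.alt_freq(p1)
    f2 = g.alt_freq(p2)
    f3 = g.alt_freq(p3)
    f4 = g.alt_freq(outgroup)
    abba = (1 - f1) * f2 * f3 * (1 - f4)
    baba = f1 * (1 - f2) * f3 * (1 - f4)
    num_site = abba - baba
    if statistic == "D":
        den_site = abba + baba
    elif statistic == "f_d":
        fd_donor = np.maximum(f2, f3)
        abba_d = (1 - f1) * fd_donor * fd_donor * (1 - f4)
        baba_d = f1 * (1 - fd_donor) * fd_donor * (1 - f4)
        den_site = abba_d - baba_d
    else:
        raise ValueError("statistic must be 'D' or 'f_d'")
    usable = ~(np.isnan(num_site) | np.isnan(den_site))

    rows, nums, dens = [], [], []
    for chrom, chrom_len in _chrom_lengths(g).items():
        on = (g.chrom == chrom) & usable
        pos = g.pos[on]
        num_c = num_site[on]
        den_c = den_site[on]
        n_windows = int(np.ceil(chrom_len / window_bp))
        for w in range(n_windows):
            start = w * window_bp + 1
            end = min((w + 1) * window_bp, chrom_len)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            wn = float(num_c[lo:hi].sum())
            wd = float(den_c[lo:hi].sum())
            value = wn / wd if wd != 0 else float("nan")
            rows.append(
                {"chrom": chrom, "start": start, "end": end, "value": value,
                 "n_sites": int(hi - lo), "statistic": statistic}
            )
            nums.append(wn)
            dens.append(abs(wd))
    genome = weighted_block_jackknife(np.array(nums), np.array(dens))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "n_sites", "statistic"])
    if np.isfinite(genome.se) and genome.se > 0:
        df["significant"] = df["value"].abs() > z_threshold * genome.se
    else:
        df["significant"] = False
    return df, genome


# ---------------------------------------------------------------------------
# time scaling


@dataclass
class TimeScale:
    generations: float
    generation_time: float
    years: float
    ka: float


def generations_to_years(generations: float, generation_time: float = 21.0) -> TimeScale:
    """Scale a generation count to years and ka (one decimal, half away)."""
    from .util import round_half_away

    if generations <= 0 or generation_time <= 0:
        raise ValueError("generations and generation_time must be positive")
    years = generations * generation_time
    return TimeScale(generations, generation_time, years, round_half_away(years / 1000.0, 1))


def years_to_generations(years: float, generation_time: float = 21.0) -> float:
    if years <= 0 or generation_time <= 0:
        raise ValueError("years and generation_time must be positive")
    return years / generation_time
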