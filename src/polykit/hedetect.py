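"""Homoeologous-exchange detection from subgenome read depth.

The chain is: per-gene subgenome coverage -> 10-gene sliding-window
allele balance A = 4 * (CC/(CC+EE) - 0.5) -> per-window dosage class
(thresholds +/-1.5 homozygous, +/-0.5 balanced) -> maximal-run
segmentation -> chi-squared 3:1 tests with Bonferroni control ->
cross-accession shared/private intervals -> HE-pair filtering for the
expression analyses.

Dosage-class names: the homozygous (|A| > 1.5) and balanced (|A| < 0.5)
bands follow the published thresholds; the intermediate bands are named
CC_biased / EE_biased here (3:1-like states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CLASS_ORDER = ("EE_hom", "EE_biased", "balanced", "CC_biased", "CC_hom")
CC_WARD = ("CC_biased", "CC_hom")
EE_WARD = ("EE_biased", "EE_hom")


# ---------------------------------------------------------------------------
# coverage


def gene_coverage_from_depth(
    depth: pd.DataFrame, genes: pd.DataFrame, syntelogs: pd.DataFrame
) -> pd.DataFrame:
    """Mean per-gene depth from a per-base depth track, paired by syntelog.

    ``depth`` holds BED-style rows (chrom, start, end, depth; 0-based
    half-open, constant depth per row); ``genes`` holds 1-based
    inclusive gene models (gene_id, chrom, start, end).  Pairs missing
    a side keep the present side's depth and NaN on the other, which
    excludes them from the allele-balance computation downstream.
    """
    means = _gene_means(depth, genes)
    out = syntelogs[["pair_id", "chrom", "ancestral_index", "gene_cc", "gene_ee"]].copy()
    out["cc_depth"] = [means.get(g, np.nan) for g in out["gene_cc"]]
    out["ee_depth"] = [means.get(g, np.nan) for g in out["gene_ee"]]
    return out[["pair_id", "chrom", "ancestral_index", "cc_depth", "ee_depth"]]


def _gene_means(depth: pd.DataFrame, genes: pd.DataFrame) -> dict[str, float]:
    means: dict[str, float] = {}
    for chrom, chrom_depth in depth.groupby("chrom", sort=False):
        chrom_depth = chrom_depth.sort_values("start")
        starts = chrom_depth["start"].to_numpy(dtype=np.int64)
        ends = chrom_depth["end"].to_numpy(dtype=np.int64)
        vals = chrom_depth["depth"].to_numpy(dtype=float)
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping depth intervals on {chrom}")
        cum = np.concatenate([[0.0], np.cumsum(vals * (ends - starts))])
        for _, g in genes[genes["chrom"] == chrom].iterrows():
            gs, ge = int(g["start"]) - 1, int(g["end"])  # to 0-based half-open
            if ge <= gs:
                raise ValueError(f"gene {g['gene_id']} has zero-length span")
            lo = np.searchsorted(ends, gs, side="right")
            hi = np.searchsorted(starts, ge, side="left")
            if lo >= hi:
                raise ValueError(f"no depth data covering gene {g['gene_id']}")
            total = cum[hi] - cum[lo]
            total -= vals[lo] * max(gs - starts[lo], 0)
            total -= vals[hi - 1] * max(ends[hi - 1] - ge, 0)
            means[g["gene_id"]] = total / (ge - gs)
    return means


# ---------------------------------------------------------------------------
# allele balance


def allele_balance(cc, ee):
    """A = 4 * (CC / (CC + EE) - 0.5); NaN where CC + EE == 0."""
    cc = np.asarray(cc, dtype=float)
    ee = np.asarray(ee, dtype=float)
    total = cc + ee
    with np.errstate(invalid="ignore", divide="ignore"):
        a = 4.0 * (cc / total - 0.5)
    return np.where(total > 0, a, np.nan)


def windowed_balance(profile: pd.DataFrame, window_genes: int = 10) -> pd.DataFrame:
    """Sliding-window (step 1) mean coverages and allele balance.

    ``profile`` needs chrom, ancestral_index, cc_depth, ee_depth,
    ordered by ancestral index, one row per retained pair.  Pairs with
    a missing side (NaN depth) are dropped before windowing.  A
    chromosome shorter than the window yields a single partial window
    flagged in the ``partial`` column.
    """
    if window_genes < 1:
        raise ValueError("window_genes must be >= 1")
    rows = []
    usable = profile.dropna(subset=["cc_depth", "ee_depth"])
    for chrom, sub in usable.groupby("chrom", sort=False):
        sub = sub.sort_values("ancestral_index")
        cc = sub["cc_depth"].to_numpy(dtype=float)
        ee = sub["ee_depth"].to_numpy(dtype=float)
        idx = sub["ancestral_index"].to_numpy()
        n = len(sub)
        w = min(window_genes, n)
        kernel = np.ones(w) / w
        mean_cc = np.convolve(cc, kernel, mode="valid")
        mean_ee = np.convolve(ee, kernel, mode="valid")
        a = allele_balance(mean_cc, mean_ee)
        for k in range(n - w + 1):
            rows.append(
                {
                    "chrom": chrom,
                    "win_start": int(idx[k]),
                    "center_index": int(idx[k + w // 2]) if k + w // 2 < n else int(idx[-1]),
                    "mean_cc": mean_cc[k],
                    "mean_ee": mean_ee[k],
                    "A": a[k],
                    "partial": w < window_genes,
                }
            )
    track = pd.DataFrame(
        rows, columns=["chrom", "win_start", "center_index", "mean_cc", "mean_ee", "A", "partial"]
    )
    track.attrs["window_genes"] = window_genes
    return track


def classify_balance(a):
    """Dosage class from allele balance; NaN maps to ``no_data``.

    A > 1.5 -> CC_hom, A < -1.5 -> EE_hom, |A| < 0.5 -> balanced,
    0.5 <= A <= 1.5 -> CC_biased, -1.5 <= A <= -0.5 -> EE_biased.
    """
    arr = np.asarray(a, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.select(
        [
            np.isnan(arr),
            arr > 1.5,
            arr < -1.5,
            np.abs(arr) < 0.5,
            arr >= 0.5,
        ],
        ["no_data", "CC_hom", "EE_hom", "balanced", "CC_biased"],
        default="EE_biased",
    )
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# segmentation


def segment_dosage(
    track: pd.DataFrame,
    min_windows: int = 5,
    accession: str | None = None,
    profile: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge classified windows into non-overlapping dosage segments.

    Each gene takes the class of the window centered on it (edge genes
    take the nearest window's class); maximal same-class gene runs
    shorter than ``min_windows`` are absorbed into the balanced
    background, then adjacent same-class runs merge.  Gene ranges are
    half-open ancestral-index intervals.

    When the per-gene ``profile`` that produced the track is supplied,
    segment boundaries are refined on per-gene allele balance, which
    undoes the window smearing (one window can span many ancestral
    indices where fractionation thinned the retained pairs).
    """
    window = track.attrs.get("window_genes", 10)
    segments = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("win_start")
        centers = sub["center_index"].to_numpy()
        classes = classify_balance(sub["A"].to_numpy())
        a_vals = sub["A"].to_numpy()
        first_gene = int(sub["win_start"].iloc[0])
        last_gene = int(sub["win_start"].iloc[-1]) + window - 1
        genes = np.arange(first_gene, last_gene + 1)
        nearest = np.clip(np.searchsorted(centers, genes), 0, len(centers) - 1)
        left = np.clip(nearest - 1, 0, len(centers) - 1)
        use_left = np.abs(centers[left] - genes) <= np.abs(centers[nearest] - genes)
        gene_class = np.where(use_left, classes[left], classes[nearest])

        gene_a = np.where(use_left, a_vals[left], a_vals[nearest])
        refine_a = gene_a
        if profile is not None:
            on = profile["chrom"] == chrom
            per_gene = np.full(genes.size, np.nan)
            gi = profile.loc[on, "ancestral_index"].to_numpy() - first_gene
            inside = (gi >= 0) & (gi < genes.size)
            per_gene[gi[inside]] = allele_balance(
                profile.loc[on, "cc_depth"].to_numpy()[inside],
                profile.loc[on, "ee_depth"].to_numpy()[inside],
            )
            refine_a = per_gene
        labels = _smooth_labels(gene_class.copy(), min_windows)
        labels = _split_transition_bands(labels, gene_a, window)
        labels = _smooth_labels(labels, min_windows)
        labels = _refine_boundaries(labels, refine_a, window)
        labels = _smooth_labels(labels, min_windows)
        for start, end, label in _runs(labels):
            seg_genes = genes[start:end]
            in_seg = (centers >= seg_genes[0]) & (centers <= seg_genes[-1])
            mean_a = float(np.nanmean(a_vals[in_seg])) if in_seg.any() else float("nan")
            segments.append(
                {
                    "accession": accession or "",
                    "chrom": chrom,
                    "start_gene": int(seg_genes[0]),
                    "end_gene": int(seg_genes[-1]) + 1,
                    "dosage_class": label,
                    "mean_A": mean_a,
                    "n_windows": int(in_seg.sum()),
                }
            )
    return pd.DataFrame(
        segments,
        columns=["accession", "chrom", "start_gene", "end_gene", "dosage_class", "mean_A", "n_windows"],
    )


_CLASS_RANK = {c: i for i, c in enumerate(CLASS_ORDER)}


def _split_transition_bands(labels: np.ndarray, gene_a: np.ndarray, window: int) -> np.ndarray:
    """Remove smoothing artifacts at sharp dosage boundaries.

    A run no longer than the window whose class lies strictly between
    its two flanking classes (in dosage order) is the signature of the
    sliding-window mean traversing intermediate balance values; its
    genes are reassigned to the nearer flank by allele-balance
    distance, splitting at the first crossing of the flank midpoint.
    """
    runs = _runs(labels)
    for i in range(1, len(runs) - 1):
        start, end, label = runs[i]
        l_label, r_label = runs[i - 1][2], runs[i + 1][2]
        if any(x not in _CLASS_RANK for x in (label, l_label, r_label)):
            continue
        lr, mr, rr = _CLASS_RANK[l_label], _CLASS_RANK[label], _CLASS_RANK[r_label]
        # fractionation gaps stretch a window's ancestral span, so allow
        # transition bands up to three times the window gene count
        if end - start > 3 * window or not (lr < mr < rr or lr > mr > rr):
            continue
        a_left = np.nanmean(gene_a[runs[i - 1][0]:runs[i - 1][1]])
        a_right = np.nanmean(gene_a[runs[i + 1][0]:runs[i + 1][1]])
        midpoint = (a_left + a_right) / 2.0
        toward_right = (
            gene_a[start:end] >= midpoint if a_right > a_left else gene_a[start:end] <= midpoint
        )
        crossing = np.flatnonzero(toward_right)
        cut = start + (int(crossing[0]) if crossing.size else end - start)
        labels[start:cut] = l_label
        labels[cut:end] = r_label
    return labels


def _refine_boundaries(labels: np.ndarray, gene_a: np.ndarray, window: int) -> np.ndarray:
    """Least-squares changepoint fit at every boundary between runs.

    The sliding-window mean blurs each dosage boundary over roughly one
    window span; within +/-2 windows of each boundary (capped at the
    neighboring runs' midpoints) the cut is re-placed to minimize the
    squared distance of per-gene balance values to the two run means.
    """
    runs = _runs(labels)
    out = labels.copy()
    for i in range(len(runs) - 1):
        ls, le, l_label = runs[i]
        rs, re, r_label = runs[i + 1]
        if l_label not in _CLASS_RANK or r_label not in _CLASS_RANK:
            continue
        a_left = np.nanmean(gene_a[ls:le])
        a_right = np.nanmean(gene_a[rs:re])
        if not (np.isfinite(a_left) and np.isfinite(a_right)) or a_left == a_right:
            continue
        lo = max(le - 2 * window, (ls + le) // 2)
        hi = min(rs + 2 * window, (rs + re + 1) // 2)
        seg = gene_a[lo:hi]
        seg = np.where(np.isfinite(seg), seg, (a_left + a_right) / 2.0)
        cum_l = np.concatenate([[0.0], np.cumsum((seg - a_left) ** 2)])
        cum_r = np.concatenate([[0.0], np.cumsum((seg - a_right) ** 2)])
        cost = cum_l + (cum_r[-1] - cum_r)
        cut = lo + int(np.argmin(cost))
        out[lo:cut] = l_label
        out[cut:hi] = r_label
    return out


def _smooth_labels(labels: np.ndarray, min_windows: int) -> np.ndarray:
    """Absorb runs shorter than ``min_windows`` into a flanking run.

    Shortest runs go first; a short run takes the label of its longer
    neighbor (ties and edges fall back to the balanced background).
    Deterministic, and terminates because every merge grows a run.
    """
    while True:
        runs = _runs(labels)
        short = [
            (end - start, i)
            for i, (start, end, _) in enumerate(runs)
            if end - start < min_windows
        ]
        if not short or len(runs) == 1:
            break
        _, i = min(short)
        start, end, _ = runs[i]
        left_len = runs[i - 1][1] - runs[i - 1][0] if i > 0 else -1
        right_len = runs[i + 1][1] - runs[i + 1][0] if i + 1 < len(runs) else -1
        if left_len > right_len:
            labels[start:end] = runs[i - 1][2]
        elif right_len > left_len:
            labels[start:end] = runs[i + 1][2]
        elif i > 0 and i + 1 < len(runs) and runs[i - 1][2] == runs[i + 1][2]:
            labels[start:end] = runs[i - 1][2]
        else:
            labels[start:end] = "balanced"
    return labels


def _runs(labels: np.ndarray):
    """Yield (start, end, label) for maximal equal-label runs."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, labels[start]))
            start = i
    return out


# ---------------------------------------------------------------------------
# 3:1 test


@dataclass
class HETestResult:
    cc_count: int
    ee_count: int
    expected_ratio: tuple[int, int]
    chi2: float
    df: int
    p_raw: float
    p_bonferroni: float
    n_tests: int
    direction: str  # "cc" | "ee" | "none" relative to the expected ratio
    significant: bool


def test_3to1(
    cc_count: int,
    ee_count: int,
    ratio: tuple[int, int] = (3, 1),
    n_tests: int = 1,
    alpha: float = 0.0005,
) -> HETestResult:
    """Chi-squared (df = 1) test of CC:EE counts against a dosage ratio.

    Bonferroni adjustment multiplies by ``n_tests``; the published
    significance threshold is adjusted p < 0.0005.
    """
    total = cc_count + ee_count
    if cc_count < 0 or ee_count < 0 or total == 0:
        raise ValueError("counts must be nonnegative with a positive total")
    frac_cc = ratio[0] / (ratio[0] + ratio[1])
    expected = np.array([frac_cc * total, (1 - frac_cc) * total])
    observed = np.array([cc_count, ee_count], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p_raw = float(stats.chi2.sf(chi2, df=1))
    p_bonf = min(1.0, p_raw * n_tests)
    if cc_count / total > frac_cc:
        direction = "cc"
    elif cc_count / total < frac_cc:
        direction = "ee"
    else:
        direction = "none"
    return HETestResult(
        cc_count=int(cc_count),
        ee_count=int(ee_count),
        expected_ratio=tuple(ratio),
        chi2=chi2,
        df=1,
        p_raw=p_raw,
        p_bonferroni=p_bonf,
        n_tests=int(n_tests),
        direction=direction,
        significant=p_bonf < alpha,
    )


def test_segments(
    segments: pd.DataFrame,
    profiles: dict[str, pd.DataFrame],
    ratio: tuple[int, int] = (3, 1),
    alpha: float = 0.0005,
) -> pd.DataFrame:
    """Run the dosage test over every non-balanced segment.

    Counts are the integerized sums of mean gene depths inside the
    segment (depth as read-count proxy); n_tests for Bonferroni is the
    number of segments tested across all accessions in this call.
    """
    tested = segments[~segments["dosage_class"].isin(("balanced", "no_data"))]
    n_tests = len(tested)
    rows = []
    for _, seg in tested.iterrows():
        prof = profiles[seg["accession"]]
        mask = (
            (prof["chrom"] == seg["chrom"]).to_numpy()
            & (prof["ancestral_index"].to_numpy() >= seg["start_gene"])
            & (prof["ancestral_index"].to_numpy() < seg["end_gene"])
        )
        cc = int(round(prof.loc[mask, "cc_depth"].sum()))
        ee = int(round(prof.loc[mask, "ee_depth"].sum()))
        res = test_3to1(cc, ee, ratio=ratio, n_tests=n_tests, alpha=alpha)
        rows.append(
            {
                "accession": seg["accession"],
                "chrom": seg["chrom"],
                "start_gene": seg["start_gene"],
                "end_gene": seg["end_gene"],
                "dosage_class": seg["dosage_class"],
                "cc_count": res.cc_count,
                "ee_count": res.ee_count,
                "chi2": res.chi2,
                "p_raw": res.p_raw,
                "p_bonferroni": res.p_bonferroni,
                "direction": res.direction,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "chrom", "start_gene", "end_gene", "dosage_class",
            "cc_count", "ee_count", "chi2", "p_raw", "p_bonferroni",
            "direction", "significant",
        ],
    )


# ---------------------------------------------------------------------------
# cross-accession segments


def shared_segments(
    segments: pd.DataFrame, min_share: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split non-balanced intervals into shared and private sets.

    A gene index belongs to the shared set for a dosage class when at
    least ``min_share`` accessions carry that class there; positions
    carried by fewer (but at least one) accessions are private.
    Implemented as a per-gene vote over half-open segment intervals.
    """
    accs = segments["accession"].unique()
    if len(accs) < 2:
        raise ValueError("need segments from at least 2 accessions")
    active = segments[~segments["dosage_class"].isin(("balanced", "no_data"))]
    shared_rows, private_rows = [], []
    for (chrom, klass), sub in active.groupby(["chrom", "dosage_class"], sort=False):
        hi = int(sub["end_gene"].max())
        counts = np.zeros(hi + 1, dtype=np.int64)
        for _, seg in sub.iterrows():
            counts[int(seg["start_gene"]):int(seg["end_gene"])] += 1
        for mask, sink in ((counts >= min_share, shared_rows),
                           ((counts > 0) & (counts < min_share), private_rows)):
            for start, end in _bool_runs(mask):
                sink.append(
                    {"chrom": chrom, "start_gene": start, "end_gene": end,
                     "dosage_class": klass,
                     "n_accessions": int(counts[start:end].max())}
                )
    cols = ["chrom", "start_gene", "end_gene", "dosage_class", "n_accessions"]
    return pd.DataFrame(shared_rows, columns=cols), pd.DataFrame(private_rows, columns=cols)


def _bool_runs(mask: np.ndarray):
    from .util import merge_index_runs

    return merge_index_runs(mask)


def filter_he_pairs(
    pairs: pd.DataFrame, segments: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop syntelog pairs inside any non-balanced segment of any accession.

    Returns (filtered pairs, removal log).
    """
    active = segments[~segments["dosage_class"].isin(("balanced", "no_data"))]
    removed = np.zeros(len(pairs), dtype=bool)
    reason = np.full(len(pairs), "", dtype=object)
    chrom = pairs["chrom"].to_numpy()
    idx = pairs["ancestral_index"].to_numpy()
    for _, seg in active.iterrows():
        mask = (
            (chrom == seg["chrom"])
            & (idx >= seg["start_gene"])
            & (idx < seg["end_gene"])
        )
        newly = mask & ~removed
        reason[newly] = f"{seg['accession']}:{seg['dosage_class']}"
        removed |= mask
    log = pairs.loc[removed, ["pair_id", "chrom", "ancestral_index"]].copy()
    log["reason"] = reason[removed]
    return pairs.loc[~removed].copy(), log


def he_direction_summary(segments: pd.DataFrame, binomial: bool = False) -> pd.DataFrame:
    """Per-accession counts of genes in CC-ward vs EE-ward segments.

    ``ratio`` is CC-ward / EE-ward gene counts (inf when no EE-ward
    genes).  With ``binomial=True`` adds a two-sided exact test against
    an even split.
    """
    rows = []
    for acc, sub in segments.groupby("accession", sort=False):
        lengths = (sub["end_gene"] - sub["start_gene"]).to_numpy()
        cc = int(lengths[sub["dosage_class"].isin(CC_WARD).to_numpy()].sum())
        ee = int(lengths[sub["dosage_class"].isin(EE_WARD).to_numpy()].sum())
        row = {
            "accession": acc,
            "cc_ward_genes": cc,
            "ee_ward_genes": ee,
            "ratio": (cc / ee) if ee else float("inf") if cc else float("nan"),
        }
        if binomial and cc + ee > 0:
            row["p_binomial"] = float(stats.binomtest(cc, cc + ee, 0.5).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
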