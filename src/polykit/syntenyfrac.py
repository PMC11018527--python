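"""Fractionation and dating statistics over syntelog tables.

A syntelog table has one row per ancestral gene position (see
``core.SYNTELOG_COLUMNS``).  "Retained on a side" means the gene is
still present on that side: a ``status`` of ``ee_only`` marks a CC-side
deletion and vice versa.  Runs and windows are computed in ancestral
gene-index space and never span block boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .util import merge_index_runs

SIDES = ("cc", "ee")


def _retained_on(syntelogs: pd.DataFrame, side: str) -> np.ndarray:
    if side not in SIDES:
        raise ValueError(f"side must be 'cc' or 'ee', got {side!r}")
    lost = "ee_only" if side == "cc" else "cc_only"
    return (syntelogs["status"] != lost).to_numpy()


def retention_rate_track(
    syntelogs: pd.DataFrame,
    side: str,
    window_genes: int = 100,
    step_genes: int | None = None,
) -> pd.DataFrame:
    """Sliding-window gene retention rate along ancestral order.

    Windows are gene-index based; the trailing partial window is
    included with its true ``n_genes``.  Returns columns chrom,
    start_index, end_index (half-open), retention_rate, n_genes.
    """
    if window_genes < 1 or (step_genes is not None and step_genes < 1):
        raise ValueError("window_genes and step_genes must be >= 1")
    if syntelogs.empty:
        raise ValueError("empty syntelog table")
    step = step_genes or window_genes
    rows = []
    for block_id, block in syntelogs.groupby("block_id", sort=False):
        block = block.sort_values("ancestral_index")
        retained = _retained_on(block, side).astype(np.int64)
        idx = block["ancestral_index"].to_numpy()
        n = len(block)
        cum = np.concatenate([[0], np.cumsum(retained)])
        for start in range(0, n, step):
            end = min(start + window_genes, n)
            k = int(cum[end] - cum[start])
            rows.append(
                {
                    "block_id": block_id,
                    "chrom": block["chrom"].iloc[0],
                    "start_index": int(idx[start]),
                    "end_index": int(idx[end - 1]) + 1,
                    "retention_rate": k / (end - start),
                    "n_genes": end - start,
                }
            )
            if end >= n:
                break
    return pd.DataFrame(rows)


def deletion_run_spectrum(syntelogs: pd.DataFrame) -> dict[str, dict[int, int]]:
    """Histogram of maximal same-side deletion run lengths, per side."""
    spectrum: dict[str, dict[int, int]] = {"cc": {}, "ee": {}}
    if syntelogs.empty:
        return spectrum
    for _, block in syntelogs.groupby("block_id", sort=False):
        block = block.sort_values("ancestral_index")
        for side in SIDES:
            deleted = ~_retained_on(block, side)
            for start, end in merge_index_runs(deleted):
                length = end - start
                spectrum[side][length] = spectrum[side].get(length, 0) + 1
    return spectrum


def intergenic_gap_profile(syntelogs: pd.DataFrame) -> pd.DataFrame:
    """Mean bp spanned by fractionation gaps versus their homoeologous span.

    For each maximal deletion run flanked by retained genes on its own
    side, the deleted-side gap is the bp between the flanking retained
    genes (exclusive); the unfractionated comparison is the same
    interval measured between the homoeologs on the retained side.
    Runs touching block edges are skipped.  Returns one row per run
    length with mean gap bp on each side and the run count.
    """
    records: list[tuple[int, float, float]] = []
    for _, block in syntelogs.groupby("block_id", sort=False):
        block = block.sort_values("ancestral_index").reset_index(drop=True)
        for side in SIDES:
            other = "ee" if side == "cc" else "cc"
            deleted = ~_retained_on(block, side)
            for start, end in merge_index_runs(deleted):
                if start == 0 or end == len(block):
                    continue
                prev_row, next_row = block.iloc[start - 1], block.iloc[end]
                gap_deleted = float(next_row[f"{side}_start"] - prev_row[f"{side}_end"] - 1)
                gap_retained = float(next_row[f"{other}_start"] - prev_row[f"{other}_end"] - 1)
                if np.isnan(gap_deleted) or np.isnan(gap_retained):
                    raise ValueError("missing coordinates for genes flanking a deletion run")
                records.append((end - start, gap_deleted, gap_retained))
    if not records:
        return pd.DataFrame(
            columns=["run_length", "mean_gap_bp_deleted_side", "mean_bp_unfractionated", "n_runs"]
        )
    df = pd.DataFrame(records, columns=["run_length", "deleted", "retained"])
    out = (
        df.groupby("run_length")
        .agg(
            mean_gap_bp_deleted_side=("deleted", "mean"),
            mean_bp_unfractionated=("retained", "mean"),
            n_runs=("deleted", "size"),
        )
        .reset_index()
    )
    return out


@dataclass
class FisherResult:
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False


def fisher_test(table) -> FisherResult:
    arr = np.asarray(table, dtype=np.int64)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return FisherResult(float("nan"), 1.0, tuple(map(tuple, arr)), degenerate=True)
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return FisherResult(float(odds), float(p), tuple(map(tuple, arr)))


def retention_origin_enrichment(
    track: pd.DataFrame,
    syntelogs: pd.DataFrame,
    side: str,
    origin: str = "wgd",
    high_q: float = 0.8,
) -> FisherResult:
    """Fisher test: are high-retention windows enriched for an origin class?

    Genes are placed in the high-retention stratum when the mean
    retention of the track windows covering them is at or above the
    ``high_q`` quantile of window values.  The 2x2 table crosses that
    stratum with ``origin_class == origin`` over genes that carry a
    label.
    """
    labeled = syntelogs[syntelogs["origin_class"] != ""].copy()
    if labeled.empty:
        raise ValueError("origin_class labels are required")
    cutoff = np.quantile(track["retention_rate"].to_numpy(), high_q)
    per_gene = _gene_window_means(track, labeled)
    high = per_gene >= cutoff
    is_origin = (labeled["origin_class"] == origin).to_numpy()
    table = [
        [int((high & is_origin).sum()), int((high & ~is_origin).sum())],
        [int((~high & is_origin).sum()), int((~high & ~is_origin).sum())],
    ]
    return fisher_test(table)


def _gene_window_means(track: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    values = np.full(len(genes), np.nan)
    counts = np.zeros(len(genes))
    sums = np.zeros(len(genes))
    gi = genes["ancestral_index"].to_numpy()
    gb = genes["block_id"].to_numpy()
    for _, w in track.iterrows():
        mask = (gb == w["block_id"]) & (gi >= w["start_index"]) & (gi < w["end_index"])
        sums[mask] += w["retention_rate"]
        counts[mask] += 1
    nonzero = counts > 0
    values[nonzero] = sums[nonzero] / counts[nonzero]
    return values


def ks_density_peaks(
    ks_values, bandwidth: float | None = None, grid_points: int = 512
) -> list[tuple[float, float]]:
    """Local maxima of a Gaussian KDE over synonymous divergences.

    Default bandwidth is Silverman's rule of thumb; an explicit
    ``bandwidth`` is the absolute kernel standard deviation.  The KDE
    is evaluated on a fixed grid over ``[0, max * 1.05]`` and peaks are
    returned sorted by density, descending.
    """
    values = np.asarray(ks_values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 finite Ks values")
    if (values < 0).any():
        raise ValueError("Ks values must be nonnegative")
    if np.ptp(values) == 0:
        return [(float(values[0]), float("inf"))]
    if bandwidth is None:
        kde = stats.gaussian_kde(values, bw_method="silverman")
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        kde = stats.gaussian_kde(values, bw_method=bandwidth / values.std(ddof=1))
    grid = np.linspace(0.0, values.max() * 1.05, grid_points)
    density = kde(grid)
    interior = np.flatnonzero(
        (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    ) + 1
    peaks = [(float(grid[i]), float(density[i])) for i in interior]
    peaks.sort(key=lambda t: -t[1])
    return peaks


def ltr_age(divergence, rate: float, jukes_cantor: bool = False):
    """Insertion age T = d / (2 * rate) from LTR divergence.

    ``jukes_cantor=True`` applies d' = -3/4 ln(1 - 4d/3) first; off by
    default so raw divergences map linearly onto time.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    d = np.asarray(divergence, dtype=float)
    if (d < 0).any():
        raise ValueError("divergence must be nonnegative")
    if jukes_cantor:
        d = -0.75 * np.log1p(-4.0 * d / 3.0)
    out = d / (2.0 * rate)
    return float(out) if out.ndim == 0 else out


def interval_overlap_test(
    set_a: pd.DataFrame, set_b: pd.DataFrame, units: pd.DataFrame
) -> FisherResult:
    """Fisher exact association between two interval sets over unit space.

    ``units`` partitions the universe (BED-style chrom/start/end rows,
    e.g. genes or fixed windows); each unit is classified by whether it
    overlaps any interval of A and of B.
    """
    if units.empty:
        raise ValueError("empty universe")
    in_a = _units_overlapping(units, set_a)
    in_b = _units_overlapping(units, set_b)
    table = [
        [int((in_a & in_b).sum()), int((in_a & ~in_b).sum())],
        [int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())],
    ]
    return fisher_test(table)


def _units_overlapping(units: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    hit = np.zeros(len(units), dtype=bool)
    if intervals is None or len(intervals) == 0:
        return hit
    us = units["start"].to_numpy()
    ue = units["end"].to_numpy()
    uc = units["chrom"].to_numpy()
    for _, iv in intervals.iterrows():
        hit |= (uc == iv["chrom"]) & (us < iv["end"]) & (ue > iv["start"])
    return hit
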