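"""Subgenome expression-bias assessment on HE-filtered syntelog pairs."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

LOG_OFFSET = 1e-4


def log_tpm(x):
    """log10(x + 1e-4) transform of TPM values; rejects negatives."""
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("TPM values must be nonnegative")
    out = np.log10(arr + LOG_OFFSET)
    return float(out) if out.ndim == 0 else out


def pair_bias(
    expression: pd.DataFrame,
    pairs: pd.DataFrame,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-pair CC/EE log10 expression ratio and bias class.

    ``expression`` is the gene-by-sample TPM table (``gene`` column
    plus sample columns); ``pairs`` should already be HE-filtered
    (``hedetect.filter_he_pairs``).  The mean over samples of
    ``log_tpm(cc) - log_tpm(ee)`` classifies a pair as CC or EE when
    its magnitude reaches ``log10(fold_threshold)``, else ``none``;
    pairs silent on both sides in every sample are ``undetermined``.
    Pairs with a missing member are skipped.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    sample_cols = [c for c in expression.columns if c != "gene"]
    if not sample_cols:
        raise ValueError("expression table has no sample columns")
    mat = expression.set_index("gene")[sample_cols]
    cutoff = np.log10(fold_threshold)
    rows = []
    for _, pair in pairs.iterrows():
        gc, ge = pair["gene_cc"], pair["gene_ee"]
        if not gc or not ge or gc not in mat.index or ge not in mat.index:
            continue
        cc = mat.loc[gc].to_numpy(dtype=float)
        ee = mat.loc[ge].to_numpy(dtype=float)
        ratio = log_tpm(cc) - log_tpm(ee)
        mean_ratio = float(np.mean(ratio))
        if (cc == 0).all() and (ee == 0).all():
            klass = "undetermined"
        elif mean_ratio >= cutoff:
            klass = "CC"
        elif mean_ratio <= -cutoff:
            klass = "EE"
        else:
            klass = "none"
        rows.append(
            {
                "pair_id": pair["pair_id"],
                "family": pair.get("family", ""),
                "mean_log_ratio": mean_ratio,
                "bias_class": klass,
                "fold_threshold": fold_threshold,
            }
        )
    return pd.DataFrame(
        rows, columns=["pair_id", "family", "mean_log_ratio", "bias_class", "fold_threshold"]
    )


def global_dominance_test(bias_results: pd.DataFrame) -> tuple[int, int, float]:
    """Exact two-sided binomial test of CC- vs EE-classed pair counts."""
    n_cc = int((bias_results["bias_class"] == "CC").sum())
    n_ee = int((bias_results["bias_class"] == "EE").sum())
    if n_cc + n_ee == 0:
        raise ValueError("no classified pairs to test")
    p = float(stats.binomtest(n_cc, n_cc + n_ee, 0.5, alternative="two-sided").pvalue)
    return n_cc, n_ee, p


def family_mosaic_summary(bias_results: pd.DataFrame) -> pd.DataFrame:
    """Per-family bias tallies; mosaic = has both CC- and EE-biased pairs."""
    rows = []
    for family, sub in bias_results.groupby("family", sort=True):
        n_cc = int((sub["bias_class"] == "CC").sum())
        n_ee = int((sub["bias_class"] == "EE").sum())
        n_none = int((sub["bias_class"] == "none").sum())
        rows.append(
            {
                "family": family,
                "n_cc": n_cc,
                "n_ee": n_ee,
                "n_none": n_none,
                "mosaic": n_cc >= 1 and n_ee >= 1,
            }
        )
    return pd.DataFrame(rows, columns=["family", "n_cc", "n_ee", "n_none", "mosaic"])
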