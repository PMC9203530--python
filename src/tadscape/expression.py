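"""Binned expression: CPM normalization, the tau tissue-specificity index,
twofold expression classes, and conservation-vs-expression tests.

Expression is quantified per genomic bin (not per gene): read counts per bin
are normalized to counts per million (CPM) per sample, replicates are
averaged into tissue values, and a bin is *testable* when its tissue-mean
CPM exceeds 0.5 in at least one of the compared tissues.

Tau measures tissue specificity:  tau = sum_i (1 - r_i) / (n - 1)  with
r_i = x_i / max(x) over the n tissues; 0 for uniform expression, 1 for
strictly single-tissue expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TauResult:
    tau: float
    n_tissues: int
    r: np.ndarray


def bin_cpm(
    counts: pd.DataFrame, sample_tissue: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CPM per sample and tissue-mean CPM (replicates averaged).

    ``counts``: bins x samples (integer counts; index = bin ids).  Returns
    ``(cpm, tissue_cpm)``.  A zero library size is an error.
    """
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    cpm = counts / lib * 1e6
    tissues = {}
    for sample, tissue in sample_tissue.items():
        tissues.setdefault(tissue, []).append(sample)
    tissue_cpm = pd.DataFrame(
        {t: cpm[cols].mean(axis=1) for t, cols in tissues.items()}
    )
    return cpm, tissue_cpm


def testable_mask(
    tissue_cpm: pd.DataFrame, tissues: list[str] | None = None, threshold: float = 0.5
) -> pd.Series:
    """Bins with tissue-mean CPM strictly above ``threshold`` in >= 1 of the
    compared tissues (all tissues when ``tissues`` is None)."""
    sub = tissue_cpm if tissues is None else tissue_cpm[tissues]
    return (sub > threshold).any(axis=1)


def tau_index(tissue_values) -> TauResult:
    """Tissue-specificity index tau = sum(1 - r_i) / (n - 1), r_i = x_i/max.

    Requires n >= 2 nonnegative values with a positive maximum (an all-zero
    vector is undefined).
    """
    x = np.asarray(tissue_values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of >= 2 tissue values")
    if (x < 0).any():
        raise ValueError("expression values must be nonnegative")
    m = x.max()
    if m == 0:
        raise ValueError("all-zero expression vector: tau undefined")
    r = x / m
    tau = float((1.0 - r).sum() / (x.size - 1))
    return TauResult(tau, x.size, r)


def tau_per_bin(tissue_cpm: pd.DataFrame, mask: pd.Series | None = None) -> pd.Series:
    """Tau for each (testable) bin; bins failing the mask get NaN."""
    vals = tissue_cpm.to_numpy(dtype=float)
    m = vals.max(axis=1)
    ok = m > 0
    if mask is not None:
        ok &= mask.to_numpy()
    tau = np.full(len(tissue_cpm), np.nan)
    n = vals.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = vals[ok] / m[ok, None]
        tau[ok] = (1.0 - r).sum(axis=1) / (n - 1)
    return pd.Series(tau, index=tissue_cpm.index, name="tau")


def fold_change_classes(
    cpm_t1: pd.Series, cpm_t2: pd.Series, fold: float = 2.0, pseudocount: float = 0.25
) -> pd.DataFrame:
    """Classify bins into up / down / stable between two tissues.

    ratio = (cpm_t2 + eps) / (cpm_t1 + eps); "up" iff ratio > fold, "down"
    iff ratio < 1/fold, else "stable" (a ratio of exactly ``fold`` is
    stable).  Also returns |log2 ratio|.
    """
    ratio = (cpm_t2 + pseudocount) / (cpm_t1 + pseudocount)
    cls = pd.Series("stable", index=ratio.index, dtype=object)
    cls[ratio > fold] = "up"
    cls[ratio < 1.0 / fold] = "down"
    return pd.DataFrame(
        {"ratio": ratio, "class": cls, "abs_log2fc": np.abs(np.log2(ratio))}
    )


def conservation_expression_test(
    group_shared,
    group_specific,
    alternative: str = "shared_less",
    paired: bool = False,
) -> dict:
    """Compare an expression-variability metric between bins at shared vs
    tissue-specific structures.

    Default: one-sided Wilcoxon rank-sum (Mann-Whitney U) test of
    shared < specific on unpaired groups; a paired signed-rank variant is
    exposed for matched designs.  Returns group medians, the statistic and
    the p-value.
    """
    a = np.asarray(group_shared, dtype=float)
    b = np.asarray(group_specific, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    alt = {"shared_less": "less", "shared_greater": "greater", "two_sided": "two-sided"}[
        alternative
    ]
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal group sizes")
        res = stats.wilcoxon(a, b, alternative=alt)
    else:
        res = stats.mannwhitneyu(a, b, alternative=alt)
    return {
        "median_shared": float(np.median(a)),
        "median_specific": float(np.median(b)),
        "n_shared": int(a.size),
        "n_specific": int(b.size),
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "test": "wilcoxon_signed_rank" if paired else "wilcoxon_rank_sum",
        "alternative": alternative,
    }
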