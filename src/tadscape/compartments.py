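"""A/B compartments and hierarchical subcompartments from Hi-C correlation.

A/B assignment is the classical eigenvector method: the first principal
component of the covariance of the bin-by-bin Pearson correlation matrix,
with its sign oriented so that the gene-dense side is "A".  Subcompartments
come from a recursive bisection of the same signal: level 1 splits A from B,
and each part is re-bisected on its own correlation submatrix down to eight
ranked labels (A1.1 = rank 8 ... B2.2 = rank 1).  The bisection is a
deliberately simple stand-in for likelihood-based nested-clustering tools:
downstream statistics consume only the ranked label vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contact import CorrelationMatrix

SUBCOMPARTMENT_LABELS = ("B2.2", "B2.1", "B1.2", "B1.1", "A2.2", "A2.1", "A1.2", "A1.1")
# rank r (1..8) <-> SUBCOMPARTMENT_LABELS[r - 1]

RANK_OF_LABEL = {lab: r + 1 for r, lab in enumerate(SUBCOMPARTMENT_LABELS)}


@dataclass
class CompartmentAssignment:
    """Per-bin A/B labels with the oriented PC1 values behind them."""

    labels: np.ndarray        # 'A' | 'B' | '' (masked)
    pc1: np.ndarray
    orientation_feature: str


@dataclass
class SubcompartmentAssignment:
    """Per-bin ranked subcompartment labels from nested bisection."""

    labels: np.ndarray        # e.g. 'A1.2'; '' for masked bins
    ranks: np.ndarray         # 8 (A1.1) down to 1 (B2.2); 0 for masked
    level: int


def _pc1(values: np.ndarray) -> np.ndarray:
    """First principal component scores of the covariance of a matrix's rows."""
    cov = np.cov(values)
    w, v = np.linalg.eigh(cov)
    if w[-1] <= 0 or np.isclose(w[-1], 0):
        raise ValueError("degenerate PC1: leading eigenvalue is zero")
    return v[:, -1]


def _bisect(values: np.ndarray, track: np.ndarray) -> np.ndarray:
    """Split rows by the sign of oriented PC1; True = high-track side."""
    pc1 = _pc1(values)
    pos = pc1 > 0
    if pos.all() or (~pos).all():
        # PC1 does not change sign: fall back to a median split on scores so
        # recursion can proceed; rank ordering is still set by the track.
        pos = pc1 > np.median(pc1)
    mean_pos = track[pos].mean() if pos.any() else -np.inf
    mean_neg = track[~pos].mean() if (~pos).any() else -np.inf
    if mean_pos < mean_neg:
        pos = ~pos
    return pos


def call_ab(
    corr: CorrelationMatrix,
    orientation_track: pd.DataFrame,
    orientation_feature: str = "gene_density",
) -> CompartmentAssignment:
    """Assign A/B from PC1 of the covariance of the correlation matrix.

    The sign is fixed so bins with positive PC1 have the higher mean value of
    the orientation track (gene density orients A); masked bins stay
    unlabeled.
    """
    keep = corr.unmasked()
    track = _track_values(orientation_track, corr)
    sub = corr.values[np.ix_(keep, keep)]
    pc1_sub = _pc1(sub)
    t = track[keep]
    pos = pc1_sub > 0
    mean_pos = t[pos].mean() if pos.any() else np.nan
    mean_neg = t[~pos].mean() if (~pos).any() else np.nan
    if np.isfinite(mean_pos) and np.isfinite(mean_neg) and mean_pos < mean_neg:
        pc1_sub = -pc1_sub
    n = corr.n_bins
    pc1 = np.full(n, np.nan)
    pc1[keep] = pc1_sub
    labels = np.full(n, "", dtype=object)
    labels[keep] = np.where(pc1_sub > 0, "A", "B")
    return CompartmentAssignment(labels, pc1, orientation_feature)


def _track_values(track: pd.DataFrame, corr: CorrelationMatrix) -> np.ndarray:
    """Per-bin values of a (chrom, start, end, value) track for corr's chromosome."""
    bs = corr.layout.bin_size
    sub = track[track["chrom"] == corr.chrom]
    out = np.full(corr.n_bins, np.nan)
    idx = (sub["start"] // bs).to_numpy()
    out[idx] = sub["value"].to_numpy()
    if np.isnan(out[corr.unmasked()]).any():
        raise ValueError("orientation track does not cover all unmasked bins")
    return out


def call_subcompartments(
    corr: CorrelationMatrix,
    orientation_track: pd.DataFrame,
    levels: int = 3,
    orientation_feature: str = "gene_density",
) -> SubcompartmentAssignment:
    """Recursive PC1 bisection into ``2**levels`` ranked subcompartments.

    Level 1 reproduces :func:`call_ab`; each part is then re-bisected on its
    own correlation submatrix, the higher-orientation side taking the higher
    rank.  Parts that cannot be split (< 2 bins, or degenerate correlation)
    stop subdividing and inherit the parent label padded with ".1" to full
    depth.
    """
    if not 1 <= levels <= 3:
        raise ValueError("levels must be 1, 2, or 3")
    keep = corr.unmasked()
    if keep.sum() < 2**levels:
        raise ValueError(f"need >= {2**levels} unmasked bins")
    track = _track_values(orientation_track, corr)
    n = corr.n_bins

    ab = call_ab(corr, orientation_track, orientation_feature)
    paths = {}  # bin index -> list of split outcomes, True = high side
    for b in np.nonzero(keep)[0]:
        paths[b] = [ab.labels[b] == "A"]

    groups = {(True,): [], (False,): []}
    for b, p in paths.items():
        groups[tuple(p)].append(b)

    for level in range(2, levels + 1):
        new_groups = {}
        for key, bins in groups.items():
            bins = np.array(sorted(bins), dtype=int)
            split = None
            if bins.size >= 2:
                sub = corr.values[np.ix_(bins, bins)]
                sub = np.nan_to_num(sub, nan=0.0)
                try:
                    high = _bisect(sub, track[bins])
                    if high.any() and (~high).any():
                        split = high
                except ValueError:
                    split = None
            if split is None:
                # cannot subdivide: the whole part goes to the high child
                new_groups[key + (True,)] = list(bins)
                new_groups[key + (False,)] = []
            else:
                new_groups[key + (True,)] = list(bins[split])
                new_groups[key + (False,)] = list(bins[~split])
        groups = new_groups

    labels = np.full(n, "", dtype=object)
    ranks = np.zeros(n, dtype=int)
    for key, bins in groups.items():
        padded = key + (True,) * (3 - len(key))
        rank = 1 + sum(int(v) << (2 - i) for i, v in enumerate(padded))
        lab = SUBCOMPARTMENT_LABELS[rank - 1]
        if levels == 1:
            lab = lab[0]  # 'A' / 'B'
        elif levels == 2:
            lab = lab[:2]  # 'A1', 'A2', ...
        for b in bins:
            labels[b] = lab
            ranks[b] = rank
    return SubcompartmentAssignment(labels, ranks, levels)


def subcompartment_enrichment(
    assign: SubcompartmentAssignment, track: pd.DataFrame, corr: CorrelationMatrix
) -> pd.Series:
    """Per-label log2(median(track | label) / median(track | all labeled bins)).

    A small pseudocount (1e-9) guards zero medians; labels with no bins get
    NaN.  The statistic is invariant to positive scaling of the track.
    """
    eps = 1e-9
    vals = _track_values(track, corr)
    labeled = assign.ranks > 0
    overall = np.median(vals[labeled])
    out = {}
    for lab in sorted(set(assign.labels[labeled])):
        sel = assign.labels == lab
        med = np.median(vals[sel])
        out[lab] = float(np.log2((med + eps) / (overall + eps)))
    return pd.Series(out, name="log2_enrichment")


SHIFT_CATEGORIES = ("<-2", "-2", "-1", "0", "1", "2", ">2")


def switching_table(
    assign1: SubcompartmentAssignment, assign2: SubcompartmentAssignment
) -> dict:
    """Tabulate per-bin rank shifts between two subcompartment assignments.

    Shift = rank2 - rank1, binned into ``{<-2, -2, -1, 0, 1, 2, >2}`` over
    bins labeled in both assignments; also reports the level-1 A/B agreement
    fraction (A = ranks 5-8).  Proportions sum to 1.
    """
    if assign1.ranks.shape != assign2.ranks.shape:
        raise ValueError("assignments are on different binnings")
    both = (assign1.ranks > 0) & (assign2.ranks > 0)
    shift = assign2.ranks[both].astype(int) - assign1.ranks[both].astype(int)
    counts = {}
    counts["<-2"] = int((shift < -2).sum())
    counts["-2"] = int((shift == -2).sum())
    counts["-1"] = int((shift == -1).sum())
    counts["0"] = int((shift == 0).sum())
    counts["1"] = int((shift == 1).sum())
    counts["2"] = int((shift == 2).sum())
    counts[">2"] = int((shift > 2).sum())
    total = int(both.sum())
    props = {k: (v / total if total else float("nan")) for k, v in counts.items()}
    ab1 = assign1.ranks[both] > 4
    ab2 = assign2.ranks[both] > 4
    agreement = float((ab1 == ab2).mean()) if total else float("nan")
    return {
        "counts": counts,
        "proportions": props,
        "n_bins": total,
        "ab_agreement": agreement,
    }
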