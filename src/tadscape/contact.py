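"""Contact-matrix container, triplet I/O, balancing, O/E, correlation and
distance-stratified statistics.

A :class:`ContactMatrix` holds one chromosome's symmetric binned counts.
Balancing is iterative correction (Sinkhorn-style matrix scaling): bins are
rescaled until every unmasked row sums to the mean row sum, which is the
doubly-stochastic structure the downstream compartment and domain statistics
rely on.  Observed/expected divides each entry by the mean contact at its
diagonal offset, removing the distance-decay trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .layout import GenomeLayout


class FormatError(ValueError):
    """Malformed interchange file; message names the offending line."""


@dataclass
class ContactMatrix:
    """Symmetric nonnegative binned contact counts for one chromosome."""

    layout: GenomeLayout
    chrom: str
    counts: np.ndarray
    balance_weights: np.ndarray | None = None
    masked_bins: frozenset[int] = field(default_factory=frozenset)
    balanced_converged: bool = True

    def __post_init__(self):
        n = self.layout.n_bins(self.chrom)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({n}, {n}) for {self.chrom}"
            )
        if not np.allclose(self.counts, self.counts.T, equal_nan=True):
            raise ValueError("counts must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.counts) < 0:
                raise ValueError("counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def unmasked(self) -> np.ndarray:
        keep = np.ones(self.n_bins, dtype=bool)
        keep[list(self.masked_bins)] = False
        return keep


# ---------------------------------------------------------------------------
# Triplet TSV I/O
# ---------------------------------------------------------------------------
# Format: chrom <TAB> start1 <TAB> start2 <TAB> count, starts are 0-based bin
# starts; upper- or lower-triangle rows accepted, canonicalized on read.

def read_contact_matrix(path, layout: GenomeLayout, chrom: str | None = None) -> ContactMatrix:
    """Read a triplet TSV into a dense symmetric matrix.

    Rejects out-of-range bins, off-grid starts, negative counts and unknown
    chromosomes, naming the 1-based offending line.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start1", "start2", "count"],
        dtype={"chrom": str}, comment="#",
    )
    if df.empty:
        raise FormatError(f"{path}: no triplet rows")
    if chrom is None:
        uniq = df["chrom"].unique()
        if len(uniq) != 1:
            raise FormatError(f"{path}: multiple chromosomes, pass chrom explicitly")
        chrom = uniq[0]
    else:
        df = df[df["chrom"] == chrom]
    bs = layout.bin_size
    n = layout.n_bins(chrom)
    mat = np.zeros((n, n))
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        if not layout.has_chrom(row.chrom):
            raise FormatError(f"{path} line {line_no}: unknown chromosome {row.chrom!r}")
        if row.count < 0:
            raise FormatError(f"{path} line {line_no}: negative count {row.count}")
        if row.start1 % bs or row.start2 % bs:
            raise FormatError(f"{path} line {line_no}: start not on the {bs}-bp bin grid")
        i, j = row.start1 // bs, row.start2 // bs
        if not (0 <= i < n and 0 <= j < n):
            raise FormatError(f"{path} line {line_no}: bin out of range for {chrom}")
        i, j = min(i, j), max(i, j)
        mat[i, j] += row.count
    mat = np.triu(mat) + np.triu(mat, 1).T
    return ContactMatrix(layout, chrom, mat)


def write_contact_matrix(matrix: ContactMatrix, path) -> None:
    """Write the upper triangle (incl. diagonal) of nonzero entries, sorted."""
    bs = matrix.layout.bin_size
    iu, ju = np.nonzero(np.triu(matrix.counts))
    df = pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "start1": iu * bs,
            "start2": ju * bs,
            "count": matrix.counts[iu, ju],
        }
    ).sort_values(["start1", "start2"], kind="stable")
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Balancing (iterative correction)
# ---------------------------------------------------------------------------

def default_mask(counts: np.ndarray, low_coverage_quantile: float = 0.01) -> np.ndarray:
    """Bins to exclude: zero marginal, or bottom 1% of nonzero marginals."""
    marg = counts.sum(axis=0)
    mask = marg == 0
    nonzero_idx = np.nonzero(~mask)[0]
    k = int(low_coverage_quantile * nonzero_idx.size)
    if k > 0:
        order = nonzero_idx[np.argsort(marg[nonzero_idx], kind="stable")]
        mask[order[:k]] = True
    return mask


def balance_matrix(
    matrix: ContactMatrix,
    tol: float = 1e-5,
    max_iter: int = 200,
    mask_low_coverage: bool = True,
) -> ContactMatrix:
    """Iteratively correct so unmasked row sums equal the mean row sum.

    Returns a new :class:`ContactMatrix` carrying per-bin weights ``w`` with
    balanced counts ``w_i * w_j * counts[i, j]``.  Non-convergence within
    ``max_iter`` returns the best iterate with ``balanced_converged=False``
    and a warning.
    """
    counts = matrix.counts.astype(float)
    if mask_low_coverage:
        mask = default_mask(counts)
    else:
        mask = counts.sum(axis=0) == 0
    mask_idx = frozenset(np.nonzero(mask)[0].tolist()) | matrix.masked_bins
    mask = np.zeros(matrix.n_bins, dtype=bool)
    mask[list(mask_idx)] = True
    keep = ~mask
    if not keep.any():
        raise ValueError("all bins masked; nothing to balance")

    work = counts.copy()
    work[mask, :] = 0.0
    work[:, mask] = 0.0
    weights = np.ones(matrix.n_bins)
    converged = False
    for _ in range(max_iter):
        s = work.sum(axis=0)
        s_keep = s[keep]
        rel = np.abs(s_keep / s_keep.mean() - 1.0).max()
        if rel < tol:
            converged = True
            break
        adj = np.ones_like(s)
        adj[keep] = s_keep / s_keep.mean()
        work = work / np.outer(adj, adj)
        weights[keep] /= adj[keep]
    if not converged:
        s = work.sum(axis=0)[keep]
        if np.abs(s / s.mean() - 1.0).max() >= tol:
            warnings.warn(
                f"balancing did not converge in {max_iter} iterations; "
                "returning best iterate",
                RuntimeWarning,
                stacklevel=2,
            )
        else:
            converged = True
    out = ContactMatrix(
        matrix.layout, matrix.chrom, work,
        balance_weights=weights, masked_bins=mask_idx,
        balanced_converged=converged,
    )
    return out


# ---------------------------------------------------------------------------
# Observed / expected and correlation
# ---------------------------------------------------------------------------

def observed_over_expected(matrix: ContactMatrix) -> ContactMatrix:
    """Divide each entry by the mean unmasked contact at its offset.

    Offsets whose mean is zero (or with no unmasked pair) produce NaN
    entries, which downstream consumers treat as missing.  O/E is invariant
    to global rescaling of the input.
    """
    n = matrix.n_bins
    keep = matrix.unmasked()
    counts = matrix.counts.astype(float)
    oe = np.full((n, n), np.nan)
    idx = np.arange(n)
    for d in range(n):
        i = idx[: n - d]
        j = i + d
        pair_keep = keep[i] & keep[j]
        if not pair_keep.any():
            continue
        vals = counts[i[pair_keep], j[pair_keep]]
        m = vals.mean()
        if m == 0:
            continue
        oe[i[pair_keep], j[pair_keep]] = vals / m
        oe[j[pair_keep], i[pair_keep]] = vals / m
    return ContactMatrix(
        matrix.layout, matrix.chrom, oe,
        masked_bins=matrix.masked_bins, balance_weights=matrix.balance_weights,
    )


@dataclass
class CorrelationMatrix:
    """Symmetric bin-by-bin Pearson correlation of O/E rows."""

    layout: GenomeLayout
    chrom: str
    values: np.ndarray
    masked_bins: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def unmasked(self) -> np.ndarray:
        keep = np.ones(self.n_bins, dtype=bool)
        keep[list(self.masked_bins)] = False
        return keep


def pearson_correlation(oe: ContactMatrix) -> CorrelationMatrix:
    """Pearson correlation of O/E rows over unmasked columns; diagonal 1.

    Zero-variance rows are added to the mask (their correlations are
    undefined).
    """
    keep = oe.unmasked()
    if keep.sum() < 3:
        raise ValueError("need at least 3 unmasked bins for correlation")
    sub = oe.counts[np.ix_(keep, keep)]
    sub = np.nan_to_num(sub, nan=0.0)
    sd = sub.std(axis=1)
    degenerate_local = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr_sub = np.corrcoef(sub)
    n = oe.n_bins
    corr = np.full((n, n), np.nan)
    keep_idx = np.nonzero(keep)[0]
    corr[np.ix_(keep_idx, keep_idx)] = corr_sub
    np.fill_diagonal(corr, 1.0)
    new_mask = set(oe.masked_bins) | set(keep_idx[degenerate_local].tolist())
    for b in new_mask:
        corr[b, :] = np.nan
        corr[:, b] = np.nan
    sym = (corr + corr.T) / 2  # exact symmetry against float round-off
    return CorrelationMatrix(oe.layout, oe.chrom, sym, masked_bins=frozenset(new_mask))


# ---------------------------------------------------------------------------
# Distance-stratified contacts
# ---------------------------------------------------------------------------

@dataclass
class DistanceProfile:
    """Mean contact vs genomic distance plus the long/short contact ratio.

    ``long_short_ratio`` = sum of contacts at distance > ``threshold_bp``
    over the sum at distance <= threshold, the diagonal (offset 0, dominated
    by self-ligation) excluded from the short-range term.
    """

    chrom: str
    distance_bp: np.ndarray
    mean_contact: np.ndarray
    long_short_ratio: float
    threshold_bp: int


def distance_profile(matrix: ContactMatrix, threshold_bp: int = 20_000_000) -> DistanceProfile:
    n = matrix.n_bins
    bs = matrix.layout.bin_size
    chrom_len = matrix.layout.length(matrix.chrom)
    counts = np.nan_to_num(matrix.counts.astype(float), nan=0.0)
    offsets = np.arange(n)
    means = np.empty(n)
    sums = np.empty(n)
    for d in offsets:
        diag = np.diagonal(counts, d)
        means[d] = diag.mean()
        sums[d] = diag.sum()
    dist_bp = offsets * bs
    if threshold_bp >= chrom_len:
        warnings.warn(
            f"threshold {threshold_bp} >= chromosome length {chrom_len}; ratio = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        ratio = 0.0
    else:
        long_sum = sums[dist_bp > threshold_bp].sum()
        short_sum = sums[(dist_bp <= threshold_bp) & (offsets > 0)].sum()
        ratio = float(long_sum / short_sum) if short_sum > 0 else 0.0
    return DistanceProfile(matrix.chrom, dist_bp, means, ratio, threshold_bp)


def compare_ratio_vectors(ratios_a, ratios_b) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test on per-chromosome ratios.

    Returns ``(statistic, p_value)``; identical vectors give p = 1.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ratio vectors must be paired (same chromosomes)")
    if np.allclose(a, b):
        return 0.0, 1.0
    res = stats.wilcoxon(a, b, alternative="two-sided", zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)
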