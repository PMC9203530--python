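"""TAD-like domain calling, cross-sample comparison, classification, and
boundary-centered feature profiles.

Domains are contiguous intervals of elevated internal contact frequency.
The caller is an insulation-style method: the per-bin signal is the mean
contact in a ``window x window`` square spanning the diagonal, boundaries
are sufficiently deep local minima of that signal, and domains tile the
chromosome between boundaries (minus masked gaps).  Domain sets called by
external tools can equally be supplied as BED.

Domain sets and boundary sets are BED-style DataFrames (0-based half-open);
each boundary is exactly one bin wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .contact import ContactMatrix
from .intervals import as_bed, covered_bp, intersection_bp, merge_coverage
from .layout import GenomeLayout

DOMAIN_CLASSES = ("active", "inactive", "HDF")


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def insulation_signal(matrix: ContactMatrix, window_bins: int) -> np.ndarray:
    """Mean contact in the window x window square spanning the diagonal.

    ``signal[i]`` summarizes contacts between the ``window_bins`` bins ending
    at ``i`` (inclusive) and the ``window_bins`` bins starting at ``i + 1``;
    a local minimum marks weak cross-contact, i.e. a candidate boundary
    between bins ``i`` and ``i + 1``.  Masked bins contribute nothing.
    """
    if window_bins < 2:
        raise ValueError("window_bins must be >= 2")
    n = matrix.n_bins
    keep = matrix.unmasked()
    counts = np.nan_to_num(matrix.counts.astype(float), nan=0.0)
    counts = counts * np.outer(keep, keep)
    signal = np.full(n, np.nan)
    for i in range(n - 1):
        r0 = max(0, i - window_bins + 1)
        rows = np.arange(r0, i + 1)
        cols = np.arange(i + 1, min(n, i + 1 + window_bins))
        rows = rows[keep[rows]]
        cols = cols[keep[cols]]
        if rows.size == 0 or cols.size == 0:
            continue
        signal[i] = counts[np.ix_(rows, cols)].mean()
    return signal


def _local_extrema(signal: np.ndarray):
    """Indices of strict-plateau local minima and maxima of a 1-D signal."""
    finite = np.isfinite(signal)
    mins, maxs = [], []
    idx = np.nonzero(finite)[0]
    vals = signal[idx]
    # collapse plateaus: compare each run of equal values with neighbours
    runs = []
    start = 0
    for k in range(1, len(vals) + 1):
        if k == len(vals) or vals[k] != vals[start]:
            runs.append((start, k - 1))
            start = k
    for r, (a, b) in enumerate(runs):
        left = vals[runs[r - 1][1]] if r > 0 else None
        right = vals[runs[r + 1][0]] if r < len(runs) - 1 else None
        v = vals[a]
        center = idx[(a + b) // 2]
        if (left is None or v < left) and (right is None or v < right):
            mins.append(center)
        if (left is None or v > left) and (right is None or v > right):
            maxs.append(center)
    return np.array(mins, dtype=int), np.array(maxs, dtype=int)


def call_domains(
    matrix: ContactMatrix,
    window_bins: int = 5,
    min_drop: float = 0.1,
    sample: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call domains and their single-bin boundaries on one chromosome.

    A local minimum of the insulation signal becomes a boundary when its
    depth below the lower of the two flanking local maxima exceeds
    ``min_drop`` times that maximum — a ratio criterion, so calls are
    invariant to global scaling of the matrix.  Runs of ``>= window_bins``
    masked bins split domains as gaps.

    Returns ``(domains, boundaries)`` as BED frames; ``domains`` carries a
    ``sample`` column when ``sample`` is given.
    """
    layout = matrix.layout
    chrom = matrix.chrom
    bs = layout.bin_size
    n = matrix.n_bins
    keep = matrix.unmasked()
    chrom_len = layout.length(chrom)
    if not keep.any():
        warnings.warn(f"{chrom}: all bins masked; no domains", RuntimeWarning, stacklevel=2)
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        return empty, empty.copy()

    signal = insulation_signal(matrix, window_bins)
    mins, maxs = _local_extrema(signal)
    boundary_bins = []
    for m in mins:
        left_maxs = maxs[maxs < m]
        right_maxs = maxs[maxs > m]
        flank = []
        if left_maxs.size:
            flank.append(signal[left_maxs[-1]])
        if right_maxs.size:
            flank.append(signal[right_maxs[0]])
        if not flank:
            continue
        lower_flank = min(flank)
        if lower_flank > 0 and (lower_flank - signal[m]) > min_drop * lower_flank:
            boundary_bins.append(int(m))

    # gap runs of masked bins long enough to split domains
    gap_edges = set()
    run_start = None
    for i in range(n + 1):
        if i < n and not keep[i]:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= window_bins:
                gap_edges.add(("gap", run_start, i))
            run_start = None

    cut_after = sorted(set(boundary_bins))  # domain split between bin b and b+1
    segments = []
    seg_start = 0
    for b in cut_after:
        if b + 1 > seg_start:
            segments.append((seg_start, b + 1))
        seg_start = b + 1
    if seg_start < n:
        segments.append((seg_start, n))

    # carve out gaps
    domains = []
    gaps = sorted((g[1], g[2]) for g in gap_edges)
    for s, e in segments:
        cur = s
        for gs, ge in gaps:
            if ge <= cur or gs >= e:
                continue
            if gs > cur:
                domains.append((cur, gs))
            cur = max(cur, ge)
        if cur < e:
            domains.append((cur, e))

    dom_df = pd.DataFrame(
        [(chrom, s * bs, min(e * bs, chrom_len)) for s, e in domains],
        columns=["chrom", "start", "end"],
    )
    if sample is not None:
        dom_df["sample"] = sample
    bnd_df = pd.DataFrame(
        [(chrom, b * bs, (b + 1) * bs) for b in cut_after],
        columns=["chrom", "start", "end"],
    )
    return dom_df, bnd_df


def domain_edge_boundaries(domains: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """One bin-sized boundary at each domain edge (deduplicated)."""
    bs = layout.bin_size
    rows = set()
    for r in domains.itertuples(index=False):
        b0 = r.start // bs
        b1 = max(b0, (r.end - 1) // bs)
        rows.add((r.chrom, b0 * bs, (b0 + 1) * bs))
        rows.add((r.chrom, b1 * bs, (b1 + 1) * bs))
    out = pd.DataFrame(sorted(rows), columns=["chrom", "start", "end"])
    return out


# ---------------------------------------------------------------------------
# Cross-sample comparison
# ---------------------------------------------------------------------------

def conserved_domains(
    a: pd.DataFrame, b: pd.DataFrame, reciprocal: float = 0.8
) -> tuple[pd.DataFrame, float]:
    """Reciprocal-overlap matching of two domain sets.

    A pair is conserved when the overlap exceeds ``reciprocal`` times the
    length of *both* domains (the >80% reciprocal rule).  Matching is
    one-to-one, greedy by overlap length with leftmost tie-break.  Returns
    the matched pairs and the shared fraction, i.e. matched pairs over the
    size of the smaller set.
    """
    a = as_bed(a)
    b = as_bed(b)
    cands = []
    for ia, ra in a.iterrows():
        for ib, rb in b.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            ov = min(ra["end"], rb["end"]) - max(ra["start"], rb["start"])
            if ov <= 0:
                continue
            la = ra["end"] - ra["start"]
            lb = rb["end"] - rb["start"]
            if ov > reciprocal * la and ov > reciprocal * lb:
                cands.append((ov, ra["start"], rb["start"], ia, ib))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b, pairs = set(), set(), []
    for ov, _, _, ia, ib in cands:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib, ov))
    pair_df = pd.DataFrame(pairs, columns=["index_a", "index_b", "overlap_bp"])
    denom = min(len(a), len(b))
    frac = len(pairs) / denom if denom else float("nan")
    return pair_df, frac


def shared_boundaries(
    a: pd.DataFrame, b: pd.DataFrame, bin_size: int, tol_bins: int = 1
) -> tuple[pd.DataFrame, float]:
    """Match boundary bins that overlap or lie less than ``tol_bins`` bins apart.

    The gap is measured edge-to-edge between the two bin intervals and the
    rule is strict: matched iff gap < ``tol_bins * bin_size`` (overlapping
    intervals have gap <= 0).  One-to-one, nearest-first matching.  Returns
    matched pairs and the shared fraction over the smaller set.
    """
    for df in (a, b):
        if len(df) and ((df["end"] - df["start"]) != bin_size).any():
            raise ValueError("boundary intervals must be exactly one bin wide")
    a = as_bed(a) if len(a) else a
    b = as_bed(b) if len(b) else b
    cands = []
    for ia, ra in a.iterrows():
        for ib, rb in b.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            gap = max(ra["start"], rb["start"]) - min(ra["end"], rb["end"])
            if gap < tol_bins * bin_size:
                cands.append((max(gap, 0), ra["start"], rb["start"], ia, ib))
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a, used_b, pairs = set(), set(), []
    for gap, _, _, ia, ib in cands:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib, gap))
    pair_df = pd.DataFrame(pairs, columns=["index_a", "index_b", "gap_bp"])
    denom = min(len(a), len(b))
    frac = len(pairs) / denom if denom else 0.0
    return pair_df, frac


def coverage_jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Jaccard similarity |A∩B| / |A∪B| of covered base pairs.

    Returns NaN when both sets are empty.  ``1 - coverage_jaccard`` is the
    Jaccard distance used to cluster samples.
    """
    if len(a) == 0 and len(b) == 0:
        warnings.warn("both interval sets empty; Jaccard undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    if len(a) == 0 or len(b) == 0:
        return 0.0
    inter = intersection_bp(a, b)
    union = covered_bp(pd.concat([a[["chrom", "start", "end"]], b[["chrom", "start", "end"]]]))
    return inter / union


def jaccard_distance_matrix(domain_sets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Jaccard distances between samples' domain coverages."""
    names = list(domain_sets)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim = coverage_jaccard(domain_sets[names[i]], domain_sets[names[j]])
            d[i, j] = d[j, i] = 1.0 - sim
    return pd.DataFrame(d, index=names, columns=names)


# ---------------------------------------------------------------------------
# Classification (active / inactive / HDF)
# ---------------------------------------------------------------------------

@dataclass
class DomainClassification:
    """Three-class grouping of domains with the evidence behind the labels."""

    features: pd.DataFrame          # per-domain mean feature values (raw)
    z_features: pd.DataFrame        # z-standardized per feature
    groups: pd.Series               # per-domain label in DOMAIN_CLASSES
    linkage_tree: np.ndarray        # scipy linkage matrix (complete, Euclidean)
    group_z_means: pd.DataFrame     # diagnostic: mean z per (group, feature)


def domain_feature_table(
    domains: pd.DataFrame, tracks: dict[str, pd.DataFrame], layout: GenomeLayout
) -> pd.DataFrame:
    """Mean track value over the bins each domain covers, one column per track.

    Tracks are per-bin frames with columns (chrom, start, end, value).
    """
    bs = layout.bin_size
    out = {}
    for name, tr in tracks.items():
        vals = []
        by_chrom = {c: g.set_index((g["start"] // bs))["value"] for c, g in tr.groupby("chrom")}
        for r in domains.itertuples(index=False):
            b0 = r.start // bs
            b1 = (r.end - 1) // bs
            series = by_chrom.get(r.chrom)
            if series is None:
                raise ValueError(f"track {name!r} missing chromosome {r.chrom}")
            window = series.reindex(range(b0, b1 + 1))
            if window.isna().all():
                raise ValueError(f"domain {r.chrom}:{r.start}-{r.end} has no {name!r} bins")
            vals.append(window.mean())
        out[name] = vals
    return pd.DataFrame(out, index=domains.index)


def classify_domains(
    domains: pd.DataFrame,
    tracks: dict[str, pd.DataFrame],
    layout: GenomeLayout,
    k: int = 3,
    gene_feature: str = "gene_density",
    active_mark: str = "H3K4me3",
    ltr_feature: str = "ltr_density",
    hdf_mark: str = "H3K9me2",
) -> DomainClassification:
    """Cluster domains into active / inactive / HDF groups.

    Per-domain mean features are z-standardized, clustered by complete-linkage
    agglomeration on Euclidean distance, and the tree is cut at ``k``.  The
    cluster with the highest mean gene-density + H3K4me3 z-score is labeled
    ``active``; of the rest, the one with the highest LTR + H3K9me2 z-score is
    ``HDF``; the remainder is ``inactive`` (expected to carry the highest
    overall methylation).  The per-group z-means are returned so the labeling
    can be audited.
    """
    if k > len(domains):
        raise ValueError(f"k={k} exceeds number of domains ({len(domains)})")
    feats = domain_feature_table(domains, tracks, layout)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=0).replace(0, 1.0)
    z = (feats - mu) / sd
    tree = linkage(pdist(z.to_numpy(), metric="euclidean"), method="complete")
    cluster_ids = fcluster(tree, t=k, criterion="maxclust")
    groups = pd.Series(index=domains.index, dtype=object)
    zc = z.copy()
    zc["_cluster"] = cluster_ids
    z_means = zc.groupby("_cluster").mean()
    remaining = list(z_means.index)
    act_score = z_means[gene_feature] + z_means[active_mark]
    active_c = act_score.loc[remaining].idxmax()
    remaining.remove(active_c)
    hdf_score = z_means[ltr_feature] + z_means[hdf_mark]
    hdf_c = hdf_score.loc[remaining].idxmax()
    remaining.remove(hdf_c)
    label_of = {active_c: "active", hdf_c: "HDF"}
    for c in remaining:
        label_of[c] = "inactive"
    groups[:] = [label_of[c] for c in cluster_ids]
    z_means = z_means.rename(index=label_of)
    z_means.index.name = "group"
    return DomainClassification(feats, z, groups, tree, z_means)


# ---------------------------------------------------------------------------
# Boundary-centered profiles
# ---------------------------------------------------------------------------

def boundary_profile(
    boundaries: pd.DataFrame,
    track: pd.DataFrame,
    layout: GenomeLayout,
    flank_bp: int = 500_000,
) -> pd.DataFrame:
    """Mean +- SE of a binned track versus offset from boundary bins.

    For each offset in ``[-flank, +flank]`` (bin steps) the track is averaged
    over all boundaries whose offset bin lies on-chromosome; boundaries near
    chromosome ends contribute only their valid offsets.  Returns a frame
    with columns ``offset_bp, mean, se, n``.
    """
    bs = layout.bin_size
    flank_bins = flank_bp // bs
    by_chrom = {c: g.set_index(g["start"] // bs)["value"] for c, g in track.groupby("chrom")}
    offsets = np.arange(-flank_bins, flank_bins + 1)
    sums = np.zeros(offsets.size)
    sqs = np.zeros(offsets.size)
    ns = np.zeros(offsets.size, dtype=int)
    for r in boundaries.itertuples(index=False):
        series = by_chrom.get(r.chrom)
        if series is None:
            continue
        n_bins = layout.n_bins(r.chrom)
        center = r.start // bs
        for k, off in enumerate(offsets):
            b = center + off
            if not 0 <= b < n_bins:
                continue
            v = series.get(b)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            sums[k] += v
            sqs[k] += v * v
            ns[k] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
        var = np.where(ns > 1, (sqs - ns * mean**2) / np.maximum(ns - 1, 1), np.nan)
        se = np.sqrt(np.maximum(var, 0) / np.maximum(ns, 1))
    return pd.DataFrame(
        {"offset_bp": offsets * bs, "mean": mean, "se": se, "n": ns}
    )
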