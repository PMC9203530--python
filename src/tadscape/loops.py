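"""Chromatin-loop set operations: cross-resolution merging, cross-tissue
sharing, and loop-anchor vs domain-boundary association statistics.

Loops enter as BEDPE-style DataFrames with columns ``chrom, startA, endA,
startB, endB`` (same chromosome, anchor A left of anchor B) plus optional
``resolution`` (bp) and ``sample`` columns.  Loop *detection* is upstream of
this package; the computation here is the comparison layer: loops called at
10/15/20/25-kb resolutions are merged within 25 kb into one final set, loops
are "shared" between tissues when a loop in another tissue has both anchors
within 25 kb, and anchors are tested for coincidence with domain boundaries
against both an analytic and a permutation chance expectation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .layout import GenomeLayout

LOOP_COLUMNS = ["chrom", "startA", "endA", "startB", "endB"]


def validate_loops(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOOP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing loop columns: {missing}")
    if ((df["endA"] <= df["startA"]) | (df["endB"] <= df["startB"])).any():
        raise ValueError("degenerate anchors")
    if (df["startA"] > df["startB"]).any():
        raise ValueError("anchor A must lie left of anchor B")
    return df.reset_index(drop=True)


def _midpoints(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    ma = (df["startA"].to_numpy() + df["endA"].to_numpy()) / 2
    mb = (df["startB"].to_numpy() + df["endB"].to_numpy()) / 2
    return ma, mb


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _group_within(df: pd.DataFrame, d: float) -> np.ndarray:
    """Transitive (single-linkage) grouping of loops whose anchor midpoints
    are each within ``d``; returns a group id per row."""
    n = len(df)
    uf = _UnionFind(n)
    ma, mb = _midpoints(df)
    chrom = df["chrom"].to_numpy()
    order = np.argsort(ma, kind="stable")
    for oi in range(n):
        i = order[oi]
        for oj in range(oi + 1, n):
            j = order[oj]
            if ma[j] - ma[i] > d:
                break
            if chrom[i] != chrom[j]:
                continue
            if abs(mb[i] - mb[j]) <= d:
                uf.union(i, j)
    roots = np.array([uf.find(i) for i in range(n)])
    _, ids = np.unique(roots, return_inverse=True)
    return ids


def merge_loops(sets: list[pd.DataFrame], merge_dist: int = 25_000) -> pd.DataFrame:
    """Merge loop calls from multiple resolutions within ``merge_dist``.

    Loops with both anchor midpoints within ``merge_dist`` are grouped
    transitively; each group is represented by the median anchor midpoints
    snapped to the finest contributing resolution grid, with anchor width
    equal to that resolution.  The operation is idempotent.
    """
    frames = []
    for s in sets:
        s = validate_loops(s.copy())
        if "resolution" not in s.columns:
            s["resolution"] = (s["endA"] - s["startA"]).astype(int)
        frames.append(s)
    allloops = pd.concat(frames, ignore_index=True)
    if allloops.empty:
        return allloops[LOOP_COLUMNS + ["resolution"]]
    ids = _group_within(allloops, merge_dist)
    out = []
    for gid in np.unique(ids):
        g = allloops[ids == gid]
        res = int(g["resolution"].min())
        ma = np.median((g["startA"] + g["endA"]) / 2)
        mb = np.median((g["startB"] + g["endB"]) / 2)
        sa = int(round(ma / res)) * res - res // 2
        sb = int(round(mb / res)) * res - res // 2
        sa = max(sa, 0)
        sb = max(sb, sa)  # keep A left of B
        out.append((g["chrom"].iloc[0], sa, sa + res, sb, sb + res, res))
    df = pd.DataFrame(out, columns=LOOP_COLUMNS + ["resolution"])
    return df.sort_values(["chrom", "startA", "startB"], kind="stable").reset_index(drop=True)


def shared_loops(
    per_tissue: dict[str, pd.DataFrame], d: int = 25_000
) -> dict:
    """Partition loops into shared (found in >= 2 tissues) vs tissue-specific.

    A loop is shared when some loop in a *different* tissue has both anchor
    midpoints within ``d``.  Returns per-tissue flags, the counts, and a
    non-redundant union (shared groups collapsed to one representative).
    """
    if len(per_tissue) < 2:
        raise ValueError("need >= 2 tissues")
    frames = []
    for tissue, df in per_tissue.items():
        df = validate_loops(df.copy())
        df["tissue"] = tissue
        frames.append(df)
    allloops = pd.concat(frames, ignore_index=True)
    ids = _group_within(allloops, d)
    allloops["group"] = ids
    n_tissues = allloops.groupby("group")["tissue"].nunique()
    allloops["shared"] = allloops["group"].map(n_tissues) >= 2
    union = (
        allloops.sort_values(["group", "tissue", "startA"], kind="stable")
        .groupby("group")
        .first()
        .reset_index()
    )
    return {
        "loops": allloops,
        "union": union[LOOP_COLUMNS + ["tissue", "shared"]],
        "n_shared": int(union["shared"].sum()),
        "n_specific": int((~union["shared"]).sum()),
    }


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test; thin wrapper kept as a seam for the
    enumeration oracle in the tests."""
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def loop_boundary_association(
    loops: pd.DataFrame,
    boundaries: pd.DataFrame,
    layout: GenomeLayout,
    n_perm: int = 1000,
    seed: int = 0,
    masked_bins: dict[str, np.ndarray] | None = None,
    domains: pd.DataFrame | None = None,
) -> dict:
    """Association between loop anchors and domain-boundary bins.

    Reports (i) the fraction of anchors falling in a boundary bin, (ii) the
    analytic chance expectation (fraction of genome bins that are boundary
    bins), (iii) a two-sided Fisher's exact test on the 2x2 table of
    [anchor bins vs non-anchor bins] x [boundary vs not], and (iv) the
    reciprocal statistic — fraction of boundaries carrying >= 1 anchor —
    with a seeded permutation expectation placing the same number of anchors
    uniformly on unmasked bins.
    """
    loops = validate_loops(loops.copy())
    bs = layout.bin_size
    if loops.empty or boundaries.empty:
        return {"anchor_fraction": float("nan"), "note": "empty input"}
    boundary_bins: dict[str, set] = {}
    for r in boundaries.itertuples(index=False):
        boundary_bins.setdefault(r.chrom, set()).add(r.start // bs)

    anchor_bins = []
    for r in loops.itertuples(index=False):
        anchor_bins.append((r.chrom, int((r.startA + r.endA) // 2 // bs)))
        anchor_bins.append((r.chrom, int((r.startB + r.endB) // 2 // bs)))
    on_boundary = sum(1 for c, b in anchor_bins if b in boundary_bins.get(c, ()))
    n_anchors = len(anchor_bins)
    anchor_fraction = on_boundary / n_anchors

    total_bins = layout.total_bins
    n_boundary_bins = sum(len(v) for v in boundary_bins.values())
    expected_fraction = n_boundary_bins / total_bins

    anchor_bin_set = set(anchor_bins)
    n_anchor_bins = len(anchor_bin_set)
    anchor_on = sum(1 for c, b in anchor_bin_set if b in boundary_bins.get(c, ()))
    non_anchor_bins = total_bins - n_anchor_bins
    non_anchor_on = n_boundary_bins - anchor_on
    table = [
        [anchor_on, n_anchor_bins - anchor_on],
        [non_anchor_on, non_anchor_bins - non_anchor_on],
    ]
    odds, p = fisher_exact_2x2(table)

    # reciprocal: domains (or, failing a domain set, boundaries) with >= 1
    # anchored boundary bin, vs a uniform-anchor permutation expectation
    if domains is not None and len(domains):
        units = []  # list of lists of (chrom, bin) edge-boundary bins per domain
        for r in domains.itertuples(index=False):
            b0 = r.start // bs
            b1 = max(b0, (r.end - 1) // bs)
            units.append([(r.chrom, b0), (r.chrom, b1)])
    else:
        units = [
            [(chrom, b)] for chrom, bins in boundary_bins.items() for b in sorted(bins)
        ]

    def _unit_fraction(anchor_set):
        hit = sum(1 for edges in units if any(e in anchor_set for e in edges))
        return hit / len(units)

    reciprocal_fraction = _unit_fraction(anchor_bin_set)
    rng = np.random.default_rng(seed)
    all_bins = []
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        masked = set(masked_bins.get(chrom, ())) if masked_bins else set()
        all_bins.extend((chrom, b) for b in range(nb) if b not in masked)
    null_fracs = np.empty(n_perm)
    for k in range(n_perm):
        pick = rng.choice(len(all_bins), size=n_anchor_bins, replace=False)
        perm_set = {all_bins[i] for i in pick}
        null_fracs[k] = _unit_fraction(perm_set)
    return {
        "anchor_fraction": anchor_fraction,
        "expected_fraction": expected_fraction,
        "fisher_table": table,
        "fisher_p": p,
        "odds_ratio": odds,
        "reciprocal_fraction": reciprocal_fraction,
        "reciprocal_null_mean": float(null_fracs.mean()),
        "reciprocal_null_sd": float(null_fracs.std(ddof=1)),
        "n_perm": n_perm,
        "seed": seed,
    }
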