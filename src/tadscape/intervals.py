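"""Small interval-arithmetic helpers on BED-style DataFrames.

Interval sets are pandas DataFrames with at least ``chrom``, ``start``,
``end`` columns, 0-based half-open.  These helpers cover the few operations
the pipeline needs (coverage union, pairwise overlap, Jaccard on covered bp)
and are cross-checked in the tests against brute-force per-bp computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


def as_bed(df: pd.DataFrame) -> pd.DataFrame:
    """Validate/sort a BED-like frame; returns a sorted copy."""
    missing = [c for c in BED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if (df["end"] <= df["start"]).any():
        raise ValueError("intervals must have end > start")
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def merge_coverage(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: merged, non-overlapping, sorted."""
    df = as_bed(df)
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED_COLUMNS)


def covered_bp(df: pd.DataFrame) -> int:
    m = merge_coverage(df)
    return int((m["end"] - m["start"]).sum())


def intersection_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Base pairs covered by both sets (after merging each)."""
    ma, mb = merge_coverage(a), merge_coverage(b)
    total = 0
    for chrom in sorted(set(ma["chrom"]) & set(mb["chrom"])):
        sa = ma[ma["chrom"] == chrom]
        sb = mb[mb["chrom"] == chrom]
        ia = ib = 0
        a_s, a_e = sa["start"].to_numpy(), sa["end"].to_numpy()
        b_s, b_e = sb["start"].to_numpy(), sb["end"].to_numpy()
        while ia < len(a_s) and ib < len(b_s):
            lo = max(a_s[ia], b_s[ib])
            hi = min(a_e[ia], b_e[ib])
            if hi > lo:
                total += hi - lo
            if a_e[ia] < b_e[ib]:
                ia += 1
            else:
                ib += 1
    return int(total)


def overlap_bp(chrom_a, start_a, end_a, chrom_b, start_b, end_b) -> int:
    """Overlap of two single intervals in bp (0 if different chromosomes)."""
    if chrom_a != chrom_b:
        return 0
    return max(0, min(end_a, end_b) - max(start_a, start_b))
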