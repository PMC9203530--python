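"""Binned epigenomic feature tracks from site-level calls and fragments.

Methylation: the level of a bin is the percentage of *heavily methylated*
cytosines in it, where a site is heavy when methylated reads account for at
least 25% of its mapped reads.  Levels are computed per context (CpG, CHG,
CHH); the "overall" level pools the sites of all three contexts (so it stays
bounded by 100).  Bins with no sites are *undefined*, not zero — they are
omitted from exported tracks.

ChIP/RNA coverage: per-bin fragment-midpoint counts normalized to counts per
million (CPM) for the sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .layout import GenomeLayout

METH_CONTEXTS = ("CpG", "CHG", "CHH")


def methylation_level(
    sites: pd.DataFrame,
    layout: GenomeLayout,
    context_filter: str | None = None,
    heavy_threshold: float = 0.25,
) -> pd.DataFrame:
    """Percent heavily methylated sites per bin.

    ``sites`` columns: chrom, pos, context, methylated, total.
    ``context_filter`` keeps one context; None pools all (the "overall"
    level).  Returns (chrom, start, end, value) with covered bins only.
    """
    req = ["chrom", "pos", "context", "methylated", "total"]
    missing = [c for c in req if c not in sites.columns]
    if missing:
        raise ValueError(f"missing site columns: {missing}")
    if (sites["methylated"] > sites["total"]).any() or (sites["total"] < 1).any():
        raise ValueError("need 0 <= methylated <= total and total >= 1")
    df = sites
    if context_filter is not None:
        if context_filter not in METH_CONTEXTS:
            raise ValueError(f"unknown context {context_filter!r}")
        df = df[df["context"] == context_filter]
    bs = layout.bin_size
    heavy = (df["methylated"] / df["total"]) >= heavy_threshold
    tmp = pd.DataFrame(
        {"chrom": df["chrom"], "bin": df["pos"] // bs, "heavy": heavy.astype(int)}
    )
    agg = tmp.groupby(["chrom", "bin"]).agg(n=("heavy", "size"), h=("heavy", "sum"))
    agg = agg.reset_index()
    return pd.DataFrame(
        {
            "chrom": agg["chrom"],
            "start": agg["bin"] * bs,
            "end": np.minimum((agg["bin"] + 1) * bs,
                              [layout.length(c) for c in agg["chrom"]]),
            "value": 100.0 * agg["h"] / agg["n"],
        }
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def coverage_cpm(fragments: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Counts-per-million of fragment midpoints per bin.

    ``fragments`` columns: chrom, start, end.  Every bin of the layout is
    reported (zero CPM where no fragment lands); CPM sums to 1e6.
    """
    if fragments.empty:
        raise ValueError("zero fragments")
    bs = layout.bin_size
    mids = (fragments["start"] + fragments["end"]) // 2
    tmp = pd.DataFrame({"chrom": fragments["chrom"], "bin": mids // bs})
    counts = tmp.groupby(["chrom", "bin"]).size()
    total = len(fragments)
    rows = []
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        length = layout.length(chrom)
        for b in range(nb):
            c = counts.get((chrom, b), 0)
            rows.append((chrom, b * bs, min((b + 1) * bs, length), 1e6 * c / total))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
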