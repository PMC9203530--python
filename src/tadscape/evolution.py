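"""Evolutionary-constraint statistics around chromatin-domain boundaries.

Four analyses live here:

* Phred-scaled assembly quality, ``QV = -10 log10(variant sites / covered
  sites)``.
* Observed/expected variant profiles around boundaries: a 40-kb window slid
  in 5-kb steps over +-500 kb of each boundary midpoint, with the
  expectation from a genome-wide homogeneity assumption (windows clipped at
  chromosome ends count proportionally).
* Synteny-break detection by chaining collinear alignment blocks; a break is
  emitted where consecutive chains change query chromosome, strand, or
  order.
* Break enrichment along scaled domain bodies, normalized by the alignable
  rate and tested against seeded random break sets (observed statistic: the
  two boundary-proximal cells of the scaled-domain histogram; empirical p
  with the add-one rule so p >= 1/(n_perm+1)).

Variants are plain frames (SNPs: ``chrom, pos``; deletions: ``chrom, start,
end``); alignment blocks are PAF-like frames (``qname, qstart, qend, strand,
tname, tstart, tend, alignable_bp``) with the reference on the *t* side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import GenomeLayout

QV_CAP = 99.0  # sentinel when no variant site is observed


def assembly_qv(n_variant_sites: int, n_covered_sites: int) -> float:
    """Phred assembly quality from the site-error fraction.

    QV = -10*log10(n_variant_sites / n_covered_sites); zero variants returns
    the capped sentinel 99.
    """
    if n_covered_sites <= 0:
        raise ValueError("n_covered_sites must be positive")
    if not 0 <= n_variant_sites <= n_covered_sites:
        raise ValueError("n_variant_sites must lie in [0, n_covered_sites]")
    if n_variant_sites == 0:
        return QV_CAP
    return -10.0 * math.log10(n_variant_sites / n_covered_sites)


# ---------------------------------------------------------------------------
# Boundary-centered variant O/E profile
# ---------------------------------------------------------------------------

def boundary_variant_profile(
    snps: pd.DataFrame | None,
    deletions: pd.DataFrame | None,
    boundaries: pd.DataFrame,
    layout: GenomeLayout,
    window: int = 40_000,
    step: int = 5_000,
    flank: int = 500_000,
    mode: str = "SNP_count",
) -> pd.DataFrame:
    """Observed/expected variant abundance in sliding windows around boundaries.

    For each offset in ``[-flank, +flank]`` (step ``step``), the observed
    statistic is summed over all boundaries in the ``window``-bp window
    centered at (boundary midpoint + offset), clipped to the chromosome; the
    expected value is the genome-wide density times the summed in-genome
    window bp.  ``mode`` selects SNP counts or deletion-covered bp.
    Returns a frame with columns ``offset_bp, obs, exp, ratio``.
    """
    if mode not in ("SNP_count", "deletion_bp"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "SNP_count":
        if snps is None or snps.empty:
            warnings.warn("no SNPs; ratio undefined", RuntimeWarning, stacklevel=2)
            offs = np.arange(-flank, flank + 1, step)
            return pd.DataFrame({"offset_bp": offs, "obs": 0.0, "exp": 0.0, "ratio": np.nan})
        density = len(snps) / layout.total_bp
        pos_by_chrom = {
            c: np.sort(g["pos"].to_numpy()) for c, g in snps.groupby("chrom")
        }
    else:
        if deletions is None or deletions.empty:
            warnings.warn("no deletions; ratio undefined", RuntimeWarning, stacklevel=2)
            offs = np.arange(-flank, flank + 1, step)
            return pd.DataFrame({"offset_bp": offs, "obs": 0.0, "exp": 0.0, "ratio": np.nan})
        density = (deletions["end"] - deletions["start"]).sum() / layout.total_bp
        dels_by_chrom = {
            c: (g["start"].to_numpy(), g["end"].to_numpy())
            for c, g in deletions.sort_values("start").groupby("chrom")
        }

    offsets = np.arange(-flank, flank + 1, step)
    obs = np.zeros(offsets.size)
    exp_bp = np.zeros(offsets.size)
    half = window // 2
    for r in boundaries.itertuples(index=False):
        chrom_len = layout.length(r.chrom)
        mid = (r.start + r.end) // 2
        lo = np.clip(mid + offsets - half, 0, chrom_len)
        hi = np.clip(mid + offsets + half, 0, chrom_len)
        exp_bp += hi - lo
        if mode == "SNP_count":
            pos = pos_by_chrom.get(r.chrom)
            if pos is not None:
                obs += np.searchsorted(pos, hi) - np.searchsorted(pos, lo)
        else:
            d = dels_by_chrom.get(r.chrom)
            if d is not None:
                ds, de = d
                for k in range(offsets.size):
                    ov = np.minimum(de, hi[k]) - np.maximum(ds, lo[k])
                    obs[k] += ov[ov > 0].sum()
    exp = density * exp_bp
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(exp > 0, obs / exp, np.nan)
    return pd.DataFrame({"offset_bp": offsets, "obs": obs, "exp": exp, "ratio": ratio})


# ---------------------------------------------------------------------------
# Synteny breaks
# ---------------------------------------------------------------------------

def detect_synteny_breaks(
    blocks: pd.DataFrame,
    min_block_bp: int = 10_000,
    max_join_gap_bp: int = 100_000,
) -> pd.DataFrame:
    """Chain collinear alignment blocks and emit reference break positions.

    Blocks are chained when consecutive (on the reference) blocks share the
    query chromosome and strand, are query-order consistent for that strand,
    and both reference and query gaps are <= ``max_join_gap_bp``.  Chains
    spanning < ``min_block_bp`` on the reference are discarded.  A break is
    placed at the reference midpoint between consecutive surviving chains.
    Overlapping reference blocks are resolved by keeping the longer (with a
    warning).  Returns a frame ``chrom, pos``.
    """
    req = ["qname", "qstart", "qend", "strand", "tname", "tstart", "tend"]
    missing = [c for c in req if c not in blocks.columns]
    if missing:
        raise ValueError(f"missing block columns: {missing}")
    breaks = []
    for chrom, sub in blocks.groupby("tname", sort=True):
        sub = sub.sort_values(["tstart", "tend"], kind="stable").reset_index(drop=True)
        # resolve reference overlaps: keep the longer block
        kept = []
        for r in sub.itertuples(index=False):
            if kept and r.tstart < kept[-1].tend:
                prev = kept[-1]
                if (r.tend - r.tstart) > (prev.tend - prev.tstart):
                    kept[-1] = r
                warnings.warn(
                    f"{chrom}: overlapping reference blocks resolved by length",
                    RuntimeWarning,
                    stacklevel=2,
                )
            else:
                kept.append(r)
        # chain
        chains = []  # list of dicts with tstart, tend and last block
        cur = None
        for r in kept:
            if cur is None:
                cur = {"tstart": r.tstart, "tend": r.tend, "last": r}
                continue
            prev = cur["last"]
            ref_gap = r.tstart - prev.tend
            joinable = (
                r.qname == prev.qname
                and r.strand == prev.strand
                and ref_gap <= max_join_gap_bp
            )
            if joinable:
                if r.strand == "+":
                    q_gap = r.qstart - prev.qend
                    joinable = 0 - max_join_gap_bp <= q_gap <= max_join_gap_bp and r.qstart >= prev.qstart
                else:
                    q_gap = prev.qstart - r.qend
                    joinable = 0 - max_join_gap_bp <= q_gap <= max_join_gap_bp and r.qend <= prev.qend
            if joinable:
                cur["tend"] = r.tend
                cur["last"] = r
            else:
                chains.append(cur)
                cur = {"tstart": r.tstart, "tend": r.tend, "last": r}
        if cur is not None:
            chains.append(cur)
        chains = [c for c in chains if c["tend"] - c["tstart"] >= min_block_bp]
        for a, b in zip(chains, chains[1:]):
            breaks.append((chrom, (a["tend"] + b["tstart"]) // 2))
    return pd.DataFrame(breaks, columns=["chrom", "pos"])


# ---------------------------------------------------------------------------
# Break enrichment along scaled domain bodies
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Observed statistic against its seeded permutation null."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_perm: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p": self.p,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _relative_cells(
    positions: np.ndarray,
    chroms: np.ndarray,
    domain_lookup: dict[str, tuple[np.ndarray, np.ndarray]],
    n_rel_bins: int,
) -> np.ndarray:
    """Map positions to scaled-domain cells 0..n_rel_bins-1 (or -1 if outside
    every domain; such positions snap to the nearest domain edge cell)."""
    cells = np.full(positions.size, -1, dtype=int)
    for i, (c, p) in enumerate(zip(chroms, positions)):
        if c not in domain_lookup:
            continue
        starts, ends = domain_lookup[c]
        j = np.searchsorted(starts, p, side="right") - 1
        if j >= 0 and p < ends[j]:
            rel = (p - starts[j]) / (ends[j] - starts[j])
            cells[i] = min(int(rel * n_rel_bins), n_rel_bins - 1)
        else:
            # outside all domains: assign to the terminal cell of the nearest edge
            d_right = starts[j + 1] - p if j + 1 < starts.size else np.inf
            d_left = p - ends[j] if j >= 0 else np.inf
            cells[i] = 0 if d_right <= d_left else n_rel_bins - 1
    return cells


def break_boundary_enrichment(
    breaks: pd.DataFrame,
    domains: pd.DataFrame,
    alignable_track: pd.DataFrame,
    layout: GenomeLayout,
    n_rel_bins: int = 10,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, EnrichmentResult]:
    """Alignability-normalized break density along scaled domain bodies.

    Each break maps to the relative position of its containing domain,
    histogrammed into ``n_rel_bins`` cells; each cell is divided by the mean
    alignable fraction of the genomic bins mapping to it.  The null places
    the same number of breaks at random genomic-bin midpoints with
    probability proportional to alignable fraction (``n_perm`` seeded
    replicates).  The observed statistic is the normalized count summed over
    the two terminal (boundary-proximal) cells; empirical p uses the add-one
    rule.

    Returns ``(profile, enrichment)`` with profile columns
    ``rel_cell, count, alignable_mean, normalized, fold``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    bs = layout.bin_size
    domain_lookup = {}
    for c, g in domains.sort_values("start").groupby("chrom"):
        domain_lookup[c] = (g["start"].to_numpy(), g["end"].to_numpy())

    # per-genomic-bin alignable fraction and scaled-domain cell
    bin_chroms, bin_mids, bin_align = [], [], []
    align_by_chrom = {
        c: g.set_index(g["start"] // bs)["value"] for c, g in alignable_track.groupby("chrom")
    }
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        series = align_by_chrom.get(chrom)
        for b in range(nb):
            v = float(series.get(b, np.nan)) if series is not None else np.nan
            if not np.isfinite(v):
                continue
            bin_chroms.append(chrom)
            bin_mids.append(b * bs + bs // 2)
            bin_align.append(v)
    bin_chroms = np.array(bin_chroms)
    bin_mids = np.array(bin_mids)
    bin_align = np.array(bin_align)
    bin_cells = _relative_cells(bin_mids, bin_chroms, domain_lookup, n_rel_bins)

    align_mean = np.full(n_rel_bins, np.nan)
    for c in range(n_rel_bins):
        sel = bin_cells == c
        if sel.any():
            align_mean[c] = bin_align[sel].mean()
    # relative alignability: a uniform rescaling of the track cancels out
    align_rel = align_mean / bin_align.mean()

    def _normalized_hist(cells: np.ndarray) -> np.ndarray:
        hist = np.bincount(cells[cells >= 0], minlength=n_rel_bins).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(align_rel > 0, hist / align_rel, np.nan)

    obs_cells = _relative_cells(
        breaks["pos"].to_numpy(), breaks["chrom"].to_numpy(), domain_lookup, n_rel_bins
    )
    obs_norm = _normalized_hist(obs_cells)
    observed = float(np.nansum(obs_norm[[0, n_rel_bins - 1]]))

    rng = np.random.default_rng(seed)
    weights = bin_align / bin_align.sum()
    n_breaks = len(breaks)
    null_stats = np.empty(n_perm)
    for k in range(n_perm):
        pick = rng.choice(bin_align.size, size=n_breaks, replace=True, p=weights)
        null_norm = _normalized_hist(bin_cells[pick])
        null_stats[k] = np.nansum(null_norm[[0, n_rel_bins - 1]])
    null_mean = float(null_stats.mean())
    null_sd = float(null_stats.std(ddof=1)) if n_perm > 1 else float("nan")
    z = (observed - null_mean) / null_sd if null_sd and null_sd > 0 else float("nan")
    p = (1 + int((null_stats >= observed).sum())) / (n_perm + 1)
    fold = obs_norm * n_rel_bins / np.nansum(obs_norm) if np.nansum(obs_norm) > 0 else obs_norm
    profile = pd.DataFrame(
        {
            "rel_cell": np.arange(n_rel_bins),
            "count": np.bincount(obs_cells[obs_cells >= 0], minlength=n_rel_bins),
            "alignable_mean": align_mean,
            "normalized": obs_norm,
            "fold": fold,
        }
    )
    return profile, EnrichmentResult(observed, null_mean, null_sd, float(z), float(p), n_perm, seed)
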