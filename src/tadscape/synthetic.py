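"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of a large, repeat-rich
plant genome assayed by Hi-C, WGBS, ChIP and RNA-seq:

* contact maps follow a power-law distance decay with multiplicative
  within-domain and loop-anchor folds and Poisson counts — the simplest
  generative model whose observed/expected has a closed form;
* feature tracks are class-conditional (active domains rich in genes and
  H3K4me3, heterochromatin-driven folding (HDF) domains rich in LTR
  retrotransposons and H3K9me2, inactive domains most heavily methylated);
* variants come from an inhomogeneous Poisson process with a configurable
  depletion factor inside boundary zones;
* synteny blocks tile the reference with a configurable fraction of breaks
  placed within one bin of a domain boundary;
* expression counts are negative-binomial with a configurable fraction of
  tissue-specific bins.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact import ContactMatrix
from .layout import GenomeLayout

DOMAIN_CLASSES = ("active", "inactive", "HDF")

# Mean domain sizes (bp) and mixing proportions follow the three-class
# structure observed in large repeat-rich plant genomes: HDF domains are the
# largest (~1.1 Mb) and cover most of the genome; active domains are the
# smallest minority class.
DEFAULT_CLASS_SIZE_BP = {"active": 734_000, "inactive": 698_000, "HDF": 1_100_000}
DEFAULT_CLASS_PROBS = {"active": 0.12, "inactive": 0.38, "HDF": 0.50}


@dataclass
class SyntheticTruth:
    """Planted ground truth behind a synthetic dataset."""

    domains: pd.DataFrame          # chrom, start, end, class
    boundaries: pd.DataFrame       # chrom, start, end (one bin wide)
    loops: pd.DataFrame            # chrom, startA, endA, startB, endB
    compartment_rank: dict = field(default_factory=dict)  # chrom -> per-bin 1..8
    variant_depletion_factor: float = 1.0
    break_boundary_fraction: float = 0.0
    seed: int = 0

    def validate(self, layout: GenomeLayout) -> None:
        for r in self.domains.itertuples(index=False):
            if not (0 <= r.start < r.end <= layout.length(r.chrom)):
                raise ValueError("domain outside chromosome")
        for c, g in self.domains.groupby("chrom"):
            s = g.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise ValueError("overlapping domains")
        if not 0 < self.variant_depletion_factor <= 1:
            raise ValueError("variant_depletion_factor must be in (0, 1]")
        if not 0 <= self.break_boundary_fraction <= 1:
            raise ValueError("break_boundary_fraction must be in [0, 1]")
        for c, ranks in self.compartment_rank.items():
            if len(ranks) != layout.n_bins(c):
                raise ValueError(f"rank track length mismatch on {c}")
            if ((np.asarray(ranks) < 1) | (np.asarray(ranks) > 8)).any():
                raise ValueError("ranks must lie in 1..8")


def plant_truth(
    layout: GenomeLayout,
    seed: int,
    class_size_bp: dict | None = None,
    class_probs: dict | None = None,
    loops_per_chrom: int = 20,
    corner_loop_fraction: float = 0.5,
    variant_depletion_factor: float = 1.0,
    break_boundary_fraction: float = 0.0,
) -> SyntheticTruth:
    """Plant non-overlapping classed domains, boundaries, loops and ranks.

    Domains tile each chromosome: lengths are Poisson around the per-class
    mean size (min 2 bins), classes drawn from ``class_probs``.  Half of the
    loops (by default) connect the two edge bins of a domain ("corner"
    loops); the rest join random bin pairs within 2 Mb.  Compartment ranks
    are blocky runs of mean 25 bins.
    """
    rng = np.random.default_rng(seed)
    class_size_bp = dict(DEFAULT_CLASS_SIZE_BP if class_size_bp is None else class_size_bp)
    class_probs = dict(DEFAULT_CLASS_PROBS if class_probs is None else class_probs)
    classes = list(class_probs)
    probs = np.array([class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    bs = layout.bin_size

    dom_rows, bnd_rows = [], []
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        pos = 0
        starts = []
        while pos < nb:
            cls = classes[rng.choice(len(classes), p=probs)]
            mean_bins = max(2, int(round(class_size_bp[cls] / bs)))
            length = max(2, int(rng.poisson(mean_bins)))
            end = min(pos + length, nb)
            if nb - end < 2:  # absorb a too-short tail
                end = nb
            dom_rows.append((chrom, pos * bs, min(end * bs, layout.length(chrom)), cls))
            starts.append(pos)
            if end < nb:
                bnd_rows.append((chrom, (end - 1) * bs, end * bs))
            pos = end
    domains = pd.DataFrame(dom_rows, columns=["chrom", "start", "end", "class"])
    boundaries = pd.DataFrame(bnd_rows, columns=["chrom", "start", "end"])

    loop_rows = []
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        doms = domains[domains["chrom"] == chrom]
        n_corner = int(round(loops_per_chrom * corner_loop_fraction))
        pick = rng.choice(len(doms), size=min(n_corner, len(doms)), replace=False)
        for i in pick:
            r = doms.iloc[i]
            b0 = r["start"] // bs
            b1 = (r["end"] - 1) // bs
            if b1 > b0:
                loop_rows.append((chrom, b0 * bs, (b0 + 1) * bs, b1 * bs, (b1 + 1) * bs))
        for _ in range(loops_per_chrom - len(pick)):
            a = int(rng.integers(0, nb - 2))
            span = int(rng.integers(2, max(3, min(nb - a, 2_000_000 // bs))))
            b = min(a + span, nb - 1)
            loop_rows.append((chrom, a * bs, (a + 1) * bs, b * bs, (b + 1) * bs))
    loops = pd.DataFrame(
        loop_rows, columns=["chrom", "startA", "endA", "startB", "endB"]
    ).sort_values(["chrom", "startA", "startB"], kind="stable").reset_index(drop=True)

    ranks = {}
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        r = np.empty(nb, dtype=int)
        pos = 0
        while pos < nb:
            run = max(1, int(rng.geometric(1 / 25)))
            r[pos : pos + run] = int(rng.integers(1, 9))
            pos += run
        ranks[chrom] = r

    truth = SyntheticTruth(
        domains, boundaries, loops, ranks,
        variant_depletion_factor, break_boundary_fraction, seed,
    )
    truth.validate(layout)
    return truth


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

def simulate_contact_map(
    layout: GenomeLayout,
    truth: SyntheticTruth,
    chrom: str,
    decay_exponent: float = 1.0,
    within_domain_fold: float = 2.0,
    loop_fold: float = 3.0,
    mean_depth: float = 50.0,
    seed: int = 0,
    gap_fraction: float = 0.02,
) -> ContactMatrix:
    """Poisson contact counts on a power-law decay with planted structure.

    Expected count for bin pair (i, j):

        mean_depth * (|i-j| + 1)^(-decay_exponent)
                   * within_domain_fold^[i,j in the same domain]
                   * loop_fold^[(i,j) is a loop anchor pair]

    Counts are Poisson, the matrix symmetric.  A fraction ``gap_fraction``
    of bins is zeroed out to emulate unmappable regions and exercise
    masking.
    """
    if within_domain_fold < 1 or loop_fold < 1:
        raise ValueError("fold parameters must be >= 1")
    if mean_depth <= 0 or decay_exponent <= 0:
        raise ValueError("mean_depth and decay_exponent must be positive")
    n = layout.n_bins(chrom)
    if n < 4:
        raise ValueError("need >= 4 bins per chromosome")
    rng = np.random.default_rng(seed)
    bs = layout.bin_size

    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    expected = mean_depth * (dist + 1.0) ** (-decay_exponent)

    dom_id = np.full(n, -1)
    doms = truth.domains[truth.domains["chrom"] == chrom].reset_index(drop=True)
    for k, r in doms.iterrows():
        b0 = r["start"] // bs
        b1 = (r["end"] - 1) // bs
        dom_id[b0 : b1 + 1] = k
    same = (dom_id[:, None] == dom_id[None, :]) & (dom_id[:, None] >= 0)
    expected = expected * np.where(same, within_domain_fold, 1.0)

    for r in truth.loops[truth.loops["chrom"] == chrom].itertuples(index=False):
        i = r.startA // bs
        j = r.startB // bs
        if i != j:
            expected[i, j] *= loop_fold
            expected[j, i] *= loop_fold

    upper = np.triu_indices(n)
    counts = np.zeros((n, n))
    counts[upper] = rng.poisson(expected[upper])
    counts = counts + np.triu(counts, 1).T

    masked = frozenset()
    if gap_fraction > 0:
        n_gap = int(round(gap_fraction * n))
        if n_gap:
            gaps = rng.choice(n, size=n_gap, replace=False)
            counts[gaps, :] = 0
            counts[:, gaps] = 0
            masked = frozenset(int(g) for g in gaps)
    return ContactMatrix(layout, chrom, counts, masked_bins=masked)


# ---------------------------------------------------------------------------
# Feature tracks
# ---------------------------------------------------------------------------

# baseline per-bin value, class shifts, noise SD, and [lo, hi] clipping for
# each emitted track; directions follow the three-class structure above
DEFAULT_TRACK_MODEL = {
    "gene_density": {"base": 0.25, "shifts": {"active": 0.30, "inactive": 0.0, "HDF": -0.10}, "sd": 0.08, "clip": (0.0, 1.0)},
    "ltr_density": {"base": 0.40, "shifts": {"active": -0.20, "inactive": 0.0, "HDF": 0.30}, "sd": 0.08, "clip": (0.0, 1.0)},
    "mCpG": {"base": 0.50, "shifts": {"active": -0.10, "inactive": 0.20, "HDF": 0.05}, "sd": 0.06, "clip": (0.0, 1.0)},
    "mCHG": {"base": 0.40, "shifts": {"active": -0.10, "inactive": 0.20, "HDF": 0.05}, "sd": 0.06, "clip": (0.0, 1.0)},
    "mCHH": {"base": 0.10, "shifts": {"active": -0.05, "inactive": 0.15, "HDF": 0.02}, "sd": 0.04, "clip": (0.0, 1.0)},
    "H3K4me3": {"base": 1.0, "shifts": {"active": 2.0, "inactive": 0.0, "HDF": -0.3}, "sd": 0.30, "clip": (0.0, None)},
    "H3K9me2": {"base": 1.0, "shifts": {"active": -0.3, "inactive": 0.0, "HDF": 2.0}, "sd": 0.30, "clip": (0.0, None)},
    "H3K27me3": {"base": 1.0, "shifts": {"active": 0.0, "inactive": 0.8, "HDF": 0.0}, "sd": 0.30, "clip": (0.0, None)},
}


def simulate_tracks(
    layout: GenomeLayout,
    truth: SyntheticTruth,
    class_effects: dict | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Class-conditional per-bin feature tracks.

    Bins take the class of the domain containing their midpoint (bins in no
    domain keep the baseline).  Values are normal around base + class shift,
    clipped to each track's range; methylation-fraction tracks stay in
    [0, 1].  The "methylation" (overall) track is the mean of the three
    context tracks, matching a pooled-site level with equal context weight.
    ``class_effects`` overrides shift entries, e.g.
    ``{"ltr_density": {"HDF": 0.0}}``; a shift for an unknown class is an
    error.
    """
    rng = np.random.default_rng(seed)
    model = {k: {**v, "shifts": dict(v["shifts"])} for k, v in DEFAULT_TRACK_MODEL.items()}
    if class_effects:
        for track, shifts in class_effects.items():
            if track not in model:
                raise ValueError(f"unknown track {track!r}")
            for cls, val in shifts.items():
                if cls not in DOMAIN_CLASSES:
                    raise ValueError(f"unknown class label {cls!r}")
                model[track]["shifts"][cls] = val

    bs = layout.bin_size
    class_by_bin: dict[str, np.ndarray] = {}
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        cls = np.full(nb, "", dtype=object)
        sub = truth.domains[truth.domains["chrom"] == chrom]
        # "class" is a keyword, so address columns positionally
        for start, end, label in zip(sub["start"], sub["end"], sub["class"]):
            cls[start // bs : (end - 1) // bs + 1] = label
        class_by_bin[chrom] = cls

    tracks: dict[str, pd.DataFrame] = {}
    for name, spec in model.items():
        rows = []
        for chrom in layout.chrom_names:
            nb = layout.n_bins(chrom)
            cls = class_by_bin[chrom]
            mean = np.full(nb, spec["base"], dtype=float)
            for c in DOMAIN_CLASSES:
                mean[cls == c] += spec["shifts"].get(c, 0.0)
            vals = rng.normal(mean, spec["sd"])
            lo, hi = spec["clip"]
            if lo is not None:
                vals = np.maximum(vals, lo)
            if hi is not None:
                vals = np.minimum(vals, hi)
            starts = np.arange(nb) * bs
            ends = np.minimum(starts + bs, layout.length(chrom))
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": vals}))
        tracks[name] = pd.concat(rows, ignore_index=True)

    overall = tracks["mCpG"].copy()
    overall["value"] = (
        tracks["mCpG"]["value"] + tracks["mCHG"]["value"] + tracks["mCHH"]["value"]
    ) / 3.0
    tracks["methylation"] = overall
    return tracks


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def _boundary_zones(
    layout: GenomeLayout, boundaries: pd.DataFrame, halfwidth: int
) -> dict[str, list[tuple[int, int]]]:
    """Merged +-halfwidth zones around boundary midpoints, per chromosome."""
    zones: dict[str, list[tuple[int, int]]] = {}
    for chrom, g in boundaries.groupby("chrom"):
        ivs = []
        for r in g.sort_values("start").itertuples(index=False):
            mid = (r.start + r.end) // 2
            ivs.append((max(0, mid - halfwidth), min(layout.length(chrom), mid + halfwidth)))
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        zones[chrom] = merged
    return zones


def simulate_variants(
    layout: GenomeLayout,
    boundaries: pd.DataFrame,
    background_density: float = 1e-3,
    depletion_factor: float = 1.0,
    boundary_halfwidth: int = 20_000,
    seed: int = 0,
    deletion_density: float | None = None,
    deletion_mean_len: int = 300,
) -> dict:
    """SNPs and deletions from an inhomogeneous Poisson process.

    The rate is ``background_density * depletion_factor`` within
    ``boundary_halfwidth`` of a boundary midpoint and ``background_density``
    elsewhere.  Deletion starts follow the same process at
    ``deletion_density`` (default: background/20) with geometric lengths of
    mean ``deletion_mean_len`` bp.  Returns ``{"snps": ..., "deletions": ...}``.
    """
    if not 0 < depletion_factor <= 1:
        raise ValueError("depletion_factor must be in (0, 1]")
    if background_density <= 0:
        raise ValueError("background_density must be positive")
    if deletion_density is None:
        deletion_density = background_density / 20.0
    rng = np.random.default_rng(seed)
    zones = _boundary_zones(layout, boundaries, boundary_halfwidth)

    def _sample_positions(rate_bg: float) -> list[tuple[str, int]]:
        out = []
        for chrom in layout.chrom_names:
            length = layout.length(chrom)
            segs = []
            cur = 0
            for s, e in zones.get(chrom, []):
                if s > cur:
                    segs.append((cur, s, rate_bg))
                segs.append((s, e, rate_bg * depletion_factor))
                cur = e
            if cur < length:
                segs.append((cur, length, rate_bg))
            for s, e, rate in segs:
                k = rng.poisson(rate * (e - s))
                if k:
                    pos = np.sort(rng.integers(s, e, size=k))
                    out.extend((chrom, int(p)) for p in pos)
        return out

    snps = pd.DataFrame(_sample_positions(background_density), columns=["chrom", "pos"])
    del_starts = _sample_positions(deletion_density)
    rows = []
    for chrom, s in del_starts:
        length = int(rng.geometric(1.0 / deletion_mean_len))
        rows.append((chrom, s, min(s + length, layout.length(chrom))))
    deletions = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    deletions = deletions[deletions["end"] > deletions["start"]].reset_index(drop=True)
    return {"snps": snps, "deletions": deletions}


# ---------------------------------------------------------------------------
# Synteny blocks
# ---------------------------------------------------------------------------

def flat_alignable_profile(rel_pos: float) -> float:
    """Default alignable-rate profile: 0.8 everywhere along the domain."""
    return 0.8


def simulate_synteny_blocks(
    layout: GenomeLayout,
    domains: pd.DataFrame,
    n_breaks: int = 50,
    break_boundary_fraction: float = 0.0,
    alignable_fraction_profile=flat_alignable_profile,
    seed: int = 0,
    block_bp: int = 200_000,
    block_gap_bp: int = 5_000,
    min_break_spacing_bp: int = 500_000,
) -> dict:
    """Collinear block tiling of the reference with planted breaks.

    A fraction ``break_boundary_fraction`` of the ``n_breaks`` breaks is
    placed within one bin of a domain boundary; the rest are uniform.
    Breaks are spaced >= ``min_break_spacing_bp`` apart (rejection
    sampling).  Between breaks, the segment is tiled by ~``block_bp`` blocks
    separated by ``block_gap_bp`` gaps, all mapping collinearly to one query
    chromosome per segment (query chromosome switches at every break, so
    each break is detectable).  Per-block ``alignable_bp`` is the block
    length times the profile value at the block midpoint's relative position
    in its containing domain.

    Returns ``{"blocks": ..., "breaks": ...}``.
    """
    if n_breaks < 1:
        raise ValueError("n_breaks must be >= 1")
    if not 0 <= break_boundary_fraction <= 1:
        raise ValueError("break_boundary_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bs = layout.bin_size
    lengths = np.array([layout.length(c) for c in layout.chrom_names], dtype=float)
    chrom_probs = lengths / lengths.sum()

    dom_lookup = {}
    for c, g in domains.sort_values("start").groupby("chrom"):
        dom_lookup[c] = (g["start"].to_numpy(), g["end"].to_numpy())

    edge_positions = []
    for r in domains.itertuples(index=False):
        edge_positions.append((r.chrom, r.start))
        edge_positions.append((r.chrom, r.end))

    n_at_boundary = int(round(n_breaks * break_boundary_fraction))
    breaks: dict[str, list[int]] = {c: [] for c in layout.chrom_names}

    def _spaced_ok(chrom: str, pos: int) -> bool:
        return all(abs(pos - q) >= min_break_spacing_bp for q in breaks[chrom])

    tries = 0
    placed_bnd = 0
    while placed_bnd < n_at_boundary and tries < 100 * n_breaks:
        tries += 1
        chrom, edge = edge_positions[rng.integers(0, len(edge_positions))]
        pos = int(edge + rng.integers(-bs + 1, bs))
        pos = int(np.clip(pos, 1, layout.length(chrom) - 2))
        if _spaced_ok(chrom, pos):
            breaks[chrom].append(pos)
            placed_bnd += 1
    placed_uni = 0
    while placed_uni < n_breaks - placed_bnd and tries < 200 * n_breaks:
        tries += 1
        chrom = layout.chrom_names[rng.choice(len(layout.chrom_names), p=chrom_probs)]
        pos = int(rng.integers(1, layout.length(chrom) - 1))
        if _spaced_ok(chrom, pos):
            breaks[chrom].append(pos)
            placed_uni += 1

    def _rel_pos(chrom: str, pos: int) -> float:
        if chrom not in dom_lookup:
            return 0.5
        starts, ends = dom_lookup[chrom]
        j = np.searchsorted(starts, pos, side="right") - 1
        if j >= 0 and pos < ends[j]:
            return (pos - starts[j]) / (ends[j] - starts[j])
        return 0.0  # at an edge / outside: boundary-proximal

    block_rows, break_rows = [], []
    query_counter = 0
    for chrom in layout.chrom_names:
        bps = sorted(breaks[chrom])
        for p in bps:
            break_rows.append((chrom, p))
        cuts = [0] + bps + [layout.length(chrom)]
        for seg_start, seg_end in zip(cuts[:-1], cuts[1:]):
            qname = f"q{query_counter}"
            query_counter += 1
            qpos = 0
            pos = seg_start
            while pos < seg_end:
                end = min(pos + block_bp, seg_end)
                if end - pos >= 1_000:
                    frac = float(alignable_fraction_profile(_rel_pos(chrom, (pos + end) // 2)))
                    frac = float(np.clip(frac, 0.0, 1.0))
                    block_rows.append(
                        (qname, qpos, qpos + (end - pos), "+", chrom, pos, end,
                         int(round((end - pos) * frac)))
                    )
                qpos += (end - pos) + block_gap_bp
                pos = end + block_gap_bp
    blocks = pd.DataFrame(
        block_rows,
        columns=["qname", "qstart", "qend", "strand", "tname", "tstart", "tend", "alignable_bp"],
    )
    true_breaks = pd.DataFrame(break_rows, columns=["chrom", "pos"]).sort_values(
        ["chrom", "pos"], kind="stable"
    ).reset_index(drop=True)
    return {"blocks": blocks, "breaks": true_breaks}


def alignable_track_from_profile(
    layout: GenomeLayout,
    domains: pd.DataFrame,
    profile=flat_alignable_profile,
) -> pd.DataFrame:
    """Per-bin alignable fraction implied by a relative-position profile."""
    dom_lookup = {}
    for c, g in domains.sort_values("start").groupby("chrom"):
        dom_lookup[c] = (g["start"].to_numpy(), g["end"].to_numpy())
    bs = layout.bin_size
    rows = []
    for chrom in layout.chrom_names:
        nb = layout.n_bins(chrom)
        for b in range(nb):
            mid = b * bs + bs // 2
            if chrom in dom_lookup:
                starts, ends = dom_lookup[chrom]
                j = np.searchsorted(starts, mid, side="right") - 1
                rel = (
                    (mid - starts[j]) / (ends[j] - starts[j])
                    if j >= 0 and mid < ends[j]
                    else 0.0
                )
            else:
                rel = 0.5
            rows.append((chrom, b * bs, min((b + 1) * bs, layout.length(chrom)),
                         float(np.clip(profile(rel), 0.0, 1.0))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    layout: GenomeLayout,
    n_tissues: int = 5,
    n_reps: int = 3,
    specific_bins: float = 0.1,
    effect_log2fc: float = 4.0,
    seed: int = 0,
    base_log2_mean: float = 6.0,
    base_log2_sd: float = 1.0,
    dispersion: float = 0.01,
    expressed_fraction: float = 0.8,
) -> dict:
    """Negative-binomial multi-tissue replicated expression counts per bin.

    Each bin draws a lognormal base mean shared across tissues; a fraction
    ``specific_bins`` of expressed bins gets one randomly chosen tissue
    up-shifted by ``effect_log2fc`` (log2).  Counts are gamma-Poisson with
    the given dispersion; per-sample library factors vary at most twofold.
    A fraction ``1 - expressed_fraction`` of bins is silent (zero mean).

    Returns ``{"counts": DataFrame bins x samples, "sample_tissue": dict,
    "specific": DataFrame(bin, tissue)}``.
    """
    if n_tissues < 2 or n_reps < 1:
        raise ValueError("need n_tissues >= 2 and n_reps >= 1")
    if not 0 <= specific_bins <= 1:
        raise ValueError("specific_bins must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_bins = layout.total_bins
    tissues = [f"tissue{i + 1}" for i in range(n_tissues)]
    samples = [f"{t}_rep{r + 1}" for t in tissues for r in range(n_reps)]
    sample_tissue = {s: s.rsplit("_", 1)[0] for s in samples}

    base = 2.0 ** rng.normal(base_log2_mean, base_log2_sd, size=n_bins)
    silent = rng.random(n_bins) >= expressed_fraction
    base[silent] = 0.0

    mean = np.tile(base[:, None], (1, n_tissues))
    expressed_idx = np.nonzero(~silent)[0]
    n_specific = int(round(specific_bins * expressed_idx.size))
    spec_rows = []
    if n_specific:
        chosen = rng.choice(expressed_idx, size=n_specific, replace=False)
        for b in chosen:
            t = int(rng.integers(0, n_tissues))
            mean[b, t] *= 2.0 ** effect_log2fc
            spec_rows.append((int(b), tissues[t]))
    specific = pd.DataFrame(spec_rows, columns=["bin", "tissue"])

    lib_factor = rng.uniform(1.0, 2.0, size=len(samples))
    counts = np.zeros((n_bins, len(samples)), dtype=np.int64)
    for si, s in enumerate(samples):
        t = tissues.index(sample_tissue[s])
        mu = mean[:, t] * lib_factor[si]
        if dispersion > 0:
            shape = 1.0 / dispersion
            lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=n_bins) * mu / shape, 0.0)
        else:
            lam = mu
        counts[:, si] = rng.poisson(lam)

    # bin ids carry genomic coordinates for joining with other tracks
    bin_index = []
    bs = layout.bin_size
    for chrom in layout.chrom_names:
        for b in range(layout.n_bins(chrom)):
            bin_index.append(f"{chrom}:{b * bs}-{min((b + 1) * bs, layout.length(chrom))}")
    df = pd.DataFrame(counts, index=bin_index, columns=samples)
    return {"counts": df, "sample_tissue": sample_tissue, "specific": specific}
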