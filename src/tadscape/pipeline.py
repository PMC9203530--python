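"""End-to-end orchestration: synthetic data -> all analysis stages -> summary.

A :class:`RunConfig` (YAML-loadable, unknown keys rejected) fixes the genome
layout, every analysis threshold, and one global seed.  ``run_pipeline``
generates a dataset for two synthetic tissues, runs every stage, writes the
stage tables under the output directory, and emits a machine-readable
``summary.json`` that echoes all thresholds.  Runs are deterministic given
the seed: each stage draws from its own generator seeded by a stable hash of
(global seed, stage name).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartments as cp
from . import contact as ct
from . import domains as dm
from . import evolution as ev
from . import expression as xp
from . import io as tio
from . import loops as lp
from . import synthetic as syn
from .layout import GenomeLayout


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults are the standard analysis scale."""

    # genome
    chrom_names: list = field(default_factory=lambda: ["chr1", "chr2"])
    chrom_lengths: list = field(default_factory=lambda: [20_000_000, 20_000_000])
    bin_size: int = 40_000
    # thresholds
    flank_bp: int = 500_000
    step_bp: int = 5_000
    window_bp: int = 40_000
    merge_dist: int = 25_000
    reciprocal: float = 0.8
    fold: float = 2.0
    heavy_threshold: float = 0.25
    long_range_threshold: int = 20_000_000
    n_perm: int = 100
    cpm_threshold: float = 0.5
    pseudocount_cpm: float = 0.25
    window_bins: int = 5
    min_drop: float = 0.1
    subcompartment_levels: int = 3
    n_rel_bins: int = 10
    # generator
    decay_exponent: float = 1.0
    within_domain_fold: float = 2.0
    loop_fold: float = 3.0
    mean_depth: float = 50.0
    gap_fraction: float = 0.02
    background_density: float = 1e-3
    depletion_factor: float = 1.0
    boundary_halfwidth: int = 20_000
    n_breaks: int = 40
    break_boundary_fraction: float = 0.5
    n_tissues: int = 5
    n_reps: int = 3
    specific_bins: float = 0.1
    effect_log2fc: float = 4.0
    loops_per_chrom: int = 20
    # run
    seed: int = 0
    outdir: str = "results/pipeline"
    stages: list = field(
        default_factory=lambda: [
            "simulate", "contact", "compartments", "domains", "loops",
            "evolution", "expression",
        ]
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def layout(self) -> GenomeLayout:
        return GenomeLayout(self.chrom_names, self.chrom_lengths, self.bin_size)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (zlib.crc32(stage.encode("utf8")) ^ (global_seed * 2654435761)) % (2**31)


def _jitter_loops(loops: pd.DataFrame, layout: GenomeLayout, rng, keep: float = 0.7) -> pd.DataFrame:
    """Second-tissue loop set: keep a fraction of loops, shift the rest."""
    bs = layout.bin_size
    rows = []
    for r in loops.itertuples(index=False):
        if rng.random() < keep:
            rows.append(tuple(r))
        else:
            shift = int(rng.integers(2, 6)) * bs
            nb = layout.n_bins(r.chrom)
            sa = min(r.startA + shift, (nb - 3) * bs)
            sb = min(r.startB + shift, (nb - 1) * bs)
            if sb <= sa:
                sb = sa + bs
            rows.append((r.chrom, sa, sa + bs, sb, sb + bs))
    return pd.DataFrame(rows, columns=loops.columns.tolist())


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage; returns the summary dict (also written as
    ``summary.json`` under ``config.outdir``)."""
    layout = config.layout()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(config)}
    files: dict = {}

    # ----- simulate ---------------------------------------------------------
    sseed = stage_seed(config.seed, "simulate")
    truth = syn.plant_truth(
        layout, sseed,
        loops_per_chrom=config.loops_per_chrom,
        variant_depletion_factor=config.depletion_factor,
        break_boundary_fraction=config.break_boundary_fraction,
    )
    maps = {}
    for t_idx, tissue in enumerate(("tissue1", "tissue2")):
        maps[tissue] = {
            chrom: syn.simulate_contact_map(
                layout, truth, chrom,
                decay_exponent=config.decay_exponent,
                within_domain_fold=config.within_domain_fold,
                loop_fold=config.loop_fold,
                mean_depth=config.mean_depth,
                seed=stage_seed(sseed + t_idx, f"map:{tissue}:{chrom}"),
                gap_fraction=config.gap_fraction,
            )
            for chrom in layout.chrom_names
        }
    tracks = syn.simulate_tracks(layout, truth, seed=stage_seed(sseed, "tracks"))
    variants = syn.simulate_variants(
        layout, truth.boundaries,
        background_density=config.background_density,
        depletion_factor=config.depletion_factor,
        boundary_halfwidth=config.boundary_halfwidth,
        seed=stage_seed(sseed, "variants"),
    )
    synteny = syn.simulate_synteny_blocks(
        layout, truth.domains,
        n_breaks=config.n_breaks,
        break_boundary_fraction=config.break_boundary_fraction,
        seed=stage_seed(sseed, "synteny"),
    )
    expr = syn.simulate_expression(
        layout,
        n_tissues=config.n_tissues,
        n_reps=config.n_reps,
        specific_bins=config.specific_bins,
        effect_log2fc=config.effect_log2fc,
        seed=stage_seed(sseed, "expression"),
    )
    rng_loops = np.random.default_rng(stage_seed(sseed, "loops2"))
    loops_by_tissue = {
        "tissue1": truth.loops,
        "tissue2": _jitter_loops(truth.loops, layout, rng_loops),
    }

    tio.write_bed(truth.domains, out / "truth_domains.bed", extra_cols=["class"])
    tio.write_bed(truth.boundaries, out / "truth_boundaries.bed")
    tio.write_bedpe(truth.loops, out / "truth_loops.bedpe")
    tio.write_variants(variants["snps"], variants["deletions"], out / "variants.tsv")
    tio.write_blocks(synteny["blocks"], out / "synteny_blocks.tsv")
    tio.write_expression(expr["counts"], out / "expression.tsv")
    for name, tr in tracks.items():
        tio.write_bedgraph(tr, out / f"track_{name}.bedGraph")
        files[f"track_{name}"] = f"track_{name}.bedGraph"
    for tissue, per_chrom in maps.items():
        for chrom, m in per_chrom.items():
            p = out / f"contacts_{tissue}_{chrom}.tsv"
            ct.write_contact_matrix(m, p)
            files[f"contacts_{tissue}_{chrom}"] = p.name
    files.update(
        truth_domains="truth_domains.bed", truth_boundaries="truth_boundaries.bed",
        truth_loops="truth_loops.bedpe", variants="variants.tsv",
        synteny_blocks="synteny_blocks.tsv", expression="expression.tsv",
    )
    tio.write_manifest(files, config.seed, out / "manifest.yaml")
    summary["simulate"] = {
        "n_domains": int(len(truth.domains)),
        "n_boundaries": int(len(truth.boundaries)),
        "n_loops": int(len(truth.loops)),
        "n_snps": int(len(variants["snps"])),
        "n_deletions": int(len(variants["deletions"])),
        "n_blocks": int(len(synteny["blocks"])),
        "n_breaks_planted": int(len(synteny["breaks"])),
    }
    if "simulate" in config.stages and len(config.stages) == 1:
        _write_summary(summary, out)
        return summary

    # ----- contact ----------------------------------------------------------
    balanced = {
        tissue: {c: ct.balance_matrix(m) for c, m in per.items()}
        for tissue, per in maps.items()
    }
    oe = {
        tissue: {c: ct.observed_over_expected(b) for c, b in per.items()}
        for tissue, per in balanced.items()
    }
    ratios = {
        tissue: {
            c: ct.distance_profile(maps[tissue][c], config.long_range_threshold).long_short_ratio
            for c in layout.chrom_names
        }
        for tissue in maps
    }
    r1 = [ratios["tissue1"][c] for c in layout.chrom_names]
    r2 = [ratios["tissue2"][c] for c in layout.chrom_names]
    stat, pval = ct.compare_ratio_vectors(r1, r2)
    summary["contact"] = {
        "long_short_ratio": {t: ratios[t] for t in ratios},
        "ratio_wilcoxon_p": pval,
    }

    # ----- compartments -----------------------------------------------------
    gene_track = tracks["gene_density"]
    sub_assign = {}
    for tissue in oe:
        per = {}
        for c in layout.chrom_names:
            corr = ct.pearson_correlation(oe[tissue][c])
            per[c] = cp.call_subcompartments(
                corr, gene_track, levels=config.subcompartment_levels
            )
        sub_assign[tissue] = per
    enr = {}
    for c in layout.chrom_names:
        corr = ct.pearson_correlation(oe["tissue1"][c])
        e = cp.subcompartment_enrichment(sub_assign["tissue1"][c], tracks["ltr_density"], corr)
        enr[c] = {k: float(v) for k, v in e.items()}
    switch = {}
    for c in layout.chrom_names:
        tab = cp.switching_table(sub_assign["tissue1"][c], sub_assign["tissue2"][c])
        switch[c] = {
            "proportions": tab["proportions"],
            "ab_agreement": tab["ab_agreement"],
            "n_bins": tab["n_bins"],
        }
    summary["compartments"] = {"ltr_enrichment": enr, "switching": switch}

    # ----- domains ----------------------------------------------------------
    called = {}
    for tissue in balanced:
        dlist, blist = [], []
        for c in layout.chrom_names:
            d, b = dm.call_domains(
                balanced[tissue][c], window_bins=config.window_bins,
                min_drop=config.min_drop, sample=tissue,
            )
            dlist.append(d)
            blist.append(b)
        called[tissue] = {
            "domains": pd.concat(dlist, ignore_index=True),
            "boundaries": pd.concat(blist, ignore_index=True),
        }
    for tissue in called:
        tio.write_bed(called[tissue]["domains"][["chrom", "start", "end"]],
                      out / f"domains_{tissue}.bed")
        tio.write_bed(called[tissue]["boundaries"], out / f"boundaries_{tissue}.bed")
    pairs, cons_frac = dm.conserved_domains(
        called["tissue1"]["domains"], called["tissue2"]["domains"], config.reciprocal
    )
    bpairs, shared_frac = dm.shared_boundaries(
        called["tissue1"]["boundaries"], called["tissue2"]["boundaries"],
        config.bin_size,
    )
    jac = dm.coverage_jaccard(called["tissue1"]["domains"], called["tissue2"]["domains"])
    feature_names = ["gene_density", "ltr_density", "methylation", "H3K4me3", "H3K9me2", "H3K27me3"]
    classification = dm.classify_domains(
        called["tissue1"]["domains"].reset_index(drop=True),
        {k: tracks[k] for k in feature_names},
        layout,
        ltr_feature="ltr_density",
    )
    class_counts = classification.groups.value_counts().to_dict()
    profile = dm.boundary_profile(
        called["tissue1"]["boundaries"], gene_track, layout, flank_bp=config.flank_bp
    )
    profile.to_csv(out / "boundary_profile_gene_density.tsv", sep="\t", index=False)
    summary["domains"] = {
        "n_domains": {t: int(len(called[t]["domains"])) for t in called},
        "conserved_fraction": float(cons_frac),
        "shared_boundary_fraction": float(shared_frac),
        "coverage_jaccard": float(jac),
        "class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
    }

    # ----- loops ------------------------------------------------------------
    merged = lp.merge_loops(list(loops_by_tissue.values()), config.merge_dist)
    share = lp.shared_loops(loops_by_tissue, d=config.merge_dist)
    assoc = lp.loop_boundary_association(
        merged, called["tissue1"]["boundaries"], layout,
        n_perm=min(config.n_perm * 10, 1000),
        seed=stage_seed(config.seed, "loop_assoc"),
        domains=called["tissue1"]["domains"],
    )
    summary["loops"] = {
        "n_merged": int(len(merged)),
        "n_shared": share["n_shared"],
        "n_specific": share["n_specific"],
        "anchor_fraction": assoc["anchor_fraction"],
        "expected_fraction": assoc["expected_fraction"],
        "fisher_p": assoc["fisher_p"],
        "odds_ratio": assoc["odds_ratio"],
        "reciprocal_fraction": assoc["reciprocal_fraction"],
        "reciprocal_null_mean": assoc["reciprocal_null_mean"],
    }

    # ----- evolution --------------------------------------------------------
    qv = ev.assembly_qv(len(variants["snps"]), layout.total_bp)
    prof_snp = ev.boundary_variant_profile(
        variants["snps"], None, truth.boundaries, layout,
        window=config.window_bp, step=config.step_bp, flank=config.flank_bp,
        mode="SNP_count",
    )
    prof_del = ev.boundary_variant_profile(
        None, variants["deletions"], truth.boundaries, layout,
        window=config.window_bp, step=config.step_bp, flank=config.flank_bp,
        mode="deletion_bp",
    )
    prof_snp.to_csv(out / "variant_profile_snp.tsv", sep="\t", index=False)
    prof_del.to_csv(out / "variant_profile_del.tsv", sep="\t", index=False)
    detected = ev.detect_synteny_breaks(synteny["blocks"])
    align_track = syn.alignable_track_from_profile(layout, truth.domains)
    brk_profile, brk_enr = ev.break_boundary_enrichment(
        detected, truth.domains, align_track, layout,
        n_rel_bins=config.n_rel_bins, n_perm=config.n_perm,
        seed=stage_seed(config.seed, "break_enrichment"),
    )
    brk_profile.to_csv(out / "break_profile.tsv", sep="\t", index=False)
    at_zero = float(prof_snp.loc[prof_snp["offset_bp"] == 0, "ratio"].iloc[0])
    summary["evolution"] = {
        "qv": float(qv),
        "snp_ratio_at_0": at_zero,
        "snp_ratio_mean": float(np.nanmean(prof_snp["ratio"])),
        "del_ratio_at_0": float(prof_del.loc[prof_del["offset_bp"] == 0, "ratio"].iloc[0]),
        "n_breaks_detected": int(len(detected)),
        "break_enrichment": brk_enr.as_dict(),
    }

    # ----- expression -------------------------------------------------------
    cpm, tissue_cpm = xp.bin_cpm(expr["counts"], expr["sample_tissue"])
    mask = xp.testable_mask(tissue_cpm, threshold=config.cpm_threshold)
    tau = xp.tau_per_bin(tissue_cpm, mask)
    fc = xp.fold_change_classes(
        tissue_cpm["tissue1"][mask], tissue_cpm["tissue2"][mask],
        fold=config.fold, pseudocount=config.pseudocount_cpm,
    )
    # bins at shared vs tissue-specific called boundaries
    shared_idx = set(bpairs["index_a"])
    b1 = called["tissue1"]["boundaries"]
    shared_b = b1.loc[sorted(shared_idx)] if len(b1) else b1
    specific_b = b1.drop(index=sorted(shared_idx)) if len(b1) else b1
    bin_ids = tissue_cpm.index.to_series()
    coords = bin_ids.str.extract(r"(?P<chrom>[^:]+):(?P<start>\d+)-")
    bin_chrom = coords["chrom"].to_numpy()
    bin_start = coords["start"].astype(int).to_numpy()

    def _bins_at(bset: pd.DataFrame) -> np.ndarray:
        keys = {(r.chrom, r.start) for r in bset.itertuples(index=False)}
        return np.array([
            (c, s) in keys for c, s in zip(bin_chrom, bin_start)
        ])

    tau_vals = tau.to_numpy()
    ok = np.isfinite(tau_vals)
    at_shared = _bins_at(shared_b) & ok
    at_specific = _bins_at(specific_b) & ok
    if at_shared.sum() >= 2 and at_specific.sum() >= 2:
        test = xp.conservation_expression_test(
            tau_vals[at_shared], tau_vals[at_specific], alternative="shared_less"
        )
    else:
        test = {"p": float("nan"), "note": "too few boundary bins"}
    summary["expression"] = {
        "n_testable": int(mask.sum()),
        "median_tau": float(np.nanmedian(tau_vals)),
        "fc_class_counts": {k: int(v) for k, v in sorted(fc["class"].value_counts().items())},
        "tau_shared_vs_specific": test,
    }

    _write_summary(summary, out)
    return summary


def _write_summary(summary: dict, out: Path) -> None:
    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1, default=float) + "\n"
    )
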