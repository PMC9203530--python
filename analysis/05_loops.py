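"""Merge the demo loop calls across tissues, split shared vs tissue-specific
loops, and test whether loop anchors coincide with domain boundaries more
often than chance (analytic expectation + Fisher's exact test + permutation
reciprocal).

Writes results/05_loop_summary.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd
from _common import RESULTS, SCRATCH, SEED, demo_config

from tadscape import contact as ct
from tadscape import domains as dm
from tadscape import io as tio
from tadscape import loops as lp
from tadscape.pipeline import _jitter_loops, stage_seed


def main():
    cfg = demo_config()
    layout = cfg.layout()
    loops1 = tio.read_bedpe(SCRATCH / "truth_loops.bedpe")
    # second-tissue loop set: same jitter rule the pipeline uses
    sim_seed = stage_seed(cfg.seed, "simulate")
    rng = np.random.default_rng(stage_seed(sim_seed, "loops2"))
    loops2 = _jitter_loops(loops1, layout, rng)

    doms, bnds = [], []
    for chrom in layout.chrom_names:
        m = ct.read_contact_matrix(SCRATCH / f"contacts_tissue1_{chrom}.tsv", layout)
        d, b = dm.call_domains(ct.balance_matrix(m), window_bins=cfg.window_bins,
                               min_drop=cfg.min_drop)
        doms.append(d)
        bnds.append(b)
    domains = pd.concat(doms, ignore_index=True)
    boundaries = pd.concat(bnds, ignore_index=True)

    merged = lp.merge_loops([loops1, loops2], merge_dist=cfg.merge_dist)
    share = lp.shared_loops({"tissue1": loops1, "tissue2": loops2}, d=cfg.merge_dist)
    assoc = lp.loop_boundary_association(
        merged, boundaries, layout, n_perm=1000,
        seed=stage_seed(SEED, "loop_assoc"), domains=domains,
    )

    rows = [
        ("n_loops_tissue1", len(loops1)),
        ("n_loops_tissue2", len(loops2)),
        ("n_merged_union", len(merged)),
        ("n_shared_ge2_tissues", share["n_shared"]),
        ("n_tissue_specific", share["n_specific"]),
        ("anchor_fraction_at_boundaries", round(assoc["anchor_fraction"], 4)),
        ("expected_fraction_by_chance", round(assoc["expected_fraction"], 4)),
        ("fisher_p", assoc["fisher_p"]),
        ("odds_ratio", round(assoc["odds_ratio"], 3)),
        ("domains_with_anchored_boundary", round(assoc["reciprocal_fraction"], 4)),
        ("permutation_expectation", round(assoc["reciprocal_null_mean"], 4)),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "value"])
    RESULTS.mkdir(parents=True, exist_ok=True)
    df.to_csv(RESULTS / "05_loop_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(
        "\nHalf of the planted loops are domain corner-to-corner contacts, so "
        "anchors hit boundaries above the analytic chance level, and the "
        "fraction of domains with an anchored boundary clearly exceeds its "
        "permutation expectation; with ~100 anchors the Fisher test itself "
        "is underpowered at this demo scale."
    )


if __name__ == "__main__":
    main()
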