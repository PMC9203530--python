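"""Balance the demo contact maps, compute observed/expected and the
long/short contact ratio per chromosome, and compare tissues with a paired
Wilcoxon test.

Reads the triplet matrices written by 01_simulate_dataset.py; writes
results/02_long_short_ratios.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd
from _common import RESULTS, SCRATCH, demo_config

from tadscape import contact as ct


def main():
    cfg = demo_config()
    layout = cfg.layout()
    rows = []
    ratios = {}
    for tissue in ("tissue1", "tissue2"):
        ratios[tissue] = []
        for chrom in layout.chrom_names:
            m = ct.read_contact_matrix(SCRATCH / f"contacts_{tissue}_{chrom}.tsv", layout)
            bal = ct.balance_matrix(m)
            oe = ct.observed_over_expected(bal)
            prof = ct.distance_profile(m, threshold_bp=cfg.long_range_threshold)
            keep = bal.unmasked()
            rows.append(
                {
                    "tissue": tissue,
                    "chrom": chrom,
                    "long_short_ratio": prof.long_short_ratio,
                    "n_masked_bins": int((~keep).sum()),
                    "mean_oe": float(np.nanmean(oe.counts)),
                }
            )
            ratios[tissue].append(prof.long_short_ratio)
    df = pd.DataFrame(rows)
    stat, p = ct.compare_ratio_vectors(ratios["tissue1"], ratios["tissue2"])
    RESULTS.mkdir(parents=True, exist_ok=True)
    df.to_csv(RESULTS / "02_long_short_ratios.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\npaired Wilcoxon (tissue1 vs tissue2 per-chromosome ratios): p = {p:.3g}")
    print("Distance decay dominates: mean O/E per chromosome is ~1 after the transform.")


if __name__ == "__main__":
    main()
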