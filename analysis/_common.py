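"""Shared paths and the demo study configuration for the analysis scripts.

The demo genome is two 20-Mb chromosomes at 40-kb bins — large enough for
every statistic to be estimable, small enough to run in seconds.  Bulky
intermediates (contact matrices, variant lists) live under ``scratch/``;
the result tables each script writes live under ``results/``.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "demo_data"
RESULTS = ROOT / "results"

SEED = 1


def demo_config(outdir=None):
    from tadscape.pipeline import RunConfig

    return RunConfig(
        outdir=str(outdir or SCRATCH),
        seed=SEED,
        depletion_factor=0.5,          # planted boundary depletion of variants
        break_boundary_fraction=0.5,   # half of synteny breaks at boundaries
        long_range_threshold=5_000_000,  # 20-Mb demo chromosomes
    )
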