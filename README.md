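# tadscape

Integrative 3D-genome analysis for large, repeat-rich plant genomes:
A/B compartments and ranked subcompartments from Hi-C, TAD-like domain
calling and three-class (active / inactive / HDF) classification,
chromatin-loop comparison, boundary-centered evolutionary-constraint
statistics, and chromatin-conservation versus expression-stability
analysis. A synthetic-data module plants ground truth for every stage, so
the whole pipeline is testable end-to-end without sequencing data.

It is written for genomicists who have binned contact matrices, interval
calls and signal tracks in hand (from any upstream toolchain) and want the
*comparison layer*: the statistics that turn those objects into biological
statements.

## The statistics at the core

* **Compartments** — PC1 of the covariance of the Pearson-correlated O/E
  matrix assigns A/B (sign oriented by gene density); recursive bisection
  yields eight ranked subcompartments A1.1 … B2.2 (rank 8 … 1), with
  per-label feature enrichment `log2(median_label / median_genome)` and
  cross-tissue rank-switching tables.
* **Domains** — an insulation-style caller (mean contact in a window
  spanning the diagonal; boundaries at sufficiently deep local minima),
  reciprocal >80% conservation, one-bin boundary sharing, coverage Jaccard
  `|A∩B|/|A∪B|`, and complete-linkage Euclidean clustering of z-scored
  domain features into active / inactive / HDF groups.
* **Loops** — merge-within-25-kb across resolutions, shared-within-25-kb
  across tissues, and anchor–boundary association with analytic and
  permutation chance expectations plus Fisher's exact test.
* **Evolutionary constraint** — assembly quality `QV = -10·log10(P_err)`;
  observed/expected variant profiles in 40-kb windows sliding at 5-kb steps
  across ±500 kb of boundaries under a homogeneity null; synteny-break
  detection by chaining collinear alignment blocks; break enrichment along
  alignability-normalized scaled domain bodies against a 100-replicate
  permutation null with empirical p = (1 + #{null ≥ obs}) / (n_perm + 1).
* **Expression** — binned CPM with a >0.5-CPM testable filter, the tau
  tissue-specificity index `τ = Σ(1 − x_i/max x)/(n − 1)`, twofold
  up/down/stable classes, and one-sided rank-sum tests of whether bins at
  shared chromatin structures vary less in expression than bins at
  tissue-specific ones.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Generate a demo genome (two 20-Mb chromosomes, 40-kb bins) with a planted
variant depletion of 0.5 around domain boundaries and half of all synteny
breaks at boundaries, then run the constraint analysis:

```bash
python analysis/01_simulate_dataset.py
python analysis/06_evolutionary_constraint.py
```

which prints (seed 1):

```
assembly QV (SNP sites over genome): 30.07
SNP Obs/Exp at boundary midpoints: 0.503 (planted depletion 0.5)
SNP Obs/Exp at +-400-500 kb:       1.002 (background)
deletion Obs/Exp at boundaries:     0.376

synteny breaks detected: 39 (planted: see 01_dataset_summary.tsv)
terminal-cell break enrichment vs alignability-weighted null:
 observed  null_mean  null_sd      z      p  n_perm       seed
     23.0       8.18   2.9827 4.9686 0.0099     100 1417309438
```

Reading this: SNP density right at boundaries is half its genome-wide
expectation — exactly the planted depletion factor — and recovers to ~1 by
±400 kb; 39 of the 40 planted synteny breaks are re-detected from the raw
alignment blocks; and the breaks concentrate in the two boundary-proximal
cells of the scaled domain body about 2.8× above the alignability-weighted
random expectation (z ≈ 5, the smallest p the 100-replicate null can
produce is 1/101 ≈ 0.0099).

The other numbered scripts under `analysis/` cover contact structure
(long/short contact ratios), compartment switching, domain
calling/classification, loop sharing and association, and expression
stability; each writes its tables under `results/`. The same stages run as
one orchestrated, seeded pipeline:

```python
from tadscape.pipeline import RunConfig, run_pipeline
summary = run_pipeline(RunConfig(outdir="out", seed=7))
```

which writes all stage outputs plus a `summary.json` echoing every
threshold; two runs with the same seed are byte-identical.

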