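# Methods

`tadscape` implements the comparison-layer statistics of an integrative
3D-genome study of a large, repeat-rich plant genome: compartment and
subcompartment assignment from Hi-C, TAD-like domain calling and
classification, loop-set comparison, boundary-centered evolutionary
constraint, and the relationship between chromatin conservation and
expression stability. Everything runs end-to-end on synthetic data with
planted ground truth, so every stage is testable without the original
sequencing data.

## Coordinate conventions

All coordinates are 0-based, half-open. A genome is a `GenomeLayout`
(chromosome lengths + one bin size); the bin of position `p` is
`p // bin_size`, and a chromosome has `ceil(length / bin_size)` bins. The
standard analysis bin is 40 kb. Boundaries are always exactly one bin wide.

## Contact maps

**Balancing.** Matrices are balanced by iterative correction (Sinkhorn-style
matrix scaling): bins are rescaled until every unmasked row sum equals the
mean row sum, to relative tolerance 1e-5 (default; 200 iterations max).
Non-convergence returns the best iterate, flagged. Masked bins are those
with zero marginal plus the bottom 1% of nonzero marginals — standard Hi-C
practice for unmappable and low-coverage bins. Balancing preserves symmetry
and the zero pattern. Exact Knight–Ruiz scaling is not reproduced: every
downstream statistic depends only on the approximate doubly-stochastic
structure, which both algorithms deliver.

**Observed/expected.** Each entry is divided by the mean unmasked contact at
its diagonal offset on that chromosome. Offsets with zero mean give
undefined (NaN) entries, which stay excluded downstream. O/E is invariant to
global rescaling of the matrix.

**Distance statistics.** The long/short contact ratio is the summed contact
above a distance threshold (default 20 Mb) over the sum at or below it, with
the main diagonal excluded from the short-range term (self-ligation
artifacts dominate offset 0). Two samples are compared by a two-sided
paired Wilcoxon signed-rank test over per-chromosome ratios. The ratio is
computed from raw counts by default; balanced counts can be supplied
instead.

## Compartments and subcompartments

A/B assignment is the eigenvector method: PC1 of the covariance of the
bin-by-bin Pearson correlation of the O/E matrix. The sign of PC1 is fixed
automatically by an orientation track (gene density by default): the side
with the higher mean track value is "A". A degenerate PC1 (zero leading
eigenvalue) is an error.

Subcompartments come from recursive bisection: level 1 is the A/B split;
each part is re-bisected on its own correlation submatrix, with the
higher-orientation side taking the higher rank, down to eight labels
(A1.1 = rank 8 … B2.2 = rank 1). This is a deliberate, declared stand-in
for likelihood-based nested-clustering tools (e.g. Calder): it produces the
same ranked label vocabulary, which is all the downstream statistics
consume, without reproducing any external tool's internals. When a part
cannot be split (fewer than 2 bins, or a degenerate submatrix), it stops
subdividing and inherits its parent label padded to full depth. If PC1 does
not change sign inside a part, the part is split at the median PC1 score so
recursion can proceed; rank order is still set by the orientation track.

Per-label enrichment of a feature track is
`log2(median(track | label) / median(track | all labeled bins))` with a
1e-9 pseudocount guarding zero medians. Cross-sample switching tabulates
per-bin rank differences into `{<-2, -2, -1, 0, 1, 2, >2}` plus the level-1
A/B agreement fraction (A = ranks 5–8).

## Domain calling, comparison and classification

**Calling.** One insulation-style caller stands in for the external tools
the original analyses compared (the downstream statistics only need a
domain set, and external BED calls are accepted as input). The per-bin
signal is the mean contact in a `window x window` square spanning the
diagonal (default window 5 bins at 40 kb). A local signal minimum becomes a
boundary when its depth below the lower flanking local maximum exceeds
`min_drop` (default 0.1) times that maximum — a ratio criterion, so calls
are invariant to global matrix scaling. Domains tile the chromosome between
boundaries; runs of at least `window` masked bins split domains as gaps.
The defaults recover planted domains across fold >= 1.5 in simulation.

**Comparison.** Two domains are conserved when their overlap exceeds 80% of
*both* lengths (reciprocal rule; strict inequality), matched one-to-one
greedily by overlap with leftmost tie-break. Two boundaries are shared when
their bin intervals overlap or lie less than one bin apart, with the gap
measured edge-to-edge and the rule applied strictly (`gap < bin_size`);
matching is one-to-one, nearest first. Coverage similarity between samples
is the Jaccard index of covered base pairs; `1 - J` feeds hierarchical
clustering of samples. Shared fractions are reported over the smaller set,
making both comparisons symmetric in their arguments.

**Classification.** Per-domain mean feature values (TE/LTR density, gene
density, overall methylation, H3K4me3, H3K9me2, H3K27me3) are z-standardized
per feature and clustered by complete-linkage agglomeration on Euclidean
distance; the tree is cut at k = 3. Groups are auto-labeled: highest mean
gene + H3K4me3 z-score = active; of the rest, highest LTR + H3K9me2 =
HDF (heterochromatin-driven folding); the remainder = inactive (expected to
carry the highest overall methylation). The per-group z-means are returned
so the labeling can be audited. Per-domain features are means (not sums) of
bin values.

**Boundary profiles.** For offsets within ±500 kb (bin steps), a track is
averaged over all boundaries whose offset bin is on-chromosome; boundaries
near chromosome ends contribute only their valid offsets. Mean, SE and n
are reported per offset.

## Loops

Loop detection is upstream (BEDPE input); this package implements the
comparison layer. Merging groups loops transitively (single linkage) when
both anchor midpoints are within 25 kb, and represents each group by median
anchor midpoints snapped to the finest contributing resolution grid; the
operation is idempotent. Sharing between tissues uses the same both-anchors
within-25-kb rule; a loop is shared when matched in at least one other
tissue. The anchor/boundary association reports the fraction of anchors in
boundary bins against two chance expectations — the analytic boundary-bin
fraction of the genome, and a seeded permutation placing the same number of
anchors uniformly on unmasked bins (for the reciprocal statistic: the
fraction of domains with an anchored edge) — plus a two-sided Fisher's
exact test on the anchor-bin × boundary-bin 2×2 table. Both expectations
are provided because "by random chance" can reasonably mean either.

## Evolutionary constraint

**Assembly QV.** `QV = -10 log10(variant sites / covered sites)`; zero
variant sites returns the capped sentinel 99.

**Variant profiles.** A 40-kb window slides in 5-kb steps across ±500 kb of
each boundary midpoint. Observed = SNP count (or deletion-covered bp)
summed over boundaries; expected = genome-wide density × summed in-genome
window bp, under the assumption that variants are homogeneously distributed.
Windows are clipped at chromosome ends with the expectation reduced
proportionally. Insertions are not analyzed. Observed and expected are
summed (not averaged) across boundaries; their ratio is identical under
homogeneity.

**Synteny breaks.** Alignment blocks (PAF-like, reference on the target
side) are chained when consecutive blocks share query chromosome and
strand, are query-order consistent for that strand, and have reference and
query gaps <= 100 kb; chains spanning < 10 kb are dropped. A break is
emitted at the reference midpoint between consecutive chains. Overlapping
reference blocks are resolved by keeping the longer, with a warning. The
chaining rule is this package's own declared procedure; both thresholds are
exposed.

**Break enrichment.** Breaks map to the relative position of their
containing domain (positions outside any domain snap to the nearest edge
cell), histogrammed into 10 cells. Each cell is divided by the *relative*
mean alignable fraction of the genomic bins mapping to it (relative to the
genome mean, so a uniform rescaling of the alignability track cancels) —
this removes the bias that boundary-proximal sequence is more conserved and
hence more alignable. The observed statistic is the normalized count in the
two terminal (boundary-proximal) cells. The null re-places the same number
of breaks at random bin midpoints with probability proportional to
alignable fraction, 100 seeded replicates by default; the empirical p uses
the add-one rule, `p = (1 + #{null >= obs}) / (n_perm + 1)`, so p is never
zero and never below `1/(n_perm+1)`.

## Epigenome tracks

Per-bin methylation level is the percentage of heavily methylated cytosines
— sites whose methylated reads are at least 25% of mapped reads — computed
per context (CpG, CHG, CHH). The "overall" level pools the sites of all
three contexts, which keeps it bounded by 100 and consistent with the
per-context definition (the alternative reading, summing the three
percentages, is not bounded). Bins with no sites are undefined, not zero,
and are omitted from bedGraph export. ChIP/RNA coverage per bin is
fragment-midpoint counts normalized to CPM; midpoint assignment (rather
than bp-overlap proration) matches read-count semantics at bin scale.

## Expression

Counts per bin are CPM-normalized per sample; replicates are averaged into
tissue values; a bin is testable when its tissue-mean CPM exceeds 0.5
(strictly) in at least one compared tissue. Tau is
`sum(1 - x_i/max(x)) / (n - 1)`: 0 for uniform, 1 for single-tissue
expression. Fold-change classes between two tissues use
`ratio = (cpm2 + 0.25) / (cpm1 + 0.25)`: up if ratio > 2, down if
ratio < 1/2, else stable (the 0.25-CPM pseudocount guards near-zero bins
that pass the testable filter; exposed in the config). The
conservation-vs-expression comparison is a one-sided Wilcoxon rank-sum test
(shared < specific): the two groups are unpaired, so the rank-sum form is
correct even though a paired signed-rank variant is exposed for matched
designs. Differential-expression model fitting is out of scope; the twofold
classes plus Fisher's exact machinery stand in for enrichment questions.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (parameters, seed) and default to the
study's conditions where stated:

* **Contact maps** — Poisson counts around
  `depth * (d+1)^-alpha * fold_domain^[same domain] * fold_loop^[anchor pair]`,
  the simplest generative model whose O/E has a closed form (enabling the
  analytic checks in the tests). Defaults: alpha = 1, domain fold 2, loop
  fold 3, mean depth 50 at the first diagonal; 2% of bins zeroed as
  unmappable gaps to exercise masking.
* **Domains** — tile each chromosome; class mix and mean sizes follow the
  observed three-class catalogue (active ~734 kb / 12%, inactive ~698 kb /
  38%, HDF ~1.1 Mb / 50%); per-class size means are parameters because the
  full size distributions are not published.
* **Tracks** — class-conditional normals with directions matching the
  three-class structure (active: genes + H3K4me3; HDF: LTR + H3K9me2;
  inactive: highest methylation); methylation fractions clipped to [0, 1];
  the overall methylation track is the mean of the three contexts (equal
  site weight).
* **Variants** — inhomogeneous Poisson with rate
  `background * depletion_factor` within ±halfwidth of boundary midpoints;
  deletion lengths geometric with mean 300 bp (multi-bin coverage without
  dominating any window).
* **Synteny blocks** — collinear ~200-kb blocks with 5-kb gaps per segment,
  query chromosome switching at every planted break; a configurable
  fraction of breaks within one bin of a domain boundary; per-block
  alignable bp from a relative-position profile (default flat 0.8). Breaks
  are spaced >= 500 kb so each is recoverable by chaining.
* **Expression** — gamma-Poisson (NB) counts with dispersion 0.01 around a
  shared lognormal base mean; 80% of bins expressed; a configurable fraction
  of bins gets one tissue up-shifted by a configurable log2 effect; library
  sizes vary at most twofold; 5 tissues × 3 replicates by default.

Not emulated: read-level data, restriction-fragment structure, the Rabl
anti-diagonal, trans contacts, genuine biological covariance between
expression and chromatin (the demo's conservation-vs-expression test is
therefore null by construction; the planted-association version lives in
the test suite). Passing tests show the *statistics* are computed correctly
under a known generative model — not that real data satisfies that model.

## Pipeline and problem sizes

The demo configuration is two 20-Mb chromosomes at 40-kb bins (500 bins
each), two synthetic Hi-C tissues, 5 expression tissues × 3 replicates,
100 permutations for enrichment nulls. This scale keeps a full end-to-end
run in seconds while leaving every statistic estimable; all sizes are
config knobs. Runs are deterministic given the global seed: each stage
draws from a generator seeded by a stable CRC32-based hash of (seed, stage
name), and the run summary (`summary.json`) echoes every threshold. The
demo lowers the long/short distance threshold to 5 Mb because a 20-Mb
chromosome has no >20-Mb contacts.

## Known limitations

* The subcompartment stand-in shares only the label vocabulary and rank
  semantics with likelihood-based tools; on real data their assignments
  would differ in detail.
* The insulation caller is single-scale; nested domain hierarchies are not
  modeled.
* The greedy one-to-one matchers are order-stable but not globally optimal;
  with heavily fragmented calls a maximum matching could differ.
* Fisher's exact test on bin counts treats bins as independent, which real
  Hi-C data violates at short range; the permutation expectation is the
  more defensible null and both are reported.
* `conserved_domains`/`shared_boundaries` report shared fractions over the
  smaller set; other denominators (union, per-sample) are easy to derive
  from the returned matchings.
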