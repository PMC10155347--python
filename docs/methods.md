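# Methods

## The classification model

A sequenced cfDNA fragment carries binary 5mC calls `m_j ∈ {0,1}` at the
CpG sites it covers. A tissue reference methylome gives, at each site,
the percent of that tissue's molecules that are methylated,
`m'_j ∈ [0,100]`. Under the assumption that the reference percentage is
the per-molecule methylation probability and that sites are independent,
the probability that the read's call agrees with a molecule of that
tissue at site *j* is `m'_j` when `m_j = 1` and `100 − m'_j` when
`m_j = 0` (on a 0–100 scale). Averaging over the `N_sites` informative
sites the read covers gives the match score `f^tissue`, the mean
per-site agreement probability. Both tissue scores are computed over the
*same* informative-site table — sites present in both references with
coverage > 4 in both and differing methylation — so that the normalized
tumor score `p = f^tumor / (f^tumor + f^immune)` compares like with
like. Reads covering no table site, or with both scores zero, are
skipped.

Classification uses a dual threshold: immune when `p < t_immune`
(default 0.1), tumor when `p > t_cancer` (default 0.9), strict
inequalities, otherwise unclassified. Unclassified reads are excluded
from the tumor read fraction `n_tumor / (n_tumor + n_immune)`, the
sample-level tumor-burden estimate. Each classified read counts once,
regardless of how many CpGs it carries. The stringency/coverage
trade-off is explicit: tighter thresholds raise per-read confidence and
lower the fraction of reads classified.

For a read drawn from its own reference (calls Bernoulli(`m'/100`)),
the expected score is

    E[f_self] = (1/N) Σ_j (m'_j² + (100 − m'_j)²) / 100,

which is maximal for fully methylated or unmethylated sites and 50 at
`m' = 50` — the formal statement that intermediate-methylation sites are
uninformative. The test suite and acceptance script verify the empirical
mean against this closed form.

### ROC convention

The dual-threshold system does not collapse to one ROC curve by itself.
We follow the convention of one curve per immune threshold: the cancer
threshold is swept along a grid, each operating point contributes
(1 − specificity, sensitivity), and the AUC is the trapezoidal integral
with (0,0) and (1,1) anchors. Sensitivity and specificity are computed
over classified reads only by default (`classified_only=False` counts
unclassified reads against both rates); the fraction of reads classified
is reported alongside every operating point. The headline scalar is the
AUC at the most stringent (lowest) immune threshold in the grid.

## Reference construction

Intersection is keyed strand-insensitively on the C position of the CpG
dyad (minus-strand records shifted by −1; co-located records merged by
coverage-weighted mean), because opposite-strand calls of one dyad
measure the same epialleles; a flag preserves strands. "Differing"
methylation means any nonzero difference by default; `min_abs_diff`
exposes a stricter cutoff since near-zero differences carry almost no
signal per site.

Gene-level methylation is the unweighted mean of per-site percent
methylation over covered sites (coverage > 0) in `[start, end)`; a
coverage-weighted variant is available behind a flag. Genes with no
covered site are missing, never 0 — absence of data is not
hypomethylation. Overlapping genes each receive every site they span.
The differential panels keep, per direction, up to 25 protein-coding
genes with tumor and blood on opposite sides of 50% methylation, ranked
by |tumor − blood|, ties broken lexicographically by gene id.

## Admixture and titration

Mixtures draw `round_half_up(total · fraction)` tumor reads and the
complement immune reads, each without replacement (mirroring physical
mixing of distinct molecules), with a seeded PCG64 generator; a truth
table records every read's origin. Replicate *r* of the titration grid
uses seed `base_seed + r`. With fully divergent references the estimator
is unbiased and its error is binomial in the number of classified reads.

## Cohort statistics

- **Genome-wide methylation**: unweighted mean over sites with
  coverage > 0.
- **Fragment summary**: libraries larger than 50,000 fragments are
  subsampled (seeded, without replacement); mono-nucleosome =
  length < 250.5 bp, di-nucleosome = 250.5 < length ≤ 600 bp, longer
  fragments excluded. The half-bp boundary is unambiguous for integer
  lengths; no minimum length is applied to the mono bin.
- **Differential methylation**: genes covered by at least one sample and
  with nonzero standard deviation of the per-sample means are tested;
  Welch's two-sample t-test by default (`equal_var=True` switches to
  Student's) — Welch is the safer default because cancer cohorts show
  larger between-sample variance than healthy ones. Benjamini–Hochberg
  FDR, significant at q < 0.01. Genes with fewer than two non-missing
  values in either group are skipped (logged), i.e. missing sample
  values are dropped pairwise rather than imputed.
- **Biotype filters**: cohort mode removes pseudogene and unprocessed
  classes, TEC, lncRNA and miRNA, retaining unknown biotypes; reference
  mode keeps only `protein_coding`.
- **Promoters**: 2 kb upstream to 500 bp downstream of the gene start,
  strand-reflected for minus-strand genes, clipped at 0 — a constant
  2,500 bp window except at contig edges.
- **Random-grouping control**: group sizes are preserved, labels
  shuffled with a seeded PRNG, and the full differential analysis rerun
  per repeat (default 20); with true signal the significant-gene counts
  should collapse toward zero. Running it with the identity permutation
  reproduces the true-label analysis exactly.
- **Longitudinal tracking**: a panel gene is tumor-concordant at a
  timepoint when its cfDNA mean lies on the tumor side of 50%
  (hyper > 50, hypo < 50); genes missing at a timepoint leave its
  denominator.

## Synthetic data: what it emulates and what it does not

The generator produces one synthetic contig (`chrS`) with CpGs every
40 bp. Background methylation is drawn from a scaled Beta(0.25, 0.25) —
the U-shape of real genomes, where most CpGs are near 0% or 100%. At
informative sites the two tissues are separated by exactly the requested
divergence (random direction, center uniform within the feasible range);
non-informative sites carry identical values in both tissues so the
truth set is exact. Per-site coverage is Poisson (mean 30, floor 5 so
the default coverage filter keeps simulated sites). Reads are placed
uniformly; lengths follow an 80/20 normal mixture at 167/334 bp
(SD 10/15, floor 50 bp), the mono/di-nucleosome ladder of cfDNA; calls
are independent Bernoulli(`m'/100`) draws. Cohort tables use per-gene
baselines uniform on [20, 80] plus Gaussian noise, with planted genes
shifted by the effect size (alternating sign) in group b, clipped to
[0, 100].

Deliberately absent: CpG-density variation and hotspots, basecalling
error, strand asymmetry, correlated methylation along a molecule,
copy-number structure, and library-prep biases. Passing tests therefore
demonstrate the correctness of the computations and the behavior of the
estimators under the model's assumptions — not classification
performance on real cfDNA, where reference divergence is far from
complete and calls are noisy.

Default per-read modification-probability binarization is `p ≥ 0.5`;
callers emit probabilities and no universal cutoff exists, so it is
configurable everywhere the TSV is read.

## Numerical choices and degenerate inputs

- All coordinates 0-based half-open internally; GTF converted on read
  (start − 1). BedMethyl writes shortest-round-trip floats so the
  read/write cycle is lossless.
- `p` exactly at a threshold is unclassified (strict inequalities).
- Zero-denominator normalization (`f^tumor = f^immune = 0`) marks the
  read skipped, excluded from numerator and denominator of the tumor
  read fraction.
- Empty intersections and empty panels warn rather than fail; an empty
  informative-site table at classification time is an error.
- Tied |delta| in panel ranking breaks by gene id; mergesort keeps all
  sorts stable.
- Seeded operations use `numpy.random.default_rng` (PCG64), stable
  across platforms.

## Problem sizes

The test suite and acceptance script run, per section: 10,000-site
references with 1,000 oracle-checked reads; 2,000-site references with
2,000–5,000 reads for the ROC limits; a 7-fraction × 2-depth × 5-replicate
titration from 10,000-read pools; 100,000 reads for the closed-form
score check; and 200-gene cohorts with 10 samples per group, 20 null and
5 signal repeats plus a 20-repeat permutation control. These sizes give
sampling errors comfortably inside the asserted tolerances while keeping
a full run in tens of seconds on one CPU.

## Known limitations

Two-tissue classification only (no multi-class deconvolution or
reference-free methods); no DMR segmentation; no haplotype phasing; the
BAM modified-base adapter handles the common single-modification C+m
case and treats the per-read TSV as the canonical interchange.
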