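# methylotype

Single-molecule methylation classification for cell-free DNA (cfDNA).

Blood plasma carries short, nucleosome-protected DNA fragments shed by
dying cells. In cancer patients a subset of these fragments originates
from the tumor (ctDNA), and tumor cells carry a distinctive 5mC
methylation landscape. Long-read sequencing with modified-base calling
reads the methylation state of every CpG on every individual molecule,
which makes it possible to ask, read by read: *does this fragment's
methylation pattern look like the patient's tumor, or like their immune
cells?* The fraction of confidently tumor-matched reads is then a
tumor-burden proxy that can be tracked across longitudinal blood draws.

`methylotype` implements that analysis stack for anyone working with
per-read methylation calls (e.g. from nanopore modified-base BAMs):

- **Reference construction** — intersect tumor and immune (PBMC)
  BedMethyl profiles on genomic position with a coverage filter
  (coverage > 4 in both), keeping *informative sites* where the two
  tissues' methylation differs; build top-25 hyper/hypo differential
  gene panels for longitudinal gene-level tracking.
- **Read classification** — score each read *i* against each tissue
  reference over the informative sites it covers:

  ```
  f_i^tissue = (1/N_sites) * Σ_j prob(m_j = m'_j),
  prob(m_j = m'_j) = m'_j        if m_j = 1
                     100 − m'_j  if m_j = 0
  ```

  where `m_j ∈ {0,1}` is the read's call at site *j* and `m'_j ∈ [0,100]`
  the tissue's percent methylation. The normalized tumor score
  `p_i = f_i^tumor / (f_i^tumor + f_i^immune)` is thresholded with a dual
  cutoff (immune if `p < 0.1`, tumor if `p > 0.9` by default); reads in
  between stay unclassified and are dropped from the final tally.
- **Admixture & titration** — seeded in silico mixtures of labelled read
  pools at controlled tumor fractions and depths, with ROC/AUC threshold
  sweeps against the known origins.
- **Cohort statistics** — genome-wide mean methylation,
  mono/di-nucleosome fragment-size summaries (250.5 bp boundary, 600 bp
  maximum, 50,000-read subsample), gene- and promoter-level differential
  methylation (Welch t-test, Benjamini–Hochberg FDR at q < 0.01), and a
  random-grouping permutation control.
- **Synthetic data** — a first-class generator producing two-tissue
  methylomes with tunable divergence, Bernoulli per-read CpG calls,
  nucleosome-ladder fragment lengths, and cohorts with planted
  differential genes, so the whole pipeline is testable without any
  sequencing data.

## Worked example

Simulate a tumor/immune reference pair, build the informative-site
table, create a 25% tumor admixture at 5,000 reads, and estimate its
tumor fraction:

```python
from methylotype import *

spec = MethylomeSimSpec(n_sites=5000, informative_fraction=0.5,
                        divergence=80, seed=42)
tumor, immune, truth = simulate_reference_pair(spec)
sites = select_informative_sites(intersect_profiles(tumor, immune))
print("informative sites:", len(sites))

t_reads, _ = simulate_reads(tumor, ReadSimSpec(n_reads=4000, seed=1))
i_reads, _ = simulate_reads(immune, ReadSimSpec(n_reads=4000, seed=2))
mixed, mix_truth = mix_reads(t_reads, i_reads,
                             AdmixtureSpec(0.25, 5000, seed=3))
scores, summary = classify_sample(mixed, sites)
print("tumor_read_fraction: %.4f" % summary.tumor_read_fraction)
print("AUC: %.3f" % roc_sweep(scores, mix_truth).auc_stringent)
```

Output:

```
informative sites: 2500
tumor_read_fraction: 0.2474
AUC: 0.995
```

2,500 of the 5,000 simulated CpGs differ between the tissues and pass
the coverage filter. Of the 5,000 mixed reads, 1,750 are confidently
classified at the stringent (0.1, 0.9) thresholds — short reads covering
few informative CpGs land between the thresholds and are excluded — and
the tumor share among the confident calls, 0.2474, recovers the true
25% mixing fraction. The ROC sweep over the cancer threshold at immune
threshold 0.1 yields an AUC of 0.995 at this reference divergence.

The same workflow is available from the shell:

```
methylotype sim refs --n-sites 5000 --divergence 80 --seed 42 --out refs/
methylotype refbuild --tumor refs/tumor.bed --immune refs/immune.bed --out sites.tsv
methylotype sim reads --source refs/tumor.bed --label tumor --n-reads 4000 --out reads/
methylotype classify --sites sites.tsv --reads reads/tumor_calls.tsv
```

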