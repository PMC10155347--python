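"""Cohort-level methylation and fragmentation statistics.

Covers the sample- and cohort-level analyses around the read classifier:

* genome-wide mean methylation over covered CpG sites;
* nucleosome fragment-size summary (mono vs di-nucleosome counts at the
  250.5 bp boundary, 600 bp maximum, seeded 50,000-read subsample);
* gene- and promoter-level differential methylation between two groups
  (Welch t-test per gene, Benjamini-Hochberg FDR, q < 0.01), with the
  biotype filters applied before testing;
* a random-grouping permutation control for the differential analysis;
* longitudinal tracking of tumor-concordant panel genes in cfDNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylome_io import GeneAnnotation, ReferenceMethylome, ValidationError
from .reference_builder import GenePanel

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSummary",
    "genome_wide_mean",
    "fragment_summary",
    "diff_methylation",
    "filter_annotations",
    "promoter_regions",
    "random_grouping_control",
    "longitudinal_gene_tracking",
]

#: Boundary between mono- and di-nucleosome fragments (bp). The half-bp
#: value makes the boundary unambiguous for integer lengths.
MONO_DI_CUTOFF = 250.5

#: Fragments longer than this are excluded from the nucleosome tally.
MAX_FRAGMENT_LEN = 600

#: Library subsample size for the fragment summary.
FRAGMENT_SUBSAMPLE = 50_000

#: FDR significance cutoff for differential methylation.
DEFAULT_Q_CUTOFF = 0.01

#: Promoter window: 2 kb upstream to 500 bp downstream of the gene start,
#: strand-aware.
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500

#: Biotype classes removed in cohort mode: pseudogene classes (including
#: unprocessed), to-be-experimentally-confirmed (TEC), lncRNA, miRNA.
COHORT_EXCLUDED_BIOTYPES = ("TEC", "lncRNA", "miRNA")


@dataclass(frozen=True)
class FragmentSummary:
    """Mono/di-nucleosome fragment counts for one library.

    ``mono_di_ratio`` is n_mono / n_di, or None when no di-nucleosome
    fragments were observed.
    """

    n_mono: int
    n_di: int
    n_excluded: int

    @property
    def mono_di_ratio(self) -> float | None:
        return self.n_mono / self.n_di if self.n_di else None


def genome_wide_mean(methylome: ReferenceMethylome) -> float:
    """Mean percent methylation over all sites with coverage > 0.

    Returns NaN when no site is covered.
    """
    covered = methylome.sites.loc[methylome.sites["coverage"] > 0, "pct_meth"]
    if len(covered) == 0:
        return float("nan")
    return float(covered.mean())


def fragment_summary(
    lengths: np.ndarray | list[int],
    cutoff: float = MONO_DI_CUTOFF,
    max_len: float = MAX_FRAGMENT_LEN,
    subsample_n: int = FRAGMENT_SUBSAMPLE,
    seed: int = 0,
) -> FragmentSummary:
    """Tally mono- vs di-nucleosome fragments.

    When the library holds more than ``subsample_n`` fragments a seeded
    subsample (without replacement) is taken first; smaller libraries are
    used in full. Then mono = count(length < cutoff), di = count(cutoff <
    length <= max_len), excluded = count(length > max_len).
    """
    lengths = np.asarray(lengths)
    if len(lengths) and lengths.min() <= 0:
        raise ValidationError("fragment lengths must be positive")
    if len(lengths) > subsample_n:
        rng = np.random.default_rng(seed)
        lengths = rng.choice(lengths, size=subsample_n, replace=False)
    n_mono = int((lengths < cutoff).sum())
    n_di = int(((lengths > cutoff) & (lengths <= max_len)).sum())
    n_excluded = int((lengths > max_len).sum())
    return FragmentSummary(n_mono=n_mono, n_di=n_di, n_excluded=n_excluded)


def diff_methylation(
    tables: pd.DataFrame,
    groups: pd.Series,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t-test with Benjamini-Hochberg FDR.

    ``tables`` is the long-form gene-methylation table (sample, gene_id,
    mean_pct, n_sites); ``groups`` maps sample -> group label (exactly
    two labels). Genes are first filtered to those covered by at least
    one sample (>= 1 non-missing mean) and with standard deviation of
    the per-sample means greater than zero; genes with fewer than two
    non-missing values in either group are skipped. The default test is
    Welch's (``equal_var=False``).

    Returns a DataFrame (gene_id, mean_group_a, mean_group_b,
    t_statistic, p_value, q_value, significant), sorted by q_value, with
    group a the lexicographically first label.
    """
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {labels}")
    a_samples = groups[groups == labels[0]].index
    b_samples = groups[groups == labels[1]].index
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValidationError("each group needs >= 2 samples")

    wide = tables.pivot(index="gene_id", columns="sample", values="mean_pct")
    # coverage filter: >= 1 non-missing mean anywhere; SD of the means > 0
    covered = wide.notna().any(axis=1)
    sd = wide.std(axis=1, ddof=1)
    testable = wide[covered & (sd > 0)]

    records = []
    for gene_id, row in testable.iterrows():
        a = row[row.index.isin(a_samples)].dropna().to_numpy(dtype=float)
        b = row[row.index.isin(b_samples)].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.debug(
                "gene %s skipped: <2 non-missing values in a group "
                "(%d vs %d)", gene_id, len(a), len(b)
            )
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        records.append((gene_id, a.mean(), b.mean(), float(t), float(p)))
    result = pd.DataFrame(
        records,
        columns=["gene_id", "mean_group_a", "mean_group_b", "t_statistic", "p_value"],
    )
    if len(result) == 0:
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    # zero-variance-within-both-groups genes can yield NaN t; drop them
    result = result.dropna(subset=["p_value"]).reset_index(drop=True)
    _, q, _, _ = multipletests(result["p_value"], method="fdr_bh")
    result["q_value"] = q
    result["significant"] = result["q_value"] < q_cutoff
    return result.sort_values("q_value", kind="mergesort").reset_index(drop=True)


def filter_annotations(
    genes: list[GeneAnnotation], mode: str = "cohort"
) -> list[GeneAnnotation]:
    """Apply the biotype filters used before gene-level analyses.

    ``cohort`` mode removes pseudogene classes (any biotype containing
    "pseudogene"), unprocessed classes, TEC, lncRNA and miRNA, keeping
    everything else (unknown biotypes retained). ``reference`` mode keeps
    only protein_coding genes.
    """
    if mode == "reference":
        return [g for g in genes if g.biotype == "protein_coding"]
    if mode != "cohort":
        raise ValidationError(f"unknown filter mode {mode!r}")
    kept = []
    for g in genes:
        bt = g.biotype
        if "pseudogene" in bt or "unprocessed" in bt:
            continue
        if bt in COHORT_EXCLUDED_BIOTYPES:
            continue
        kept.append(g)
    return kept


def promoter_regions(
    genes: list[GeneAnnotation],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> pd.DataFrame:
    """Strand-aware promoter windows around gene starts.

    Plus strand: [start - upstream, start + downstream); minus strand:
    [end - downstream, end + upstream); clipped at 0. Returns a BED-like
    DataFrame (chrom, start, end, gene_id, strand).
    """
    records = []
    for g in genes:
        if g.strand == "+":
            start, end = g.start - upstream, g.start + downstream
        else:
            start, end = g.end - downstream, g.end + upstream
        records.append((g.chrom, max(start, 0), max(end, 0), g.gene_id, g.strand))
    return pd.DataFrame(
        records, columns=["chrom", "start", "end", "gene_id", "strand"]
    )


def random_grouping_control(
    tables: pd.DataFrame,
    groups: pd.Series,
    n_repeats: int = 20,
    seed: int = 0,
    q_cutoff: float = DEFAULT_Q_CUTOFF,
) -> list[int]:
    """Permutation control: rerun the differential analysis under random
    relabelings.

    Group sizes are preserved; each repeat shuffles the sample labels
    with a seeded PRNG, reruns :func:`diff_methylation`, and records the
    number of genes passing q < ``q_cutoff``. With real biological signal
    these counts should collapse toward zero relative to the true-label
    run.
    """
    rng = np.random.default_rng(seed)
    counts = []
    labels = groups.to_numpy().copy()
    for _ in range(n_repeats):
        perm = rng.permutation(labels)
        perm_groups = pd.Series(perm, index=groups.index, name="group")
        result = diff_methylation(tables, perm_groups, q_cutoff=q_cutoff)
        counts.append(int(result["significant"].sum()) if len(result) else 0)
    return counts


def longitudinal_gene_tracking(
    panel: GenePanel,
    timepoint_tables: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Count tumor-concordant panel genes per cfDNA timepoint.

    A hypermethylated panel gene is concordant when its cfDNA mean is
    > 50%, a hypomethylated one when < 50%. Genes with a missing cfDNA
    mean at a timepoint are excluded from that timepoint's denominator.
    Returns one row per timepoint (timepoint, n_concordant, n_evaluated,
    concordant_fraction).
    """
    if len(panel) == 0:
        raise ValidationError("empty gene panel")
    rows = []
    for tp, table in timepoint_tables.items():
        means = table.set_index("gene_id")["mean_pct"]
        n_conc = n_eval = 0
        for gene_id in panel.hyper:
            v = means.get(gene_id)
            if v is None or pd.isna(v):
                continue
            n_eval += 1
            n_conc += int(v > 50)
        for gene_id in panel.hypo:
            v = means.get(gene_id)
            if v is None or pd.isna(v):
                continue
            n_eval += 1
            n_conc += int(v < 50)
        frac = n_conc / n_eval if n_eval else np.nan
        rows.append((tp, n_conc, n_eval, frac))
    return pd.DataFrame(
        rows,
        columns=["timepoint", "n_concordant", "n_evaluated", "concordant_fraction"],
    )
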