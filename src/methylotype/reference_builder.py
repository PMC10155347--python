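"""Build the informative-site table and differential gene panels.

The classifier needs a table of CpG sites where the tumor and immune
(PBMC) reference methylomes both have adequate coverage and carry
different methylation values. Longitudinal gene-level tracking needs
small panels of the most differentially methylated protein-coding genes
between tumor and blood, with the two tissues on opposite sides of 50%
methylation.

CpG sites are keyed strand-insensitively by default: a call on the minus
strand of a CpG dyad is collapsed to the plus-strand C coordinate
(position - 1) before intersection. Pass ``collapse_strands=False`` to
key on (chrom, pos, strand) instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methylome_io import GeneAnnotation, ReferenceMethylome, ValidationError

__all__ = [
    "GenePanel",
    "intersect_profiles",
    "select_informative_sites",
    "gene_level_methylation",
    "select_top_differential_genes",
    "SITES_TABLE_COLUMNS",
]

#: Columns of the informative-site table.
SITES_TABLE_COLUMNS = (
    "chrom",
    "pos",
    "pct_tumor",
    "pct_immune",
    "cov_tumor",
    "cov_immune",
)

#: Coverage must be strictly greater than four in both tissues, i.e. >= 5.
DEFAULT_MIN_COVERAGE = 5


@dataclass
class GenePanel:
    """Tumor-vs-blood differential gene panels.

    ``hyper`` lists tumor-hypermethylated gene_ids (tumor mean > 50,
    blood mean < 50), ``hypo`` the reverse; ``table`` carries per-gene
    (gene_id, pct_tumor_mean, pct_blood_mean, delta, direction) for every
    panel member, ranked by |delta| within each direction.
    """

    hyper: list[str] = field(default_factory=list)
    hypo: list[str] = field(default_factory=list)
    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=[
                "gene_id",
                "pct_tumor_mean",
                "pct_blood_mean",
                "delta",
                "direction",
            ]
        )
    )

    def __len__(self) -> int:
        return len(self.hyper) + len(self.hypo)


def _collapsed_sites(methylome: ReferenceMethylome, collapse: bool) -> pd.DataFrame:
    df = methylome.sites.copy()
    if collapse:
        # minus-strand CpG call sits on the G; shift to the dyad's C
        df["pos"] = np.where(df["strand"] == "-", df["start"] - 1, df["start"])
        if df.duplicated(subset=["chrom", "pos"]).any():
            # opposite-strand records of one dyad: merge by coverage-weighted
            # mean percent and summed coverage
            grp = df.groupby(["chrom", "pos"], as_index=False)
            merged = grp.apply(
                lambda g: pd.Series(
                    {
                        "coverage": g["coverage"].sum(),
                        "pct_meth": (
                            np.average(g["pct_meth"], weights=g["coverage"])
                            if g["coverage"].sum() > 0
                            else g["pct_meth"].mean()
                        ),
                    }
                ),
                include_groups=False,
            )
            df = merged.reset_index(drop=True)
        else:
            df = df[["chrom", "pos", "coverage", "pct_meth"]]
    else:
        df = df.rename(columns={"start": "pos"})
        df = df[["chrom", "pos", "strand", "coverage", "pct_meth"]]
    return df


def intersect_profiles(
    tumor: ReferenceMethylome,
    immune: ReferenceMethylome,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    collapse_strands: bool = True,
) -> pd.DataFrame:
    """Intersect tumor and immune methylomes on genomic coordinates.

    Keeps positions present in both methylomes with coverage
    >= ``min_coverage`` (default 5, i.e. strictly greater than four) in
    both. Percent values are carried through unchanged. Returns the
    informative-site table (chrom, pos, pct_tumor, pct_immune, cov_tumor,
    cov_immune), sorted and unique by (chrom, pos). An empty intersection
    warns but is not an error.
    """
    key = ["chrom", "pos"] if collapse_strands else ["chrom", "pos", "strand"]
    t = _collapsed_sites(tumor, collapse_strands)
    i = _collapsed_sites(immune, collapse_strands)
    merged = t.merge(i, on=key, suffixes=("_tumor", "_immune"))
    merged = merged.rename(
        columns={
            "coverage_tumor": "cov_tumor",
            "coverage_immune": "cov_immune",
            "pct_meth_tumor": "pct_tumor",
            "pct_meth_immune": "pct_immune",
        }
    )
    merged = merged[
        (merged["cov_tumor"] >= min_coverage)
        & (merged["cov_immune"] >= min_coverage)
    ]
    merged = merged[list(SITES_TABLE_COLUMNS)]
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )
    if len(merged) == 0:
        warnings.warn(
            "intersection of tumor and immune methylomes is empty",
            stacklevel=2,
        )
    return merged


def select_informative_sites(
    table: pd.DataFrame, min_abs_diff: float = 0.0
) -> pd.DataFrame:
    """Keep sites where tumor and immune methylation differ.

    With ``min_abs_diff = 0`` (default) any strictly nonzero difference
    qualifies; otherwise rows with |pct_tumor - pct_immune| >=
    ``min_abs_diff`` are retained.
    """
    if not 0.0 <= min_abs_diff <= 100.0:
        raise ValidationError("min_abs_diff outside [0, 100]")
    diff = (table["pct_tumor"] - table["pct_immune"]).abs()
    mask = diff > 0 if min_abs_diff == 0 else diff >= min_abs_diff
    return table[mask].reset_index(drop=True)


def gene_level_methylation(
    methylome: ReferenceMethylome,
    genes: list[GeneAnnotation],
    coverage_weighted: bool = False,
) -> pd.DataFrame:
    """Average methylation per gene over covered CpG sites.

    For each gene, the mean of ``pct_meth`` over CpG sites with coverage
    > 0 falling in [start, end). Genes may overlap; a site inside two
    genes contributes to both. Genes with zero covered sites get a
    missing (NaN) mean, distinguishing absence of data from
    hypomethylation. Default is the unweighted per-site mean; set
    ``coverage_weighted=True`` to weight sites by coverage.

    Returns a DataFrame (gene_id, gene_name, mean_pct, n_sites).
    """
    sites = methylome.sites[methylome.sites["coverage"] > 0]
    by_chrom = {c: g.sort_values("start") for c, g in sites.groupby("chrom")}
    records = []
    for gene in genes:
        grp = by_chrom.get(gene.chrom)
        if grp is None:
            records.append((gene.gene_id, gene.gene_name, np.nan, 0))
            continue
        pos = grp["start"].to_numpy()
        lo = np.searchsorted(pos, gene.start, side="left")
        hi = np.searchsorted(pos, gene.end, side="left")
        if hi <= lo:
            records.append((gene.gene_id, gene.gene_name, np.nan, 0))
            continue
        pct = grp["pct_meth"].to_numpy()[lo:hi]
        if coverage_weighted:
            cov = grp["coverage"].to_numpy()[lo:hi]
            mean = float(np.average(pct, weights=cov))
        else:
            mean = float(pct.mean())
        records.append((gene.gene_id, gene.gene_name, mean, hi - lo))
    return pd.DataFrame(
        records, columns=["gene_id", "gene_name", "mean_pct", "n_sites"]
    )


def select_top_differential_genes(
    tumor_table: pd.DataFrame,
    blood_table: pd.DataFrame,
    genes: list[GeneAnnotation] | None = None,
    k: int = 25,
    biotype_filter: str | None = "protein_coding",
) -> GenePanel:
    """Select the top-k differentially methylated genes per direction.

    Candidate genes must have the two tissues in opposing methylation
    states: hypermethylated panel requires tumor mean > 50 and blood mean
    < 50; hypomethylated panel the reverse. Within each direction genes
    are ranked by |tumor - blood| difference, descending, ties broken by
    gene_id. When ``genes`` is given and ``biotype_filter`` is set, only
    genes of that biotype are considered. Panels may hold fewer than
    ``k`` genes; an empty panel warns.
    """
    merged = tumor_table.merge(
        blood_table[["gene_id", "mean_pct"]],
        on="gene_id",
        suffixes=("_tumor", "_blood"),
    ).rename(
        columns={"mean_pct_tumor": "pct_tumor_mean", "mean_pct_blood": "pct_blood_mean"}
    )
    merged = merged.dropna(subset=["pct_tumor_mean", "pct_blood_mean"])
    if genes is not None and biotype_filter is not None:
        keep = {g.gene_id for g in genes if g.biotype == biotype_filter}
        merged = merged[merged["gene_id"].isin(keep)]
    merged = merged.assign(
        delta=merged["pct_tumor_mean"] - merged["pct_blood_mean"]
    )

    def _top(mask: pd.Series, direction: str) -> pd.DataFrame:
        cand = merged[mask].copy()
        cand["abs_delta"] = cand["delta"].abs()
        cand = cand.sort_values(
            ["abs_delta", "gene_id"], ascending=[False, True], kind="mergesort"
        ).head(k)
        cand["direction"] = direction
        return cand

    hyper = _top(
        (merged["pct_tumor_mean"] > 50) & (merged["pct_blood_mean"] < 50), "hyper"
    )
    hypo = _top(
        (merged["pct_tumor_mean"] < 50) & (merged["pct_blood_mean"] > 50), "hypo"
    )
    table = pd.concat([hyper, hypo], ignore_index=True)[
        ["gene_id", "pct_tumor_mean", "pct_blood_mean", "delta", "direction"]
    ]
    panel = GenePanel(
        hyper=hyper["gene_id"].tolist(), hypo=hypo["gene_id"].tolist(), table=table
    )
    if len(panel) == 0:
        warnings.warn("no genes qualify for the differential panel", stacklevel=2)
    return panel
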