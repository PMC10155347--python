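"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the objects the real pipeline consumes, so every
downstream stage is testable without any sequencing data:

* **Two-tissue reference methylomes** on a single synthetic contig
  (``chrS``): shared CpG positions, a U-shaped background methylation
  distribution (most CpGs near 0% or 100%, as in real genomes), and a
  controllable fraction of informative sites whose tumor/immune values
  differ by a set divergence.
* **Per-read call samples**: fragments whose lengths follow a
  nucleosome-ladder mixture (mono ~167 bp, di ~334 bp), placed uniformly
  on the contig; each covered CpG yields a Bernoulli(pct/100) binary
  call, mirroring the probabilistic model the read classifier scores
  against.
* **Cohort gene-methylation tables** with a planted set of differentially
  methylated genes, giving the t-test/FDR stage a known ground truth.

Every operation is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methylome_io import ReadMethylProfile, ReferenceMethylome, ValidationError

__all__ = [
    "MethylomeSimSpec",
    "ReadSimSpec",
    "simulate_reference_pair",
    "simulate_reads",
    "simulate_fragment_lengths",
    "simulate_cohort",
]

#: Default synthetic contig name.
SYNTHETIC_CONTIG = "chrS"

#: CpG spacing on the synthetic contig (bp). Real CpG density varies;
#: a fixed spacing keeps window CpG counts predictable.
CPG_SPACING = 40

#: Nucleosome-ladder fragment modes (bp): mono- and di-nucleosome.
MONO_MODE = 167
DI_MODE = 334


@dataclass(frozen=True)
class MethylomeSimSpec:
    """Parameters of a simulated tumor/immune reference-methylome pair.

    Attributes
    ----------
    n_sites : int
        Number of shared CpG positions.
    informative_fraction : float
        Fraction of positions where the two tissues differ.
    divergence : float
        Absolute percent-methylation difference at informative sites.
    background_alpha, background_beta : float
        Beta-distribution shape parameters (scaled to [0, 100]) for the
        shared background; defaults give the U-shape typical of genomic
        CpG methylation.
    mean_coverage : float
        Poisson mean of per-site coverage (a floor of 5 is applied so the
        default reference coverage filter keeps all simulated sites).
    seed : int
        PRNG seed.
    """

    n_sites: int
    informative_fraction: float = 0.5
    divergence: float = 80.0
    background_alpha: float = 0.25
    background_beta: float = 0.25
    mean_coverage: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValidationError("n_sites must be positive")
        if not 0.0 <= self.informative_fraction <= 1.0:
            raise ValidationError("informative_fraction outside [0, 1]")
        if not 0.0 <= self.divergence <= 100.0:
            raise ValidationError("divergence outside [0, 100]")


@dataclass(frozen=True)
class ReadSimSpec:
    """Parameters of a simulated read sample.

    ``mono_weight``/``di_weight`` are the mixture weights of the mono- and
    di-nucleosome fragment-length components (modes 167 and 334 bp); they
    must sum to 1. ``mean_cpg_per_read`` only documents the expectation
    implied by the fragment model and CpG spacing; CpG counts per read are
    determined by the window, not drawn separately.
    """

    n_reads: int
    mono_weight: float = 0.8
    di_weight: float = 0.2
    mono_sd: float = 10.0
    di_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValidationError("n_reads must be >= 0")
        if abs(self.mono_weight + self.di_weight - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")


def simulate_reference_pair(
    spec: MethylomeSimSpec,
) -> tuple[ReferenceMethylome, ReferenceMethylome, set[int]]:
    """Simulate a matched tumor/immune reference-methylome pair.

    Both methylomes share identical CpG coordinates on ``chrS``. At
    non-informative positions the two tissues carry the same background
    value drawn from a U-shaped Beta distribution; at the
    ``round(n_sites * informative_fraction)`` informative positions the
    tumor and immune values are separated by exactly ``divergence``
    percentage points, with random direction. Returns the two methylomes
    and the set of informative positions (the truth set).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    positions = np.arange(n, dtype=np.int64) * CPG_SPACING + CPG_SPACING

    background = 100.0 * rng.beta(
        spec.background_alpha, spec.background_beta, size=n
    )
    pct_tumor = background.copy()
    pct_immune = background.copy()

    n_inf = int(round(n * spec.informative_fraction))
    inf_idx = rng.choice(n, size=n_inf, replace=False)
    half = spec.divergence / 2.0
    centers = rng.uniform(half, 100.0 - half, size=n_inf) if half < 50.0 else (
        np.full(n_inf, 50.0)
    )
    direction = rng.random(n_inf) < 0.5
    hi = centers + half
    lo = centers - half
    pct_tumor[inf_idx] = np.where(direction, hi, lo)
    pct_immune[inf_idx] = np.where(direction, lo, hi)

    cov_t = np.maximum(rng.poisson(spec.mean_coverage, size=n), 5)
    cov_i = np.maximum(rng.poisson(spec.mean_coverage, size=n), 5)

    def _build(label: str, pct: np.ndarray, cov: np.ndarray) -> ReferenceMethylome:
        df = pd.DataFrame(
            {
                "chrom": SYNTHETIC_CONTIG,
                "start": positions,
                "strand": "+",
                "coverage": cov.astype(np.int64),
                "pct_meth": np.clip(pct, 0.0, 100.0),
            }
        )
        return ReferenceMethylome(label, df)

    truth = set(int(positions[i]) for i in inf_idx)
    return _build("tumor", pct_tumor, cov_t), _build("immune", pct_immune, cov_i), truth


def simulate_fragment_lengths(spec: ReadSimSpec) -> np.ndarray:
    """Draw fragment lengths from the nucleosome-ladder mixture.

    Lengths are normal draws around the mono (167 bp) / di (334 bp) modes,
    rounded to integer bp with a floor of 50 bp.
    """
    rng = np.random.default_rng(spec.seed)
    return _draw_lengths(rng, spec)


def _draw_lengths(rng: np.random.Generator, spec: ReadSimSpec) -> np.ndarray:
    is_di = rng.random(spec.n_reads) < spec.di_weight
    lengths = np.where(
        is_di,
        rng.normal(DI_MODE, spec.di_sd, size=spec.n_reads),
        rng.normal(MONO_MODE, spec.mono_sd, size=spec.n_reads),
    )
    return np.maximum(np.rint(lengths).astype(np.int64), 50)


def simulate_reads(
    source: ReferenceMethylome,
    spec: ReadSimSpec,
    read_id_prefix: str | None = None,
) -> tuple[list[ReadMethylProfile], pd.DataFrame]:
    """Simulate reads from a reference methylome.

    Each read covers a contiguous window placed uniformly on the contig;
    its length is a nucleosome-ladder draw. Every reference CpG inside the
    window yields a binary call drawn Bernoulli(pct/100). Windows with no
    CpG produce a read with empty calls (downstream scoring skips it).

    Returns the profiles and a truth table (read_id, origin) labelling
    every read with the source tissue.
    """
    if len(source) == 0:
        raise ValidationError("source methylome is empty")
    rng = np.random.default_rng(spec.seed)
    prefix = read_id_prefix or source.tissue_label
    sites = source.sites
    positions = sites["start"].to_numpy()
    pcts = sites["pct_meth"].to_numpy() / 100.0
    chrom = sites["chrom"].iloc[0]
    contig_len = int(positions.max()) + CPG_SPACING

    lengths = _draw_lengths(rng, spec)
    starts = rng.integers(0, max(contig_len - 50, 1), size=spec.n_reads)

    reads: list[ReadMethylProfile] = []
    for i in range(spec.n_reads):
        w_start = int(starts[i])
        w_end = min(w_start + int(lengths[i]), contig_len)
        lo = np.searchsorted(positions, w_start, side="left")
        hi = np.searchsorted(positions, w_end, side="left")
        calls = []
        for j in range(lo, hi):
            m = int(rng.random() < pcts[j])
            calls.append((int(positions[j]), m))
        reads.append(
            ReadMethylProfile(
                read_id=f"{prefix}_{i:06d}",
                chrom=chrom,
                aligned_start=w_start,
                aligned_end=w_end,
                calls=calls,
            )
        )
    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "origin": source.tissue_label,
        }
    )
    return reads, truth


def simulate_cohort(
    n_group_a: int,
    n_group_b: int,
    n_genes: int,
    n_affected_genes: int,
    effect_size: float,
    noise_sd: float,
    seed: int = 0,
    n_sites_per_gene: int = 20,
) -> tuple[pd.DataFrame, pd.Series, set[str]]:
    """Simulate per-sample gene-methylation tables with planted effects.

    Per-gene baseline means are uniform on [20, 80]; each sample's value
    is baseline + Gaussian noise, and in group ``b`` the
    ``n_affected_genes`` planted genes are additionally shifted by
    ``effect_size`` percentage points (sign alternating per gene). All
    values are clipped to [0, 100].

    Returns
    -------
    tables : DataFrame
        Long-form gene-methylation table with columns
        (sample, gene_id, mean_pct, n_sites).
    groups : Series
        Sample -> group label ('a' or 'b').
    truth : set of str
        The affected gene_ids.
    """
    if n_affected_genes > n_genes:
        raise ValidationError("n_affected_genes > n_genes")
    if n_group_a < 2 or n_group_b < 2:
        raise ValidationError("each group needs >= 2 samples")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"a{i:03d}" for i in range(n_group_a)] + [
        f"b{i:03d}" for i in range(n_group_b)
    ]
    labels = ["a"] * n_group_a + ["b"] * n_group_b

    baseline = rng.uniform(20.0, 80.0, size=n_genes)
    affected_idx = rng.choice(n_genes, size=n_affected_genes, replace=False)
    shift = np.zeros(n_genes)
    signs = np.where(np.arange(n_affected_genes) % 2 == 0, 1.0, -1.0)
    shift[affected_idx] = signs * effect_size

    records = []
    for s, lab in zip(samples, labels):
        vals = baseline + rng.normal(0.0, noise_sd, size=n_genes)
        if lab == "b":
            vals = vals + shift
        vals = np.clip(vals, 0.0, 100.0)
        for g, v in zip(genes, vals):
            records.append((s, g, v, n_sites_per_gene))
    tables = pd.DataFrame(
        records, columns=["sample", "gene_id", "mean_pct", "n_sites"]
    )
    groups = pd.Series(labels, index=samples, name="group")
    truth = {genes[i] for i in affected_idx}
    return tables, groups, truth
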