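"""Seeded in silico admixtures and tumor-fraction titration.

Mixtures of two labelled read pools emulate plasma samples with a known
tumor content: exactly ``round(total_reads * tumor_fraction)`` tumor
reads (round half up) and the complement of immune reads are sampled
without replacement, mirroring physical mixing of distinct molecules. A
sidecar truth table records each read's origin. ``titration_experiment``
runs a (fraction x depth x replicate) grid and reports the classifier's
estimated tumor fraction per cell; replicate seeds derive
deterministically from the base seed (base_seed + replicate index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import (
    DEFAULT_CANCER_THRESHOLD,
    DEFAULT_IMMUNE_THRESHOLD,
    ClassificationSummary,
    classify_sample,
)
from .methylome_io import ReadMethylProfile, ValidationError

__all__ = [
    "AdmixtureSpec",
    "mix_reads",
    "estimate_fraction",
    "titration_experiment",
]


@dataclass(frozen=True)
class AdmixtureSpec:
    """A mixture design: tumor fraction, total depth, and seed."""

    tumor_fraction: float
    total_reads: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValidationError("tumor_fraction outside [0, 1]")
        if self.total_reads < 0:
            raise ValidationError("total_reads must be >= 0")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def mix_reads(
    tumor_reads: list[ReadMethylProfile],
    immune_reads: list[ReadMethylProfile],
    spec: AdmixtureSpec,
) -> tuple[list[ReadMethylProfile], pd.DataFrame]:
    """Mix two read pools at a controlled fraction and depth.

    Samples ``round_half_up(total_reads * tumor_fraction)`` tumor reads
    and the complement of immune reads, each without replacement, with a
    seeded PRNG (identical seed -> identical mixture). Returns the
    shuffled mixture and a truth table (read_id, origin). Raises when a
    pool is too small, stating required vs available counts.
    """
    n_tumor = _round_half_up(spec.total_reads * spec.tumor_fraction)
    n_immune = spec.total_reads - n_tumor
    if n_tumor > len(tumor_reads):
        raise ValidationError(
            f"tumor pool too small: need {n_tumor}, have {len(tumor_reads)}"
        )
    if n_immune > len(immune_reads):
        raise ValidationError(
            f"immune pool too small: need {n_immune}, have {len(immune_reads)}"
        )
    rng = np.random.default_rng(spec.seed)
    t_idx = rng.choice(len(tumor_reads), size=n_tumor, replace=False)
    i_idx = rng.choice(len(immune_reads), size=n_immune, replace=False)
    mixed = [tumor_reads[i] for i in t_idx] + [immune_reads[i] for i in i_idx]
    origins = ["tumor"] * n_tumor + ["immune"] * n_immune
    order = rng.permutation(len(mixed))
    mixed = [mixed[i] for i in order]
    origins = [origins[i] for i in order]
    truth = pd.DataFrame(
        {"read_id": [r.read_id for r in mixed], "origin": origins}
    )
    return mixed, truth


def estimate_fraction(
    mixed: list[ReadMethylProfile],
    sites: pd.DataFrame,
    immune_threshold: float = DEFAULT_IMMUNE_THRESHOLD,
    cancer_threshold: float = DEFAULT_CANCER_THRESHOLD,
) -> ClassificationSummary:
    """Classify a mixture; the tumor read fraction estimates the mixing
    fraction. Delegates to :func:`classifier.classify_sample`."""
    _, summary = classify_sample(mixed, sites, immune_threshold, cancer_threshold)
    return summary


def titration_experiment(
    tumor_pool: list[ReadMethylProfile],
    immune_pool: list[ReadMethylProfile],
    sites: pd.DataFrame,
    fractions: list[float],
    depths: list[int],
    replicates: int = 5,
    base_seed: int = 0,
    immune_threshold: float = DEFAULT_IMMUNE_THRESHOLD,
    cancer_threshold: float = DEFAULT_CANCER_THRESHOLD,
) -> pd.DataFrame:
    """Titrate the estimator over a fraction x depth x replicate grid.

    Returns one row per cell: (true_fraction, total_reads, replicate,
    estimated_fraction, n_classified). ``estimated_fraction`` is missing
    when no read was confidently classified. Replicate r uses seed
    ``base_seed + r`` (documented, platform-stable derivation via numpy's
    PCG64), so the full grid is reproducible from ``base_seed``.
    """
    rows = []
    for frac in fractions:
        for depth in depths:
            for rep in range(replicates):
                seed = (base_seed + rep) % 2**31
                mixed, _ = mix_reads(
                    tumor_pool,
                    immune_pool,
                    AdmixtureSpec(frac, depth, seed=seed),
                )
                summary = estimate_fraction(
                    mixed, sites, immune_threshold, cancer_threshold
                )
                est = summary.tumor_read_fraction
                rows.append(
                    (
                        frac,
                        depth,
                        rep,
                        np.nan if est is None else est,
                        summary.n_tumor + summary.n_immune,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "true_fraction",
            "total_reads",
            "replicate",
            "estimated_fraction",
            "n_classified",
        ],
    )
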