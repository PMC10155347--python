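"""Read-level classification against tumor and immune reference profiles.

Each read *i* carrying binary CpG calls ``m_j`` is scored against a
tissue's reference methylation ``m'_j`` (percent, 0-100) over the
informative sites it covers:

    f_i^tissue = sum_j prob(m_j = m'_j) / N_sites,
    prob(m_j = m'_j) = m'_j if m_j = 1, else 100 - m'_j

i.e. ``f`` is the mean probability that the read's calls match the
tissue profile, on a 0-100 scale. Both tissue scores are computed over
the same informative-site table; reads covering no table site are
skipped. The normalized per-read tumor score is the ratio

    p_i = f_i^tumor / (f_i^tumor + f_i^immune)

(undefined when the denominator is zero; such reads are skipped). A dual
threshold calls a read immune when ``p < immune_threshold`` and tumor
when ``p > cancer_threshold`` (strict inequalities); reads in between
stay unclassified and drop out of the final tally. The tumor read
fraction — confidently tumor-called reads over all confidently called
reads — is the sample-level tumor-burden proxy.

``roc_sweep`` evaluates sensitivity/specificity over a grid of threshold
pairs against truth labels and integrates one ROC curve (trapezoidal)
per immune threshold, sweeping the cancer threshold, as well as the
fraction of reads that remain classified at each operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methylome_io import ReadMethylProfile, ValidationError

__all__ = [
    "ReadScore",
    "ClassificationSummary",
    "RocResult",
    "score_read",
    "normalize_score",
    "classify_read",
    "classify_sample",
    "roc_sweep",
    "DEFAULT_IMMUNE_THRESHOLD",
    "DEFAULT_CANCER_THRESHOLD",
]

#: Stringent dual thresholds: immune < 0.1, tumor > 0.9.
DEFAULT_IMMUNE_THRESHOLD = 0.1
DEFAULT_CANCER_THRESHOLD = 0.9

LABEL_TUMOR = "tumor"
LABEL_IMMUNE = "immune"
LABEL_UNCLASSIFIED = "unclassified"
LABEL_SKIPPED = "skipped"


@dataclass(frozen=True)
class ReadScore:
    """Per-read scores and classification.

    ``f_tumor``/``f_immune`` are mean match probabilities on a 0-100
    scale over the ``n_sites`` informative sites the read covers; ``p``
    is the normalized tumor score in [0, 1], or None when undefined
    (no scorable sites, or both f scores zero). ``label`` is one of
    tumor / immune / unclassified / skipped.
    """

    read_id: str
    f_tumor: float
    f_immune: float
    n_sites: int
    p: float | None
    label: str


@dataclass(frozen=True)
class ClassificationSummary:
    """Aggregate classification counts for one sample.

    ``tumor_read_fraction`` = n_tumor / (n_tumor + n_immune), or None if
    no read was confidently classified. Skipped reads (no scorable sites
    or undefined p) are excluded from n_scored.
    """

    n_total: int
    n_scored: int
    n_tumor: int
    n_immune: int
    n_unclassified: int

    def __post_init__(self) -> None:
        if self.n_scored != self.n_tumor + self.n_immune + self.n_unclassified:
            raise ValidationError("inconsistent classification counts")

    @property
    def n_skipped(self) -> int:
        return self.n_total - self.n_scored

    @property
    def tumor_read_fraction(self) -> float | None:
        called = self.n_tumor + self.n_immune
        return self.n_tumor / called if called else None


@dataclass
class RocResult:
    """Threshold-sweep operating points and per-curve AUCs.

    ``grid`` has one row per (immune_threshold, cancer_threshold) with
    sensitivity, specificity and fraction_classified; ``auc`` maps each
    immune threshold to the trapezoidal AUC of its cancer-threshold
    sweep. ``auc_stringent`` is the headline scalar at the lowest immune
    threshold in the grid.
    """

    grid: pd.DataFrame
    auc: dict[float, float] = field(default_factory=dict)

    @property
    def auc_stringent(self) -> float:
        return self.auc[min(self.auc)]


def score_read(
    read: ReadMethylProfile,
    reference: dict[tuple[str, int], float],
) -> tuple[float | None, int]:
    """Score one read against a single-tissue reference.

    ``reference`` maps (chrom, pos) to the tissue's percent methylation.
    Each call at a reference site contributes ``m'`` when methylated and
    ``100 - m'`` when not; ``f`` is the mean over contributing sites.
    Returns ``(f, n_sites)``; ``(None, 0)`` when no call position is in
    the reference (the read is skipped, not an error).
    """
    total = 0.0
    n = 0
    chrom = read.chrom
    for pos, m in read.calls:
        mp = reference.get((chrom, pos))
        if mp is None:
            continue
        total += mp if m == 1 else 100.0 - mp
        n += 1
    if n == 0:
        return None, 0
    return total / n, n


def normalize_score(f_tumor: float, f_immune: float) -> float | None:
    """Normalized tumor score p = f_tumor / (f_tumor + f_immune).

    Returns None when the denominator is zero (read excluded downstream).
    """
    denom = f_tumor + f_immune
    if denom == 0:
        return None
    return f_tumor / denom


def classify_read(
    p: float,
    immune_threshold: float = DEFAULT_IMMUNE_THRESHOLD,
    cancer_threshold: float = DEFAULT_CANCER_THRESHOLD,
) -> str:
    """Dual-threshold call: immune if p < immune_threshold, tumor if
    p > cancer_threshold, else unclassified (strict inequalities)."""
    if immune_threshold > cancer_threshold:
        raise ValidationError(
            f"immune_threshold {immune_threshold} > cancer_threshold "
            f"{cancer_threshold}"
        )
    if p < immune_threshold:
        return LABEL_IMMUNE
    if p > cancer_threshold:
        return LABEL_TUMOR
    return LABEL_UNCLASSIFIED


def _reference_maps(
    sites: pd.DataFrame,
) -> tuple[dict[tuple[str, int], float], dict[tuple[str, int], float]]:
    keys = list(zip(sites["chrom"], sites["pos"].astype(int)))
    tumor = dict(zip(keys, sites["pct_tumor"].astype(float)))
    immune = dict(zip(keys, sites["pct_immune"].astype(float)))
    return tumor, immune


def classify_sample(
    reads: list[ReadMethylProfile],
    sites: pd.DataFrame,
    immune_threshold: float = DEFAULT_IMMUNE_THRESHOLD,
    cancer_threshold: float = DEFAULT_CANCER_THRESHOLD,
) -> tuple[list[ReadScore], ClassificationSummary]:
    """Score, normalize and classify every read of a sample.

    ``sites`` is the informative-site table (chrom, pos, pct_tumor,
    pct_immune, ...). Reads with no scorable site or undefined p are
    marked skipped and excluded from the summary's scored counts.
    """
    if len(sites) == 0:
        raise ValidationError("informative-site table is empty")
    if immune_threshold > cancer_threshold:
        raise ValidationError("thresholds out of order")
    ref_tumor, ref_immune = _reference_maps(sites)
    scores: list[ReadScore] = []
    n_tumor = n_immune = n_unclassified = 0
    for read in reads:
        f_t, n_t = score_read(read, ref_tumor)
        f_i, _ = score_read(read, ref_immune)
        if f_t is None:
            scores.append(ReadScore(read.read_id, 0.0, 0.0, 0, None, LABEL_SKIPPED))
            continue
        p = normalize_score(f_t, f_i)
        if p is None:
            scores.append(
                ReadScore(read.read_id, f_t, f_i, n_t, None, LABEL_SKIPPED)
            )
            continue
        label = classify_read(p, immune_threshold, cancer_threshold)
        if label == LABEL_TUMOR:
            n_tumor += 1
        elif label == LABEL_IMMUNE:
            n_immune += 1
        else:
            n_unclassified += 1
        scores.append(ReadScore(read.read_id, f_t, f_i, n_t, p, label))
    summary = ClassificationSummary(
        n_total=len(reads),
        n_scored=n_tumor + n_immune + n_unclassified,
        n_tumor=n_tumor,
        n_immune=n_immune,
        n_unclassified=n_unclassified,
    )
    return scores, summary


def scores_to_frame(scores: list[ReadScore]) -> pd.DataFrame:
    """Tabulate ReadScores (read_id, f_tumor, f_immune, n_sites, p, label)."""
    return pd.DataFrame(
        {
            "read_id": [s.read_id for s in scores],
            "f_tumor": [s.f_tumor for s in scores],
            "f_immune": [s.f_immune for s in scores],
            "n_sites": [s.n_sites for s in scores],
            "p": [s.p for s in scores],
            "label": [s.label for s in scores],
        }
    )


def roc_sweep(
    scores: list[ReadScore],
    truth: pd.DataFrame,
    immune_grid: np.ndarray | list[float] | None = None,
    cancer_grid: np.ndarray | list[float] | None = None,
    classified_only: bool = True,
) -> RocResult:
    """Sweep the dual thresholds against truth labels.

    ``truth`` maps read_id to origin ('tumor' or 'immune'). Per grid
    point, sensitivity = tumor reads called tumor / tumor reads
    classified, specificity = immune reads called immune / immune reads
    classified, plus the fraction of scored reads that remain classified.
    With ``classified_only=False`` the denominators are all truth reads
    (unclassified counted against both rates). One ROC curve is formed
    per immune threshold by sweeping the cancer threshold; its AUC is the
    trapezoidal integral over (1 - specificity, sensitivity) with (0,0)
    and (1,1) anchors.
    """
    if immune_grid is None:
        immune_grid = [0.1, 0.25, 0.5]
    if cancer_grid is None:
        cancer_grid = np.round(np.arange(0.5, 1.0, 0.02), 10)
    origin = dict(zip(truth["read_id"], truth["origin"]))
    ps, labels_true = [], []
    for s in scores:
        if s.p is None:
            continue
        if s.read_id not in origin:
            raise ValidationError(f"read {s.read_id} has no truth label")
        ps.append(s.p)
        labels_true.append(origin[s.read_id])
    p_arr = np.asarray(ps, dtype=float)
    is_tumor = np.asarray([t == LABEL_TUMOR for t in labels_true])
    n_reads = len(p_arr)

    rows = []
    aucs: dict[float, float] = {}
    for it in immune_grid:
        curve = []
        for ct in cancer_grid:
            if it > ct:
                continue
            called_t = p_arr > ct
            called_i = p_arr < it
            classified = called_t | called_i
            tumor_called_t = int((called_t & is_tumor).sum())
            immune_called_i = int((called_i & ~is_tumor).sum())
            if classified_only:
                sens_den = int((classified & is_tumor).sum())
                spec_den = int((classified & ~is_tumor).sum())
            else:
                sens_den = int(is_tumor.sum())
                spec_den = int((~is_tumor).sum())
            sens = tumor_called_t / sens_den if sens_den else np.nan
            spec = immune_called_i / spec_den if spec_den else np.nan
            frac = float(classified.sum() / n_reads) if n_reads else np.nan
            rows.append((it, ct, sens, spec, frac))
            if not (np.isnan(sens) or np.isnan(spec)):
                curve.append((1.0 - spec, sens))
        aucs[float(it)] = _trapezoid_auc(curve)
    grid = pd.DataFrame(
        rows,
        columns=[
            "immune_threshold",
            "cancer_threshold",
            "sensitivity",
            "specificity",
            "fraction_classified",
        ],
    )
    return RocResult(grid=grid, auc=aucs)


def _trapezoid_auc(points: list[tuple[float, float]]) -> float:
    """Trapezoidal AUC over (FPR, TPR) points, anchored at (0,0), (1,1)."""
    pts = sorted(set(points) | {(0.0, 0.0), (1.0, 1.0)})
    xs = np.array([x for x, _ in pts])
    ys = np.array([y for _, y in pts])
    return float(np.trapezoid(ys, xs))
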