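"""Readers and writers for the formats the pipeline touches.

Three file families flow through the pipeline:

* **BedMethyl** (BED9+2) — per-CpG-site coverage and percent methylation,
  the standard output of nanopore modified-base callers. Column 10 is read
  coverage, column 11 percent methylation.
* **Per-read calls TSV** — the flat intermediate with one row per
  (read, CpG site): read_id, chrom, position, call. Calls may be binary
  {0,1} or modification probabilities in [0,1]; probabilities are
  binarized at a configurable threshold (default 0.5).
* **GTF/GFF3** (GENCODE dialect) — gene annotations used for gene-level
  methylation aggregation.

All coordinates are 0-based half-open internally. BED-family inputs are
native; GTF's 1-based closed intervals are converted on read
(start - 1, end unchanged). An optional adapter extracts per-read calls
directly from modified-base (MM/ML tag) alignments via pysam, emitting the
same TSV schema — the TSV remains the canonical interchange.
"""

from __future__ import annotations

import io
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "MethylSite",
    "ReferenceMethylome",
    "ReadMethylProfile",
    "GeneAnnotation",
    "read_bedmethyl",
    "write_bedmethyl",
    "read_per_read_calls",
    "write_per_read_calls",
    "binarize_call",
    "read_gene_annotations",
    "bam_to_calls",
]

#: Default per-read modification-probability cutoff for calling a site
#: methylated. Callers emit probabilities; >= this value maps to 1.
DEFAULT_BINARIZE_THRESHOLD = 0.5

#: Columns of the canonical per-read calls table.
CALLS_COLUMNS = ("read_id", "chrom", "position", "call")

#: Columns of a reference methylome site table.
SITE_COLUMNS = ("chrom", "start", "strand", "coverage", "pct_meth")


class MethylotypeError(Exception):
    """Base class for pipeline errors."""


class ParseError(MethylotypeError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(MethylotypeError):
    """A value violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethylSite:
    """One CpG site of a reference methylome.

    Attributes
    ----------
    chrom : str
        Chromosome name.
    start : int
        0-based position of the site (bp).
    strand : str
        ``+``, ``-`` or ``.``.
    coverage : int
        Number of reads covering the site (>= 0).
    pct_meth : float
        Percent methylation in [0, 100].
    """

    chrom: str
    start: int
    strand: str
    coverage: int
    pct_meth: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative position {self.start}")
        if self.coverage < 0:
            raise ValidationError(f"negative coverage {self.coverage}")
        if not 0.0 <= self.pct_meth <= 100.0:
            raise ValidationError(
                f"percent methylation {self.pct_meth} outside [0, 100]"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")


@dataclass
class ReferenceMethylome:
    """Per-CpG-site methylation profile of one tissue.

    ``sites`` is a DataFrame with columns (chrom, start, strand, coverage,
    pct_meth), unique on (chrom, start, strand) and sorted by (chrom, start).
    """

    tissue_label: str
    sites: pd.DataFrame = field(default_factory=lambda: _empty_sites())

    def __post_init__(self) -> None:
        df = self.sites
        missing = set(SITE_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"site table missing columns {sorted(missing)}")
        if len(df):
            if df["pct_meth"].min() < 0 or df["pct_meth"].max() > 100:
                raise ValidationError("percent methylation outside [0, 100]")
            if df["coverage"].min() < 0:
                raise ValidationError("negative coverage")
            key = df[["chrom", "start", "strand"]]
            if key.duplicated().any():
                dup = key[key.duplicated()].iloc[0]
                raise ValidationError(
                    f"duplicate site {dup.chrom}:{dup.start}:{dup.strand}"
                )
        self.sites = (
            df[list(SITE_COLUMNS)]
            .sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.sites)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceMethylome):
            return NotImplemented
        return self.tissue_label == other.tissue_label and self.sites.equals(
            other.sites
        )

    def iter_sites(self) -> Iterator[MethylSite]:
        for row in self.sites.itertuples(index=False):
            yield MethylSite(row.chrom, row.start, row.strand, row.coverage,
                             row.pct_meth)


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "coverage": pd.Series(dtype=np.int64),
            "pct_meth": pd.Series(dtype=float),
        }
    )


@dataclass
class ReadMethylProfile:
    """Binary methylation calls of one sequenced molecule.

    ``calls`` is a list of ``(position, m)`` with positions strictly
    increasing inside ``[aligned_start, aligned_end)`` and ``m`` in {0, 1}.
    """

    read_id: str
    chrom: str
    aligned_start: int
    aligned_end: int
    calls: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.aligned_start > self.aligned_end:
            raise ValidationError(
                f"read {self.read_id}: aligned_start > aligned_end"
            )
        prev = None
        for pos, m in self.calls:
            if m not in (0, 1):
                raise ValidationError(
                    f"read {self.read_id}: call {m} at {pos} not binary"
                )
            if not self.aligned_start <= pos < self.aligned_end:
                raise ValidationError(
                    f"read {self.read_id}: call position {pos} outside "
                    f"[{self.aligned_start}, {self.aligned_end})"
                )
            if prev is not None and pos <= prev:
                raise ValidationError(
                    f"read {self.read_id}: positions not strictly increasing "
                    f"at {pos}"
                )
            prev = pos

    @property
    def n_calls(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene record from a GENCODE-style annotation.

    Coordinates are 0-based half-open after conversion from GTF.
    """

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand {self.strand!r} not in {{+,-}}"
            )


# ---------------------------------------------------------------------------
# BedMethyl
# ---------------------------------------------------------------------------


def read_bedmethyl(path: str | Path, tissue_label: str) -> ReferenceMethylome:
    """Read a BedMethyl (BED9+2) file into a :class:`ReferenceMethylome`.

    Lines must carry at least 11 whitespace-separated columns; column 10
    (1-based) is coverage and column 11 percent methylation. Malformed
    lines raise :class:`ParseError` naming the line number; percent values
    outside [0, 100] raise :class:`ValidationError`.
    """
    chroms: list[str] = []
    starts: list[int] = []
    strands: list[str] = []
    covs: list[int] = []
    pcts: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 11:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 11 BedMethyl columns, "
                    f"got {len(fields)}"
                )
            try:
                start = int(fields[1])
                cov = int(fields[9])
                pct = float(fields[10])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if not 0.0 <= pct <= 100.0:
                raise ValidationError(
                    f"{path}: line {lineno}: percent methylation {pct} "
                    f"outside [0, 100]"
                )
            chroms.append(fields[0])
            starts.append(start)
            strands.append(fields[5])
            covs.append(cov)
            pcts.append(pct)
    if not chroms:
        return ReferenceMethylome(tissue_label, _empty_sites())
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.asarray(starts, dtype=np.int64),
            "strand": strands,
            "coverage": np.asarray(covs, dtype=np.int64),
            "pct_meth": np.asarray(pcts, dtype=float),
        }
    )
    return ReferenceMethylome(tissue_label, df)


def write_bedmethyl(methylome: ReferenceMethylome, path: str | Path) -> Path:
    """Write a methylome back to BedMethyl; round-trips losslessly.

    Percent methylation is printed with ``repr`` precision so that
    ``read_bedmethyl(write_bedmethyl(x)) == x`` for the five carried
    fields (chrom, start, strand, coverage, pct_meth).
    """
    path = Path(path)
    with open(path, "w") as fh:
        for row in methylome.sites.itertuples(index=False):
            end = row.start + 1
            # shortest round-trip float representation keeps the trip lossless
            pct_str = str(float(row.pct_meth))
            if pct_str.endswith(".0"):
                pct_str = pct_str[:-2]
            fh.write(
                f"{row.chrom}\t{row.start}\t{end}\t.\t{row.coverage}\t"
                f"{row.strand}\t{row.start}\t{end}\t0,0,0\t{row.coverage}\t"
                f"{pct_str}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Per-read calls
# ---------------------------------------------------------------------------


def binarize_call(p: float, threshold: float = DEFAULT_BINARIZE_THRESHOLD) -> int:
    """Binarize a modification probability: 1 iff ``p >= threshold``."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"call probability {p} outside [0, 1]")
    return 1 if p >= threshold else 0


def read_per_read_calls(
    path: str | Path,
    threshold: float = DEFAULT_BINARIZE_THRESHOLD,
) -> list[ReadMethylProfile]:
    """Read the per-read calls TSV into :class:`ReadMethylProfile` objects.

    The TSV must have columns read_id, chrom, position, call. The call
    column may hold binary values or probabilities in [0, 1]; probabilities
    are binarized at ``threshold``. Rows are grouped by read_id; a
    duplicated (read_id, position) pair raises :class:`ValidationError`.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"read_id": str, "chrom": str},
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    missing = set(CALLS_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        return []
    if not pd.api.types.is_numeric_dtype(df["position"]):
        bad = df.loc[
            pd.to_numeric(df["position"], errors="coerce").isna(), "position"
        ]
        raise ParseError(
            f"{path}: non-numeric position value {bad.iloc[0]!r}"
        )
    dup = df.duplicated(subset=["read_id", "position"], keep=False)
    if dup.any():
        r = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate call for read {r.read_id} at position "
            f"{r.position}"
        )
    calls = df["call"].astype(float)
    if (calls < 0).any() or (calls > 1).any():
        bad = calls[(calls < 0) | (calls > 1)].iloc[0]
        raise ValidationError(f"{path}: call value {bad} outside [0, 1]")
    df = df.assign(m=[binarize_call(p, threshold) for p in calls])
    df = df.sort_values(["read_id", "position"], kind="mergesort")
    profiles: list[ReadMethylProfile] = []
    for read_id, grp in df.groupby("read_id", sort=False):
        positions = grp["position"].astype(int).tolist()
        ms = grp["m"].tolist()
        chrom = grp["chrom"].iloc[0]
        profiles.append(
            ReadMethylProfile(
                read_id=str(read_id),
                chrom=chrom,
                aligned_start=positions[0],
                aligned_end=positions[-1] + 1,
                calls=list(zip(positions, ms)),
            )
        )
    return profiles


def write_per_read_calls(
    reads: Iterable[ReadMethylProfile], path: str | Path
) -> Path:
    """Write profiles to the canonical per-read calls TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for read in reads:
            for pos, m in read.calls:
                fh.write(f"{read.read_id}\t{read.chrom}\t{pos}\t{m}\n")
    return path


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------


def read_gene_annotations(
    path: str | Path, feature: str = "gene"
) -> list[GeneAnnotation]:
    """Read gene records from a GTF/GFF3 file.

    Only records whose feature type equals ``feature`` are kept. GTF
    1-based closed coordinates are converted to 0-based half-open
    (start - 1, end unchanged). Duplicate gene_ids raise
    :class:`ValidationError`; a record without gene_id raises
    :class:`ParseError`.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if feat.featuretype != feature:
                continue
            attrs = feat.attributes
            if "gene_id" not in attrs:
                raise ParseError(
                    f"{path}: line {lineno}: missing gene_id attribute"
                )
            gene_id = attrs["gene_id"][0]
            if gene_id in seen:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate gene_id {gene_id}"
                )
            seen.add(gene_id)
            gene_name = attrs.get("gene_name", [gene_id])[0]
            biotype = attrs.get(
                "gene_type", attrs.get("gene_biotype", ["unknown"])
            )[0]
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    gene_name=gene_name,
                    chrom=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                    biotype=biotype,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# Modified-base BAM adapter
# ---------------------------------------------------------------------------


def bam_to_calls(
    path: str | Path,
    threshold: float = DEFAULT_BINARIZE_THRESHOLD,
    mod: tuple = ("C", 0, "m"),
) -> list[ReadMethylProfile]:
    """Extract per-read 5mC calls from a modified-base SAM/BAM.

    Optional adapter around pysam's MM/ML tag decoding: each aligned read
    yields one profile with calls at the reference positions of its
    modified bases, binarized at ``threshold`` (ML qualities are scaled
    probabilities in [0, 1)). The per-read TSV written by
    :func:`write_per_read_calls` remains the canonical interchange.
    """
    import pysam

    profiles: list[ReadMethylProfile] = []
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            mods = aln.modified_bases
            if not mods or mod not in mods:
                continue
            qry_to_ref = dict(
                (q, r) for q, r in aln.get_aligned_pairs(matches_only=True)
            )
            calls: dict[int, int] = {}
            for qpos, qual in mods[mod]:
                rpos = qry_to_ref.get(qpos)
                if rpos is None:
                    continue
                p = (qual + 0.5) / 256.0
                calls[rpos] = binarize_call(p, threshold)
            if not calls:
                continue
            positions = sorted(calls)
            profiles.append(
                ReadMethylProfile(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    aligned_start=aln.reference_start,
                    aligned_end=aln.reference_end,
                    calls=[(pos, calls[pos]) for pos in positions],
                )
            )
    return profiles
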