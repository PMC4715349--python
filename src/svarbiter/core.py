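"""Domain types and coordinate conventions shared by every stage.

All coordinates are 0-based half-open (BED convention) internally.  File
readers convert from their source dialect at the boundary and writers emit
the source dialect back (see :mod:`svarbiter.io`).

The evaluation geometry around a candidate SV follows the five-window
scheme: a left flank ``L``, a left-inner window ``LM``, the SV interval
itself ``M``, a right-inner window ``RM`` and a right flank ``R``.  Read
evidence is summarised separately per window because different signals
concentrate in different windows (depth drops inside ``M``; clipping,
insert-size stretch and discordance concentrate in the flanks).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "SVType",
    "Zygosity",
    "Technology",
    "SVCall",
    "RegionPartition",
    "DatasetSpec",
    "AnnotationTable",
    "REGION_NAMES",
    "partition_site",
    "interval_overlap",
]

REGION_NAMES = ("L", "LM", "M", "RM", "R")

#: Long-read per-base deletion/insertion rates measured on random regions of
#: a PacBio dataset; used as the default normalisation baseline when no
#: training regions are supplied to recompute it.
DEFAULT_LONGREAD_BASELINE = (0.0428, 0.0948)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named contig.

    Zero-length intervals (``end == start``) are permitted so that flank
    windows truncated away entirely at a contig edge stay representable.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end < self.start:
            raise ValueError(f"end < start in {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def is_empty(self) -> bool:
        return self.end == self.start

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}"


class SVType(str, enum.Enum):
    DELETION = "deletion"
    INSERTION = "insertion"
    RANDOM = "random"
    REPEAT_ELEMENT = "repeat_element"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"
    UNKNOWN = "unknown"


class Technology(str, enum.Enum):
    PAIRED_SHORT = "paired_short"
    UNPAIRED_LONG = "unpaired_long"


@dataclass(frozen=True)
class SVCall:
    """One candidate site: an interval, its SV type and provenance.

    For insertions the interval is the reported replaced-reference span,
    and ``alt_sequence`` optionally carries the inserted bases.
    """

    interval: GenomicInterval
    sv_type: SVType = SVType.DELETION
    alt_sequence: str | None = None
    source: str = ""
    zygosity: Zygosity | None = None

    def __post_init__(self) -> None:
        if self.interval.length < 1:
            raise ValueError(f"SV interval must have length >= 1: {self.interval}")
        if self.alt_sequence is not None and self.sv_type is not SVType.INSERTION:
            raise ValueError("alt_sequence is only meaningful for insertions")

    @property
    def site_id(self) -> str:
        return f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"


@dataclass(frozen=True)
class RegionPartition:
    """The five evaluation windows derived from one candidate site."""

    L: GenomicInterval
    LM: GenomicInterval
    M: GenomicInterval
    RM: GenomicInterval
    R: GenomicInterval
    flank_size: int
    truncated_left: bool = False
    truncated_right: bool = False

    def __getitem__(self, name: str) -> GenomicInterval:
        if name not in REGION_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def items(self) -> Iterable[tuple[str, GenomicInterval]]:
        for name in REGION_NAMES:
            yield name, getattr(self, name)


@dataclass
class DatasetSpec:
    """One aligned-read dataset and its technology class.

    ``long_read_indel_baseline`` is the (mean deleted, mean inserted) bases
    per base of read subtracted from long-read indel rates so that random
    regions centre near zero; it defaults to rates measured on a PacBio
    dataset and is recomputed from training random regions when available.
    """

    name: str
    technology: Technology
    bam_path: str
    mean_coverage: float | None = None
    long_read_indel_baseline: tuple[float, float] | None = None
    discordant_insert_cutoff: float | None = None

    def __post_init__(self) -> None:
        self.technology = Technology(self.technology)
        if self.technology is Technology.UNPAIRED_LONG and self.long_read_indel_baseline is None:
            self.long_read_indel_baseline = DEFAULT_LONGREAD_BASELINE
        if self.technology is Technology.PAIRED_SHORT:
            self.long_read_indel_baseline = None

    @property
    def is_paired(self) -> bool:
        return self.technology is Technology.PAIRED_SHORT


class AnnotationTable:
    """Sites x named-annotations matrix with an explicit missing-value mask.

    Values are stored in a :class:`pandas.DataFrame` (rows = site ids,
    columns = annotation names such as ``M_Cov``); ``mask`` is a boolean
    frame of identical shape, True where the value is missing (e.g. insert
    statistics over a window with no usable pairs).  Masked cells hold NaN
    until a transform imputes them.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        mask: pd.DataFrame | None = None,
        row_flags: Mapping[str, tuple[str, ...]] | None = None,
    ) -> None:
        if values.columns.duplicated().any():
            dupes = values.columns[values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate annotation names: {dupes}")
        if values.index.duplicated().any():
            raise ValueError("duplicate site ids")
        values = values.astype(float)
        if mask is None:
            mask = values.isna()
        else:
            mask = mask.astype(bool)
            if not mask.index.equals(values.index) or not mask.columns.equals(values.columns):
                raise ValueError("mask shape/labels do not match values")
        if not np.isfinite(values.to_numpy()[~mask.to_numpy()]).all():
            raise ValueError("non-finite value in unmasked cell")
        self.values = values
        self.mask = mask
        self.row_flags: dict[str, tuple[str, ...]] = dict(row_flags or {})

    # -- basic protocol ---------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def annotation_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, columns: Sequence[str]) -> "AnnotationTable":
        missing = [c for c in columns if c not in self.values.columns]
        if missing:
            raise KeyError(f"annotations not in table: {missing}")
        return AnnotationTable(
            self.values[list(columns)].copy(),
            self.mask[list(columns)].copy(),
            self.row_flags,
        )

    def filled(self, fill: float = np.nan) -> pd.DataFrame:
        """Values with masked cells replaced by ``fill``."""
        out = self.values.copy()
        out.values[self.mask.to_numpy()] = fill
        return out

    def equals(self, other: "AnnotationTable", rtol: float = 1e-9) -> bool:
        if self.annotation_names != other.annotation_names:
            return False
        if self.site_ids != other.site_ids:
            return False
        if not (self.mask.to_numpy() == other.mask.to_numpy()).all():
            return False
        a = self.values.to_numpy()
        b = other.values.to_numpy()
        keep = ~self.mask.to_numpy()
        return bool(np.allclose(a[keep], b[keep], rtol=rtol, atol=0.0, equal_nan=False))

    @staticmethod
    def from_dataframe(df: pd.DataFrame) -> "AnnotationTable":
        return AnnotationTable(df.copy())

    @staticmethod
    def concat_columns(tables: Mapping[str, "AnnotationTable"]) -> "AnnotationTable":
        """Join per-dataset tables column-wise, prefixing columns by dataset.

        Only sites present in every table are kept (a site missing a dataset
        cannot be scored by a combined model).
        """
        frames = []
        masks = []
        common: pd.Index | None = None
        for name, t in tables.items():
            if common is None:
                common = t.values.index
            else:
                common = common.intersection(t.values.index)
        assert common is not None
        for name, t in tables.items():
            v = t.values.loc[common].add_prefix(f"{name}__")
            m = t.mask.loc[common].add_prefix(f"{name}__")
            frames.append(v)
            masks.append(m)
        return AnnotationTable(pd.concat(frames, axis=1), pd.concat(masks, axis=1))


def interval_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two half-open intervals; 0 across contigs."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def partition_site(sv: SVCall, flank_size: int, contig_length: int) -> RegionPartition:
    """Split the neighbourhood of ``sv`` into the L/LM/M/RM/R windows.

    Flanks have length ``flank_size`` unless truncated at a contig edge;
    the inner windows LM/RM are capped at half the SV length so they never
    overlap each other.
    """
    if flank_size < 1:
        raise ValueError("flank_size must be >= 1")
    iv = sv.interval
    if iv.start < 0 or iv.end > contig_length:
        raise ValueError(
            f"site {sv.site_id} does not fit contig of length {contig_length}"
        )
    chrom = iv.chrom
    l_start = max(0, iv.start - flank_size)
    r_end = min(contig_length, iv.end + flank_size)
    truncated_left = l_start > iv.start - flank_size
    truncated_right = r_end < iv.end + flank_size
    inner = min(flank_size, iv.length // 2)
    return RegionPartition(
        L=GenomicInterval(chrom, l_start, iv.start),
        LM=GenomicInterval(chrom, iv.start, iv.start + inner),
        M=GenomicInterval(chrom, iv.start, iv.end),
        RM=GenomicInterval(chrom, iv.end - inner, iv.end),
        R=GenomicInterval(chrom, iv.end, r_end),
        flank_size=flank_size,
        truncated_left=truncated_left,
        truncated_right=truncated_right,
    )
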