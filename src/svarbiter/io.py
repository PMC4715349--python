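"""Readers and writers for the external formats the pipeline touches.

Strict about coordinates, lenient about extra columns: malformed records
are skipped, counted and reported with line numbers rather than aborting a
whole file.  BAM access is delegated to pysam, FASTA to pyfaidx, VCF to
pysam.VariantFile; the two BED-like candidate dialects and the
RepeatMasker-style TSV are parsed here because per-line error accounting is
part of the contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .core import AnnotationTable, GenomicInterval, SVCall, SVType, Zygosity

__all__ = [
    "RepeatTrack",
    "SnpGenotypeSet",
    "SVCallReadResult",
    "read_sv_calls",
    "read_repeat_track",
    "read_snp_genotypes",
    "write_annotation_table",
    "read_annotation_table",
    "write_classified_calls",
]

logger = logging.getLogger(__name__)

REPEAT_CLASSES = ("SINE", "LINE", "LTR", "low_complexity", "simple_repeat", "other")

_REPEAT_CLASS_MAP = {
    "SINE": "SINE",
    "LINE": "LINE",
    "LTR": "LTR",
    "LOW_COMPLEXITY": "low_complexity",
    "SIMPLE_REPEAT": "simple_repeat",
}


class RepeatTrack:
    """RepeatMasker-style repeat intervals with overlap queries by class."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.n_records = 0

    def add(self, interval: GenomicInterval, repeat_class: str) -> None:
        if repeat_class not in REPEAT_CLASSES:
            repeat_class = "other"
        if interval.is_empty():
            return
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        tree.addi(interval.start, interval.end, repeat_class)
        self.n_records += 1

    def query(self, interval: GenomicInterval) -> list[tuple[GenomicInterval, str]]:
        tree = self._trees.get(interval.chrom)
        if tree is None or interval.is_empty():
            return []
        hits = []
        for iv in sorted(tree.overlap(interval.start, interval.end)):
            hits.append((GenomicInterval(interval.chrom, iv.begin, iv.end), iv.data))
        return hits

    def coverage_fraction(self, interval: GenomicInterval) -> dict[str, float]:
        """Fraction of ``interval`` covered by each repeat class (union)."""
        out = {cls: 0.0 for cls in REPEAT_CLASSES}
        if interval.is_empty():
            return out
        by_class: dict[str, list[tuple[int, int]]] = {}
        for iv, cls in self.query(interval):
            s = max(iv.start, interval.start)
            e = min(iv.end, interval.end)
            if e > s:
                by_class.setdefault(cls, []).append((s, e))
        for cls, spans in by_class.items():
            spans.sort()
            covered = 0
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s > cur_e:
                    covered += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            covered += cur_e - cur_s
            out[cls] = covered / interval.length
        return out

    def elements(self, repeat_class: str | None = None) -> list[tuple[GenomicInterval, str]]:
        result = []
        for chrom, tree in sorted(self._trees.items()):
            for iv in sorted(tree):
                if repeat_class is None or iv.data == repeat_class:
                    result.append((GenomicInterval(chrom, iv.begin, iv.end), iv.data))
        return result


@dataclass
class SnpGenotypeSet:
    """Biallelic SNP genotype calls indexed by chromosome (0-based positions)."""

    het: dict[str, np.ndarray] = field(default_factory=dict)
    hom_alt: dict[str, np.ndarray] = field(default_factory=dict)

    def count_in(self, interval: GenomicInterval) -> tuple[int, int]:
        """(het, hom_alt) counts with position inside the interval."""
        counts = []
        for table in (self.het, self.hom_alt):
            pos = table.get(interval.chrom)
            if pos is None or interval.is_empty():
                counts.append(0)
            else:
                lo = np.searchsorted(pos, interval.start, side="left")
                hi = np.searchsorted(pos, interval.end, side="left")
                counts.append(int(hi - lo))
        return counts[0], counts[1]


@dataclass
class SVCallReadResult:
    """Parsed candidate calls plus per-line parse errors."""

    calls: list[SVCall]
    errors: list[tuple[int, str]]
    dialect: str = "bed0"

    def __iter__(self) -> Iterator[SVCall]:
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def n_errors(self) -> int:
        return len(self.errors)


_SV_TYPE_ALIASES = {
    "DEL": SVType.DELETION,
    "DELETION": SVType.DELETION,
    "INS": SVType.INSERTION,
    "INSERTION": SVType.INSERTION,
    "RANDOM": SVType.RANDOM,
    "REPEAT": SVType.REPEAT_ELEMENT,
    "REPEAT_ELEMENT": SVType.REPEAT_ELEMENT,
}


def read_sv_calls(path: str, dialect: str = "bed0", source: str = "") -> SVCallReadResult:
    """Read a BED-like candidate SV list.

    ``bed0``: 0-based half-open start/end (plain BED).  ``tsv1``: 1-based
    fully-closed coordinates, converted at the boundary.  Optional columns
    4..6: type, alt_sequence, zygosity; unknown extra columns are ignored.
    """
    if dialect not in ("bed0", "tsv1"):
        raise ValueError(f"unknown dialect {dialect!r}")
    calls: list[SVCall] = []
    errors: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                errors.append((lineno, "fewer than 3 columns"))
                continue
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError:
                errors.append((lineno, "non-integer coordinates"))
                continue
            if dialect == "tsv1":
                start -= 1  # 1-based inclusive -> 0-based half-open
            if start < 0:
                errors.append((lineno, "negative start after conversion"))
                continue
            if end <= start:
                errors.append((lineno, "end <= start after conversion"))
                continue
            sv_type = SVType.DELETION
            if len(fields) >= 4 and fields[3].strip():
                key = fields[3].strip().upper()
                if key in _SV_TYPE_ALIASES:
                    sv_type = _SV_TYPE_ALIASES[key]
                else:
                    errors.append((lineno, f"unknown SV type {fields[3]!r}"))
                    continue
            alt = None
            if len(fields) >= 5 and fields[4].strip() not in ("", ".", "NA"):
                if sv_type is SVType.INSERTION:
                    alt = fields[4].strip().upper()
            zyg = None
            if len(fields) >= 6 and fields[5].strip() not in ("", ".", "NA"):
                try:
                    zyg = Zygosity(fields[5].strip().lower())
                except ValueError:
                    zyg = Zygosity.UNKNOWN
            calls.append(
                SVCall(GenomicInterval(chrom, start, end), sv_type, alt, source, zyg)
            )
    for lineno, msg in errors:
        logger.warning("%s line %d skipped: %s", path, lineno, msg)
    return SVCallReadResult(calls, errors, dialect)


def read_repeat_track(
    path: str,
    chrom_col: int = 0,
    start_col: int = 1,
    end_col: int = 2,
    class_col: int = 3,
) -> RepeatTrack:
    """Read a UCSC rmsk-style TSV into an indexed :class:`RepeatTrack`.

    Class strings are mapped by prefix (``SINE/Alu`` -> ``SINE``); anything
    unrecognised becomes ``other``.  Unparseable rows are skipped with a
    logged count.
    """
    track = RepeatTrack()
    n_skipped = 0
    need = max(chrom_col, start_col, end_col, class_col) + 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < need:
                n_skipped += 1
                continue
            try:
                start = int(fields[start_col])
                end = int(fields[end_col])
            except ValueError:
                n_skipped += 1
                continue
            if end <= start or start < 0:
                n_skipped += 1
                continue
            raw_cls = fields[class_col].split("/")[0].split("?")[0].strip().upper()
            cls = _REPEAT_CLASS_MAP.get(raw_cls, "other")
            track.add(GenomicInterval(fields[chrom_col], start, end), cls)
    if n_skipped:
        logger.warning("%s: skipped %d unparseable repeat rows", path, n_skipped)
    track.n_skipped = n_skipped
    return track


def read_snp_genotypes(path_vcf: str, sample: int | str = 0) -> SnpGenotypeSet:
    """Load biallelic SNP genotype calls from a VCF.

    Only records with REF and (first) ALT of length 1 are retained; GT 0/1
    or 1/0 (phased or not) -> het, 1/1 -> hom_alt; records without a usable
    GT are ignored.
    """
    het: dict[str, list[int]] = {}
    hom: dict[str, list[int]] = {}
    with pysam.VariantFile(path_vcf) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path_vcf}: no sample columns")
        name = samples[sample] if isinstance(sample, int) else sample
        for rec in vcf:
            if rec.alts is None or len(rec.ref) != 1:
                continue
            alt = rec.alts[0]
            if alt is None or len(alt) != 1 or alt not in "ACGTacgt":
                continue
            gt = rec.samples[name].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            # only alleles 0/1 considered; multi-allelic extras ignored
            alleles = tuple(a for a in gt if a in (0, 1))
            if len(alleles) != len(gt):
                continue
            pos0 = rec.pos - 1  # pysam pos is 1-based
            if set(alleles) == {0, 1}:
                het.setdefault(rec.chrom, []).append(pos0)
            elif set(alleles) == {1}:
                hom.setdefault(rec.chrom, []).append(pos0)
    return SnpGenotypeSet(
        het={c: np.array(sorted(v), dtype=int) for c, v in het.items()},
        hom_alt={c: np.array(sorted(v), dtype=int) for c, v in hom.items()},
    )


def write_annotation_table(table: AnnotationTable, path: str) -> None:
    """Serialise an annotation table to CSV; masked cells become ``NA``."""
    df = table.filled(np.nan)
    df.index.name = "site_id"
    df.to_csv(path, na_rep="NA", float_format="%.10g")


def read_annotation_table(path: str) -> AnnotationTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    names = header[1:]
    if len(set(names)) != len(names):  # pandas would silently mangle these
        raise ValueError(f"{path}: duplicate annotation column names")
    df = pd.read_csv(path, index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    return AnnotationTable(df.astype(float))


def write_classified_calls(results: pd.DataFrame, path: str, dialect: str = "bed0") -> None:
    """Write the final per-site classification as a BED-like TSV.

    ``results`` must carry columns chrom/start/end (internal 0-based
    half-open) plus whatever score/vote/stratum/flag columns the classifier
    produced; coordinates are emitted in the requested source dialect.
    """
    out = results.copy()
    if dialect == "tsv1":
        out["start"] = out["start"] + 1
    elif dialect != "bed0":
        raise ValueError(f"unknown dialect {dialect!r}")
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_classified_calls(path: str, dialect: str = "bed0") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if dialect == "tsv1":
        df["start"] = df["start"] - 1
    return df
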